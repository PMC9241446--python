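"""Dynamic contrast-enhancement phantom.

Each slice carries a circular ROI whose mean intensity rises linearly after
the bolus: S(t) = baseline * (1 + slope * t) for post-injection times t, with
the pre-injection scan unenhanced. Slopes are the per-slice ground truth that
the influx-rate estimator must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dce import DCESeries
from ..errors import SpecValidationError

__all__ = ["DCEPhantomSpec", "DCEPhantom", "generate_dce_series", "default_scan_times"]


def default_scan_times(n_post: int = 6, duration: float = 10.0) -> np.ndarray:
    """Baseline at t=0 followed by ``n_post`` evenly spaced scans over ``duration`` min."""
    return np.concatenate([[0.0], np.linspace(duration / n_post, duration, n_post)])


@dataclass(frozen=True)
class DCEPhantomSpec:
    """Geometry, true slopes and noise of the enhancement phantom."""

    n_slices: int = 11
    scan_times: tuple[float, ...] = tuple(default_scan_times())
    slice_slopes: tuple[float, ...] = tuple([0.05] * 11)  # per minute
    baseline_intensity: float = 100.0
    noise_sigma: float = 0.0
    image_shape: tuple[int, int] = (16, 16)
    roi_radius: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_intensity < 0:
            raise SpecValidationError(
                f"baseline_intensity must be >= 0, got {self.baseline_intensity}"
            )
        if self.baseline_intensity == 0:
            raise SpecValidationError("baseline_intensity must be positive to define enhancement")
        t = np.asarray(self.scan_times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise SpecValidationError("scan_times must be strictly increasing")
        if (t <= 0).sum() != 1:
            raise SpecValidationError("exactly one pre-injection (t <= 0) scan is required")
        if len(self.slice_slopes) != self.n_slices:
            raise SpecValidationError("need one true slope per slice")
        if not np.all(np.isfinite(self.slice_slopes)):
            raise SpecValidationError("slopes must be finite")
        if self.noise_sigma < 0:
            raise SpecValidationError("noise_sigma must be >= 0")


@dataclass
class DCEPhantom:
    series: DCESeries
    true_slopes: np.ndarray
    spec: DCEPhantomSpec


def generate_dce_series(spec: DCEPhantomSpec) -> DCEPhantom:
    """Simulate the serial post-contrast scans and return them with true slopes."""
    spec.validate()
    h, w = spec.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    roi2d = ((yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2) <= spec.roi_radius**2
    roi = np.broadcast_to(roi2d, (spec.n_slices, h, w)).copy()

    t = np.asarray(spec.scan_times, dtype=float)
    slopes = np.asarray(spec.slice_slopes, dtype=float)
    # enhancement factor per (scan, slice); pre-injection scan (t<=0) stays at baseline
    factor = 1.0 + slopes[None, :] * np.where(t > 0, t, 0.0)[:, None]
    scans = np.full((t.size, spec.n_slices, h, w), spec.baseline_intensity)
    scans = scans * np.where(roi[None], factor[:, :, None, None], 1.0)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        scans = scans + rng.normal(0.0, spec.noise_sigma, scans.shape)

    series = DCESeries(scans=scans, scan_times=t, roi_mask=roi)
    return DCEPhantom(series=series, true_slopes=slopes, spec=spec)
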