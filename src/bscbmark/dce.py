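"""Dynamic contrast-enhanced quantification.

Relative signal enhancement per slice, per-slice Gd influx rate (Kp, the
least-squares slope of enhancement against time over the post-injection
scans), the whole-cord leakage score (sum of per-slice rates), and the
longitudinal percent normalization against a reference-day value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError, SpecValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DCESeries",
    "EnhancementCurve",
    "LeakageResult",
    "relative_enhancement",
    "estimate_kp",
    "total_leakage",
    "relative_leakage",
]


@dataclass
class DCESeries:
    """Ordered intensity volumes: 1 pre-injection scan + N post-injection.

    ``scans`` has shape (1 + N, n_slices, H, W); ``scan_times`` are minutes
    from injection (the first entry, <= 0, is the baseline scan);
    ``roi_mask`` has shape (n_slices, H, W).
    """

    scans: np.ndarray
    scan_times: np.ndarray
    roi_mask: np.ndarray

    def validate(self) -> None:
        t = np.asarray(self.scan_times, dtype=float)
        if t.ndim != 1 or t.size != self.scans.shape[0]:
            raise SpecValidationError("scan_times length must equal number of scans")
        if not np.all(np.diff(t) > 0):
            raise SpecValidationError("scan_times must be strictly increasing")
        if (t <= 0).sum() != 1:
            raise SpecValidationError("exactly one pre-injection (t <= 0) scan is required")
        if t.size < 3:
            raise SpecValidationError("need >= 2 post-injection scans")
        if self.scans.shape[1:] != self.roi_mask.shape:
            raise SpecValidationError("roi_mask shape must match a single scan volume")
        roi = np.asarray(self.roi_mask, dtype=bool)
        if not roi.reshape(roi.shape[0], -1).any(axis=1).all():
            raise SpecValidationError("ROI is empty in at least one slice")

    @property
    def n_slices(self) -> int:
        return self.scans.shape[1]


@dataclass
class EnhancementCurve:
    """Per-slice relative enhancement E(t) at the post-injection times."""

    times: np.ndarray  # (N,) post-injection minutes
    enhancement: np.ndarray  # (n_slices, N)


@dataclass
class LeakageResult:
    """Per-slice influx rates and their sum (the Gd leakage score)."""

    kp_per_slice: np.ndarray
    gd_leakage: float
    pct_vs_baseline_day: float | None = None


def relative_enhancement(series: DCESeries) -> EnhancementCurve:
    """E_i(t) = (mean ROI intensity at t - baseline mean) / baseline mean, per slice."""
    series.validate()
    roi = np.asarray(series.roi_mask, dtype=bool)
    n_slices = series.n_slices
    means = np.empty((series.scans.shape[0], n_slices))
    for i in range(n_slices):
        means[:, i] = series.scans[:, i][:, roi[i]].mean(axis=1)
    baseline = means[0]
    bad = np.flatnonzero(baseline <= 0)
    if bad.size:
        raise SpecValidationError(
            f"non-positive pre-injection ROI mean in slice(s) {bad.tolist()}"
        )
    enh = (means[1:] - baseline) / baseline  # (N, n_slices)
    return EnhancementCurve(
        times=np.asarray(series.scan_times, dtype=float)[1:],
        enhancement=enh.T,
    )


def estimate_kp(
    curve: EnhancementCurve,
    window: int | None = None,
    through_origin: bool = False,
) -> np.ndarray:
    """Per-slice influx rate: OLS slope of E(t) vs t over the fitting window.

    ``window`` restricts the fit to the first *k* post-injection scans
    (default: all). The intercept is free unless ``through_origin``;
    negative slopes are retained and logged, not clamped.
    """
    t = np.asarray(curve.times, dtype=float)
    e = np.asarray(curve.enhancement, dtype=float)
    if window is not None:
        if window < 2:
            raise SpecValidationError("fitting window must cover >= 2 scans")
        t = t[:window]
        e = e[:, :window]
    if t.size < 2:
        raise SpecValidationError("need >= 2 post-injection time points to fit a slope")

    if through_origin:
        kp = e @ t / (t @ t)
    else:
        tc = t - t.mean()
        kp = (e - e.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    n_neg = int((kp < 0).sum())
    if n_neg:
        logger.info("estimate_kp: %d slice(s) with negative fitted slope retained", n_neg)
    return kp


def total_leakage(kp_per_slice: np.ndarray) -> float:
    """Whole-cord Gd leakage: the exact sum of per-slice influx rates."""
    kp = np.asarray(kp_per_slice, dtype=float)
    if kp.size < 1:
        raise SpecValidationError("need >= 1 slice")
    return float(kp.sum())


def relative_leakage(current: float, baseline: float) -> float:
    """Percent leakage relative to the reference-day value: 100 * current / baseline."""
    if baseline <= 0:
        raise NormalizationError(
            f"reference-day leakage must be positive to normalize, got {baseline}"
        )
    return 100.0 * current / baseline
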