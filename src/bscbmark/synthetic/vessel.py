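"""Two-channel fluorescence vessel phantom.

Vessels are bright annular walls in the endothelial (cd31) channel; the
marker channel is high on a configurable fraction of the filled vessel area
(an angular wedge, so the fraction is exact up to pixel quantization); the
collagen channel is high on a perivascular halo ring outside the outer wall.
Ground-truth masks for every compartment are returned for oracle tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..errors import SpecValidationError
from ..ihc import VesselImage

__all__ = ["VesselPhantomSpec", "VesselPhantom", "generate_vessel_image"]

Vessel = tuple[tuple[float, float], float, float]  # (center yx), inner radius, outer radius


@dataclass(frozen=True)
class VesselPhantomSpec:
    image_shape: tuple[int, int] = (256, 256)
    vessels: tuple[Vessel, ...] = ()
    marker_coverage: float = 0.5
    collagen_halo_width: float = 5.0
    background_level: float = 10.0
    foreground_level: float = 200.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.marker_coverage <= 1.0:
            raise SpecValidationError(f"marker_coverage must lie in [0, 1], got {self.marker_coverage}")
        if self.collagen_halo_width < 0:
            raise SpecValidationError("collagen_halo_width must be >= 0")
        if self.foreground_level <= self.background_level:
            raise SpecValidationError("foreground_level must exceed background_level")
        h, w = self.image_shape
        for (cy, cx), r_in, r_out in self.vessels:
            if not r_out > r_in >= 0:
                raise SpecValidationError(f"need outer_radius > inner_radius >= 0, got {r_in}, {r_out}")
            reach = r_out + self.collagen_halo_width
            if cy - reach < 0 or cx - reach < 0 or cy + reach >= h or cx + reach >= w:
                raise SpecValidationError("vessel (plus halo) must lie inside the image")
        if self.noise_sigma < 0:
            raise SpecValidationError("noise_sigma must be >= 0")


@dataclass
class VesselPhantom:
    image: VesselImage
    vessel_mask: np.ndarray  # filled vessels (lumen + wall)
    wall_mask: np.ndarray
    marker_mask: np.ndarray
    halo_mask: np.ndarray
    spec: VesselPhantomSpec


def generate_vessel_image(
    spec: VesselPhantomSpec,
    region_label: str = "epicenter",
    marker_name: str = "p_selectin",
    collagen_name: str = "collagen1",
) -> VesselPhantom:
    """Render the phantom channels and return them with ground-truth masks."""
    spec.validate()
    h, w = spec.image_shape
    yy, xx = np.mgrid[0:h, 0:w]

    filled = np.zeros((h, w), dtype=bool)
    wall = np.zeros((h, w), dtype=bool)
    marker = np.zeros((h, w), dtype=bool)
    halo = np.zeros((h, w), dtype=bool)
    overlap = False

    for (cy, cx), r_in, r_out in spec.vessels:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        this_filled = d2 <= r_out**2
        if (filled & this_filled).any():
            overlap = True
        this_wall = this_filled & (d2 > r_in**2)
        theta = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
        this_marker = this_filled & (theta < 2 * np.pi * spec.marker_coverage)
        if spec.marker_coverage >= 1.0:
            this_marker = this_filled
        this_halo = (d2 > r_out**2) & (d2 <= (r_out + spec.collagen_halo_width) ** 2)
        filled |= this_filled
        wall |= this_wall
        marker |= this_marker
        halo |= this_halo

    if overlap:
        warnings.warn("overlapping vessels: reporting union geometry", stacklevel=2)
        halo &= ~filled

    bg, fg = spec.background_level, spec.foreground_level
    cd31 = np.where(wall, fg, bg).astype(float)
    marker_ch = np.where(marker, fg, bg).astype(float)
    collagen_ch = np.where(halo, fg, bg).astype(float)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        cd31 = cd31 + rng.normal(0.0, spec.noise_sigma, cd31.shape)
        marker_ch = marker_ch + rng.normal(0.0, spec.noise_sigma, marker_ch.shape)
        collagen_ch = collagen_ch + rng.normal(0.0, spec.noise_sigma, collagen_ch.shape)

    image = VesselImage(
        channels={"cd31": cd31, marker_name: marker_ch, collagen_name: collagen_ch},
        region_label=region_label,
        tissue_roi=np.ones((h, w), dtype=bool),
    )
    return VesselPhantom(
        image=image,
        vessel_mask=filled,
        wall_mask=wall,
        marker_mask=marker,
        halo_mask=halo,
        spec=spec,
    )
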