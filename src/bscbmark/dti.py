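"""Diffusion-tensor quantification.

Fits the log-linear tensor model per voxel, derives FA/AD/RD maps, calibrates
binarization thresholds against a target white-matter area fraction, and
computes the %FA-positive / %AD-positive / %RD-negative area scores over a
cord ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import (
    DegenerateCalibrationError,
    SpecValidationError,
    UnidentifiableSchemeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GradientScheme",
    "DWIStack",
    "TensorMap",
    "ScalarMapSet",
    "DTIThresholds",
    "AreaScores",
    "ThresholdCalibration",
    "fit_tensor",
    "compute_scalar_maps",
    "calibrate_threshold",
    "area_scores",
    "scalar_invariants_from_eigvals",
]


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion encoding: one b-value (s/mm^2) and unit gradient directions."""

    bval: float
    directions: np.ndarray  # (K, 3), unit rows

    def validate(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise SpecValidationError("directions must be a (K, 3) array")
        if self.bval <= 0:
            raise SpecValidationError("bval must be positive")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise SpecValidationError("gradient directions must be unit vectors")

    @property
    def n_unique_directions(self) -> int:
        """Directions that are distinct up to sign flip."""
        d = np.asarray(self.directions, dtype=float)
        canon = np.where(
            (d[:, [0]] < 0)
            | ((d[:, [0]] == 0) & (d[:, [1]] < 0))
            | ((d[:, [0]] == 0) & (d[:, [1]] == 0) & (d[:, [2]] < 0)),
            -d,
            d,
        )
        uniq = np.unique(np.round(canon, 10), axis=0)
        return len(uniq)

    def design_matrix(self) -> np.ndarray:
        """Rows [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz] for each direction."""
        g = np.asarray(self.directions, dtype=float)
        return np.column_stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ]
        )


@dataclass
class DWIStack:
    """Per-voxel vector of 1 b0 + K diffusion-weighted intensities.

    ``signals[..., 0]`` is the b0 image; ``signals[..., 1:]`` matches
    ``scheme.directions`` row for row. Leading axes are the voxel grid.
    """

    signals: np.ndarray
    scheme: GradientScheme
    affine: np.ndarray | None = None

    def validate(self) -> None:
        self.scheme.validate()
        k = np.asarray(self.scheme.directions).shape[0]
        if self.signals.shape[-1] != k + 1:
            raise SpecValidationError(
                f"signals last axis must be 1 + K = {k + 1}, got {self.signals.shape[-1]}"
            )
        if k < 6 or self.scheme.n_unique_directions < 6:
            raise UnidentifiableSchemeError(
                f"need >= 6 non-collinear directions, got {self.scheme.n_unique_directions}"
            )


@dataclass
class TensorMap:
    """Per-voxel symmetric tensors with eigenvalues sorted descending.

    ``valid_mask`` excludes voxels whose b0 or DW signal was non-positive;
    ``n_clamped`` counts negative eigenvalues clamped to zero.
    """

    tensors: np.ndarray  # (..., 3, 3)
    eigenvalues: np.ndarray  # (..., 3), lam1 >= lam2 >= lam3 >= 0
    valid_mask: np.ndarray
    n_clamped: int = 0


@dataclass
class ScalarMapSet:
    """FA/AD/RD maps over a voxel grid with the cord (and optional WM) mask."""

    fa_map: np.ndarray
    ad_map: np.ndarray
    rd_map: np.ndarray
    cord_mask: np.ndarray
    wm_mask: np.ndarray | None = None


@dataclass(frozen=True)
class DTIThresholds:
    """Binarization thresholds: FA >= fa_min, AD >= ad_min, RD <= rd_max."""

    fa_min: float = 0.55
    ad_min: float = 1.4
    rd_max: float = 0.5

    def validate(self) -> None:
        if not 0.0 < self.fa_min < 1.0:
            raise SpecValidationError(f"fa_min must lie in (0, 1), got {self.fa_min}")
        if self.ad_min <= 0 or self.rd_max <= 0:
            raise SpecValidationError("ad_min and rd_max must be positive")


@dataclass
class AreaScores:
    """Percent of the cord cross-section passing each binarization."""

    pct_fa_positive: float
    pct_ad_positive: float
    pct_rd_negative: float

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_fa": self.pct_fa_positive,
            "pct_ad": self.pct_ad_positive,
            "pct_rd": self.pct_rd_negative,
        }


@dataclass
class ThresholdCalibration:
    """Calibrated threshold and the area fraction it actually achieves."""

    threshold: float
    achieved_fraction: float
    direction: str
    target_fraction: float


def scalar_invariants_from_eigvals(eigvals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FA, AD, RD from eigenvalues sorted descending along the last axis.

    AD = lam1; RD = (lam2 + lam3) / 2;
    FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||, 0 where all eigenvalues are 0.
    """
    lam = np.asarray(eigvals, dtype=float)
    ad = lam[..., 0]
    rd = 0.5 * (lam[..., 1] + lam[..., 2])
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return fa, ad, rd


def fit_tensor(stack: DWIStack) -> TensorMap:
    """Least-squares log-linear tensor fit, voxel-wise.

    Solves ``ln(S_k / S0) = -b g_k' D g_k`` for the six unique tensor
    elements. Voxels with non-positive b0 or DW signal are flagged invalid
    and excluded; negative eigenvalues are clamped to 0 (count logged).
    """
    stack.validate()
    signals = np.asarray(stack.signals, dtype=float)
    grid_shape = signals.shape[:-1]
    flat = signals.reshape(-1, signals.shape[-1])
    s0 = flat[:, 0]
    dw = flat[:, 1:]

    valid = (s0 > 0) & np.all(dw > 0, axis=1)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.warning("fit_tensor: %d voxels with non-positive signal excluded", n_invalid)

    b = stack.scheme.bval * 1.0e-3  # eigenvalues come out in um^2/ms
    bmat = stack.scheme.design_matrix()
    pinv = np.linalg.pinv(bmat)

    y = np.zeros_like(dw)
    y[valid] = -np.log(dw[valid] / s0[valid, None]) / b
    coeffs = y @ pinv.T  # (N, 6): dxx, dyy, dzz, dxy, dxz, dyz

    tensors = np.zeros((flat.shape[0], 3, 3))
    tensors[:, 0, 0] = coeffs[:, 0]
    tensors[:, 1, 1] = coeffs[:, 1]
    tensors[:, 2, 2] = coeffs[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = coeffs[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = coeffs[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = coeffs[:, 5]

    eigvals = np.linalg.eigvalsh(tensors)[:, ::-1]  # descending
    n_clamped = int((eigvals < 0).sum())
    if n_clamped:
        logger.info("fit_tensor: clamped %d negative eigenvalues to 0", n_clamped)
    eigvals = np.clip(eigvals, 0.0, None)
    eigvals[~valid] = 0.0
    tensors[~valid] = 0.0

    return TensorMap(
        tensors=tensors.reshape(grid_shape + (3, 3)),
        eigenvalues=eigvals.reshape(grid_shape + (3,)),
        valid_mask=valid.reshape(grid_shape),
        n_clamped=n_clamped,
    )


def compute_scalar_maps(
    tensors: TensorMap,
    cord_mask: np.ndarray,
    wm_mask: np.ndarray | None = None,
) -> ScalarMapSet:
    """FA/AD/RD maps from a fitted tensor map. Degenerate voxels get FA = 0."""
    fa, ad, rd = scalar_invariants_from_eigvals(tensors.eigenvalues)
    cord = np.asarray(cord_mask, dtype=bool) & tensors.valid_mask
    return ScalarMapSet(fa_map=fa, ad_map=ad, rd_map=rd, cord_mask=cord, wm_mask=wm_mask)


def calibrate_threshold(
    scalar_map: np.ndarray,
    cord_mask: np.ndarray,
    wm_fraction: float,
    direction: Literal[">=", "<="] = ">=",
) -> ThresholdCalibration:
    """Threshold whose binarized area fraction matches ``wm_fraction``.

    Candidate thresholds are the distinct observed within-cord values (the
    achievable operating points); the one whose passing fraction is nearest
    the target is returned, ties resolved toward the more selective
    threshold. On a continuous map this is the empirical (1 - f) or f
    quantile; on a multi-modal map it is the closest achievable fraction,
    which can deviate from the target by the mass of a tied value.
    """
    if not 0.0 < wm_fraction < 1.0:
        raise SpecValidationError(f"wm_fraction must lie in (0, 1), got {wm_fraction}")
    if direction not in (">=", "<="):
        raise SpecValidationError(f"direction must be '>=' or '<=', got {direction!r}")
    mask = np.asarray(cord_mask, dtype=bool)
    if not mask.any():
        raise SpecValidationError("cord_mask is empty")
    values = np.asarray(scalar_map, dtype=float)[mask]
    if np.ptp(values) == 0:
        raise DegenerateCalibrationError(
            "scalar map is constant within the cord; no threshold separates any fraction"
        )
    n = values.size
    uniq, counts = np.unique(values, return_counts=True)  # ascending
    if direction == ">=":
        # passing count when thresholding at each distinct value
        passing = np.cumsum(counts[::-1])
        candidates = uniq[::-1]
    else:
        passing = np.cumsum(counts)
        candidates = uniq
    fractions = passing / n
    best = int(np.argmin(np.abs(fractions - wm_fraction)))  # first hit = more selective
    t = float(candidates[best])
    achieved = float(fractions[best])
    logger.info(
        "calibrate_threshold: direction %s target %.4f -> t=%.6g (achieved %.4f)",
        direction,
        wm_fraction,
        t,
        achieved,
    )
    return ThresholdCalibration(
        threshold=t, achieved_fraction=achieved, direction=direction, target_fraction=wm_fraction
    )


def _slice_scores(fa, ad, rd, mask, thresholds: DTIThresholds) -> tuple[float, float, float]:
    n = int(mask.sum())
    pct_fa = 100.0 * float((fa[mask] >= thresholds.fa_min).sum()) / n
    pct_ad = 100.0 * float((ad[mask] >= thresholds.ad_min).sum()) / n
    pct_rd = 100.0 * float((rd[mask] <= thresholds.rd_max).sum()) / n
    return pct_fa, pct_ad, pct_rd


def area_scores(
    maps: ScalarMapSet,
    thresholds: DTIThresholds | None = None,
    per_slice: bool = True,
) -> AreaScores:
    """%FA-positive / %AD-positive / %RD-negative area over the cord ROI.

    Comparisons are inclusive: ties at the threshold count as positive.
    For a 3-D map set (slice axis first) scores are computed per axial slice
    and averaged, mirroring the multi-slice acquisition; ``per_slice=False``
    pools all cord voxels instead.
    """
    if thresholds is None:
        thresholds = DTIThresholds()
    thresholds.validate()
    mask = np.asarray(maps.cord_mask, dtype=bool)
    if not mask.any():
        raise SpecValidationError("cord_mask is empty")

    if per_slice and mask.ndim == 3:
        rows = [
            _slice_scores(maps.fa_map[i], maps.ad_map[i], maps.rd_map[i], mask[i], thresholds)
            for i in range(mask.shape[0])
            if mask[i].any()
        ]
        pct_fa, pct_ad, pct_rd = (float(np.mean(col)) for col in zip(*rows))
    else:
        pct_fa, pct_ad, pct_rd = _slice_scores(
            maps.fa_map, maps.ad_map, maps.rd_map, mask, thresholds
        )
    return AreaScores(pct_fa_positive=pct_fa, pct_ad_positive=pct_ad, pct_rd_negative=pct_rd)
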