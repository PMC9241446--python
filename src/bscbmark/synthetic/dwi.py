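"""Axial spinal-cord diffusion phantom.

The cord is a disk; white matter is an annulus whose area is a configurable
fraction of the cord cross-section (defaults to the 55% injection-site
fraction used for threshold calibration); an optional lesion wedge inside the
white matter carries lowered FA/AD and raised RD. Diffusion-weighted signals
follow the mono-exponential tensor model S_k = S0 * exp(-b g_k' D g_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ..dti import DWIStack, GradientScheme, ScalarMapSet, scalar_invariants_from_eigvals
from ..errors import SpecValidationError, UnidentifiableSchemeError

__all__ = [
    "CordPhantomSpec",
    "DWIPhantom",
    "default_scheme",
    "generate_dwi_phantom",
    "naive_cord_spec",
    "lesioned_cord_spec",
]

#: Eigenvalue triplets (lam1, lam2, lam3) in um^2/ms. White matter is chosen
#: so that FA >= 0.55, AD >= 1.4 and RD <= 0.5 (the binarization thresholds
#: classify it as intact), gray matter falls on the other side of all three,
#: and lesion tissue shows lowered FA/AD with raised RD.
_WM_EIGVALS = (1.6, 0.4, 0.4)
_GM_EIGVALS = (0.9, 0.7, 0.7)
_LESION_EIGVALS = (1.0, 0.75, 0.75)


def default_scheme(bval: float = 4900.0) -> GradientScheme:
    """Six-direction dual-gradient encoding scheme plus an implicit b0.

    Directions are the +-x+-y / +-y+-z / +-x+-z diagonals, normalized.
    ``bval`` is in s/mm^2.
    """
    raw = np.array(
        [
            [1.0, 1.0, 0.0],
            [1.0, -1.0, 0.0],
            [0.0, 1.0, 1.0],
            [0.0, 1.0, -1.0],
            [1.0, 0.0, 1.0],
            [-1.0, 0.0, 1.0],
        ]
    )
    return GradientScheme(bval=bval, directions=raw / np.linalg.norm(raw, axis=1, keepdims=True))


@dataclass(frozen=True)
class CordPhantomSpec:
    """Geometry, tissue eigenvalues and noise model of the cord phantom."""

    image_shape: tuple[int, int] = (64, 64)
    cord_radius: float = 24.0
    wm_fraction: float = 0.55
    wm_values: tuple[float, float, float] = _WM_EIGVALS
    gm_values: tuple[float, float, float] = _GM_EIGVALS
    lesion_fraction: float = 0.0
    lesion_values: tuple[float, float, float] = _LESION_EIGVALS
    noise_sigma: float = 0.0
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    s0: float = 1000.0
    n_slices: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.wm_fraction < 1.0:
            raise SpecValidationError(f"wm_fraction must lie in (0, 1), got {self.wm_fraction}")
        if not 0.0 <= self.lesion_fraction < 1.0:
            raise SpecValidationError(f"lesion_fraction must lie in [0, 1), got {self.lesion_fraction}")
        for name in ("wm_values", "gm_values", "lesion_values"):
            vals = getattr(self, name)
            if len(vals) != 3 or any(v < 0 for v in vals):
                raise SpecValidationError(f"{name} must be three eigenvalues >= 0, got {vals}")
        if self.cord_radius <= 0:
            raise SpecValidationError("cord_radius must be positive")
        if self.s0 <= 0:
            raise SpecValidationError("s0 must be positive")
        if self.noise_sigma < 0:
            raise SpecValidationError("noise_sigma must be >= 0")
        if self.n_slices < 1:
            raise SpecValidationError("n_slices must be >= 1")
        h, w = self.image_shape
        if self.cord_radius > min(h, w) / 2:
            raise SpecValidationError("cord must fit inside the image")


@dataclass
class DWIPhantom:
    """Generated stack plus exact ground truth (noise-independent)."""

    stack: DWIStack
    truth: ScalarMapSet
    cord_mask: np.ndarray
    wm_mask: np.ndarray
    lesion_mask: np.ndarray
    eigenvalues: np.ndarray  # (..., 3) descending, per voxel
    spec: CordPhantomSpec


def naive_cord_spec(seed: int = 0, **overrides) -> CordPhantomSpec:
    """Healthy injection-site preset: 55% white-matter annulus, no lesion."""
    return CordPhantomSpec(seed=seed, **overrides)


def lesioned_cord_spec(seed: int = 0, lesion_fraction: float = 0.3, **overrides) -> CordPhantomSpec:
    """Preset with a demyelinating wedge occupying a fraction of the WM."""
    return CordPhantomSpec(seed=seed, lesion_fraction=lesion_fraction, **overrides)


def _tissue_masks(spec: CordPhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = spec.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    cord = r2 <= spec.cord_radius**2
    # WM annulus: inner radius chosen so the annulus area fraction equals
    # wm_fraction exactly in the continuum limit.
    r_inner = spec.cord_radius * np.sqrt(1.0 - spec.wm_fraction)
    wm = cord & (r2 > r_inner**2)
    if spec.lesion_fraction > 0:
        theta = np.arctan2(yy - cy, xx - cx)  # [-pi, pi]
        span = 2.0 * np.pi * spec.lesion_fraction
        lesion = wm & (theta >= -np.pi) & (theta < -np.pi + span)
    else:
        lesion = np.zeros_like(wm)
    return cord, wm, lesion


def generate_dwi_phantom(spec: CordPhantomSpec, scheme: GradientScheme | None = None) -> DWIPhantom:
    """Simulate a DWI stack from the cord phantom and return it with ground truth.

    Per-voxel signals follow ``S_k = S0 * exp(-b g' D g)`` for the tissue
    tensor assigned to the voxel (principal axis along the slice normal),
    with additive noise of scale ``noise_sigma``. The returned scalar maps
    and masks are exact, computed from the assigned eigenvalues.
    """
    spec.validate()
    if scheme is None:
        scheme = default_scheme()
    scheme.validate()
    if scheme.n_unique_directions < 6:
        raise UnidentifiableSchemeError(
            f"need >= 6 non-collinear diffusion directions, got {scheme.n_unique_directions}"
        )

    cord, wm, lesion = _tissue_masks(spec)
    h, w = spec.image_shape

    eigvals = np.zeros((h, w, 3))
    eigvals[...] = np.asarray(spec.gm_values)
    eigvals[wm] = np.asarray(spec.wm_values)
    eigvals[lesion] = np.asarray(spec.lesion_values)
    # principal axis = z (cord axis, through-plane); tensor is diagonal in
    # voxel frame with D = diag(lam2, lam3, lam1)
    dzz = eigvals[..., 0]
    dxx = eigvals[..., 1]
    dyy = eigvals[..., 2]

    g = scheme.directions
    # b in s/mm^2, eigenvalues in um^2/ms: b*D is dimensionless after the
    # 1e-3 unit conversion (1 um^2/ms = 1e-3 mm^2/s).
    b = scheme.bval * 1.0e-3
    # g' D g for diagonal D
    quad = (
        g[:, 0] ** 2 * dxx[..., None]
        + g[:, 1] ** 2 * dyy[..., None]
        + g[:, 2] ** 2 * dzz[..., None]
    )
    dw = spec.s0 * np.exp(-b * quad)  # (h, w, K)
    signals = np.concatenate([np.full((h, w, 1), spec.s0), dw], axis=-1)

    if spec.n_slices > 1:
        signals = np.broadcast_to(signals, (spec.n_slices, h, w, signals.shape[-1])).copy()
        cord3 = np.broadcast_to(cord, (spec.n_slices, h, w)).copy()
        wm3 = np.broadcast_to(wm, (spec.n_slices, h, w)).copy()
        lesion3 = np.broadcast_to(lesion, (spec.n_slices, h, w)).copy()
        eig3 = np.broadcast_to(eigvals, (spec.n_slices, h, w, 3)).copy()
    else:
        cord3, wm3, lesion3, eig3 = cord, wm, lesion, eigvals

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "rician":
            re = signals + rng.normal(0.0, spec.noise_sigma, signals.shape)
            im = rng.normal(0.0, spec.noise_sigma, signals.shape)
            signals = np.hypot(re, im)
        else:
            signals = signals + rng.normal(0.0, spec.noise_sigma, signals.shape)

    eig_desc = np.sort(eig3, axis=-1)[..., ::-1]
    fa, ad, rd = scalar_invariants_from_eigvals(eig_desc)
    truth = ScalarMapSet(fa_map=fa, ad_map=ad, rd_map=rd, cord_mask=cord3, wm_mask=wm3)

    stack = DWIStack(signals=signals, scheme=scheme)
    return DWIPhantom(
        stack=stack,
        truth=truth,
        cord_mask=cord3,
        wm_mask=wm3,
        lesion_mask=lesion3,
        eigenvalues=eig_desc,
        spec=spec,
    )
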