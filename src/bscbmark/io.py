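"""File-format adapters: NIfTI-1 volumes, multi-page TIFF channels, CSV tables.

Thin wrappers around nibabel / tifffile / pandas so the quantification
modules stay array-in, array-out.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import SpecValidationError
from .ihc import VesselImage

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_mask",
    "load_mask",
    "save_vessel_image",
    "load_vessel_image",
    "save_cohort_csv",
    "load_cohort_csv",
    "save_json",
    "load_yaml_config",
    "load_scan_times",
]


def save_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_mask(path: str | Path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0


def save_vessel_image(path: str | Path, image: VesselImage) -> None:
    """Multi-page TIFF, one page per channel, channel order recorded in metadata."""
    names = list(image.channels)
    stack = np.stack([np.asarray(image.channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(
        str(path),
        stack,
        photometric="minisblack",
        metadata={"channels": names, "region_label": image.region_label},
    )


def load_vessel_image(
    path: str | Path,
    channel_names: list[str] | None = None,
    region_label: str = "epicenter",
    tissue_roi: np.ndarray | None = None,
) -> VesselImage:
    """Read a multi-page TIFF; channel order from metadata unless given explicitly."""
    with tifffile.TiffFile(str(path)) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    if channel_names is None:
        channel_names = meta.get("channels")
        region_label = meta.get("region_label", region_label)
    if channel_names is None or len(channel_names) != stack.shape[0]:
        raise SpecValidationError(
            f"need one channel name per TIFF page ({stack.shape[0]}), got {channel_names}"
        )
    channels = {name: stack[i].astype(float) for i, name in enumerate(channel_names)}
    return VesselImage(channels=channels, region_label=region_label, tissue_roi=tissue_roi)


def save_cohort_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    from .stats import validate_cohort_table

    return validate_cohort_table(pd.read_csv(path))


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise SpecValidationError(f"config must be a mapping, got {type(config).__name__}")
    return config


def load_scan_times(path: str | Path) -> np.ndarray:
    """Scan-time table: CSV with a ``time_min`` column (or a single column)."""
    df = pd.read_csv(path)
    col = "time_min" if "time_min" in df.columns else df.columns[0]
    return df[col].to_numpy(dtype=float)
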