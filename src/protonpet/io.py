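"""Volume and mask I/O.

NIfTI (.nii/.nii.gz) and NRRD (.nrrd/.nhdr) are read and written
through SimpleITK. Internally arrays are indexed (x, y, z) in physical
mm coordinates with a voxel-center origin; SimpleITK's (z, y, x) array
layout is transposed at the I/O boundary, and spacing/origin are taken
from the image header. Orientation matrices beyond axis ordering are
not interpreted — volumes are assumed axis-aligned, which is what the
rest of the pipeline requires.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .grids import ROIMask, VolumeGrid

_EXTS = (".nii", ".nii.gz", ".nrrd", ".nhdr")


def _check_path(path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume file not found: {p}")
    return p


def read_volume(path) -> VolumeGrid:
    """Read a scalar volume from NIfTI or NRRD."""
    p = _check_path(path)
    img = sitk.ReadImage(str(p))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    return VolumeGrid(arr, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()))


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a volume to NIfTI or NRRD (chosen by extension)."""
    p = Path(path)
    if not any(str(p).endswith(e) for e in _EXTS):
        raise ValueError(f"unsupported volume format: {p.name} (use {_EXTS})")
    img = sitk.GetImageFromArray(volume.values.transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in volume.spacing_mm))
    img.SetOrigin(tuple(float(o) for o in volume.origin_mm))
    p.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(p))


def read_mask(path) -> ROIMask:
    """Read a uint8 ROI mask volume; any non-zero voxel is true."""
    v = read_volume(path)
    return ROIMask(v.values != 0, v.spacing_mm, v.origin_mm)


def write_mask(mask: ROIMask, path) -> None:
    p = Path(path)
    if not any(str(p).endswith(e) for e in _EXTS):
        raise ValueError(f"unsupported volume format: {p.name} (use {_EXTS})")
    img = sitk.GetImageFromArray(mask.values.transpose(2, 1, 0).astype(np.uint8))
    img.SetSpacing(tuple(float(s) for s in mask.spacing_mm))
    img.SetOrigin(tuple(float(o) for o in mask.origin_mm))
    p.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(p))


def write_bev_csv(values: np.ndarray, path, valid: np.ndarray | None = None) -> None:
    """Write a 2D BEV array as long-format CSV keyed by cell indices."""
    values = np.asarray(values)
    iu, iv = np.meshgrid(np.arange(values.shape[0]), np.arange(values.shape[1]),
                         indexing="ij")
    df = pd.DataFrame({"iu": iu.ravel(), "iv": iv.ravel(),
                       "value": values.ravel()})
    if valid is not None:
        df["valid"] = np.asarray(valid, dtype=bool).ravel()
    df.to_csv(path, index=False)


def read_bev_csv(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a long-format BEV CSV back into a dense 2D array."""
    df = pd.read_csv(_check_path(path))
    shape = (int(df["iu"].max()) + 1, int(df["iv"].max()) + 1)
    values = np.full(shape, np.nan)
    values[df["iu"], df["iv"]] = df["value"]
    valid = None
    if "valid" in df.columns:
        valid = np.zeros(shape, dtype=bool)
        valid[df["iu"], df["iv"]] = df["valid"]
    return values, valid
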