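"""NIfTI volume/mask I/O, header-affine mask resampling, and animal CSV tables."""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import SchemaError, ValidationError
from .grids import BinaryMask, BranchLabelVolume, VolumeGrid

REQUIRED_TABLE_COLUMNS = ("animal_id", "group")


def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Read a single-file NIfTI (.nii/.nii.gz) as a :class:`VolumeGrid`.

    4D images with a singleton fourth axis are squeezed; true 4D images are
    rejected.  Non-finite voxels raise a validation error reporting their
    count.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D image, got {data.ndim}D with shape {data.shape}")
    data = data.astype(np.float32)
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValidationError(f"{path} contains {n_bad} non-finite voxel(s)")
    return VolumeGrid(data, _spacing_from_header(img), np.asarray(img.affine))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI file as a boolean mask (non-zero -> True)."""
    vol = read_volume(path)
    return BinaryMask(vol.data > 0, vol.spacing, vol.affine)


def write_volume(volume: VolumeGrid | BinaryMask | BranchLabelVolume, path: str | os.PathLike) -> Path:
    """Write a grid object as NIfTI.

    Masks are stored as uint8, branch labels as int16, intensities as
    float32; header spacing and affine match the input grid.
    """
    path = Path(path)
    if isinstance(volume, BinaryMask):
        data = volume.data.astype(np.uint8)
    elif isinstance(volume, BranchLabelVolume):
        data = volume.data.astype(np.int16)
    else:
        data = volume.data.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    parent = path.parent
    try:
        parent.mkdir(parents=True, exist_ok=True)
        nib.save(img, str(path))
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
    return path


def resample_mask_to_grid(mask: BinaryMask, target: VolumeGrid | BinaryMask) -> BinaryMask:
    """Nearest-neighbour resample ``mask`` onto ``target``'s grid.

    Each target voxel index is mapped through ``target.affine`` to world
    coordinates and back through the inverse of ``mask.affine``; the nearest
    source voxel supplies the value, out-of-bounds voxels are False.
    """
    try:
        inv_src = np.linalg.inv(mask.affine)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("mask affine is singular") from exc
    # composed voxel->voxel transform: src_idx = inv(A_src) @ A_tgt @ tgt_idx
    compose = inv_src @ target.affine
    matrix = compose[:3, :3]
    offset = compose[:3, 3]
    out = ndimage.affine_transform(
        mask.data.astype(np.uint8),
        matrix,
        offset=offset,
        output_shape=target.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return BinaryMask(out > 0, target.spacing, target.affine)


def read_animal_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-animal endpoint CSV.

    Requires ``animal_id`` and ``group`` columns; endpoint columns are
    parsed numerically with blank cells as NaN.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    table = pd.read_csv(path)
    for col in REQUIRED_TABLE_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"animal table is missing required column {col!r}")
    table["animal_id"] = table["animal_id"].astype(str)
    table["group"] = table["group"].astype(str)
    for col in table.columns:
        if col not in REQUIRED_TABLE_COLUMNS:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    return table
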