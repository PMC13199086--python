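"""Voxel-grid containers shared by every pipeline stage.

The axis convention is fixed throughout the package: arrays are indexed
``(x, y, z)`` with ``z`` the axial slice axis, 0-based indices addressing
voxel centers.  ``spacing`` is the per-axis voxel size in millimetres and
``affine`` the 4x4 voxel-index -> world-mm transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError


def default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    """Axis-aligned affine with the given spacing and origin at voxel (0,0,0)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Finite real intensities in arbitrary units.
    spacing : tuple of float
        Per-axis voxel size ``(sx, sy, sz)`` in mm, strictly positive.
    affine : ndarray, shape (4, 4), optional
        Voxel-index -> world-mm transform.  Defaults to an axis-aligned
        diagonal built from ``spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float32)
        if data.ndim != 3:
            raise ValidationError(f"expected a 3D volume, got {data.ndim}D")
        n_bad = int(np.count_nonzero(~np.isfinite(data)))
        if n_bad:
            raise ValidationError(f"volume contains {n_bad} non-finite voxel(s)")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be 3 strictly positive values, got {spacing}")
        affine = self.affine
        if affine is None:
            affine = default_affine(spacing)  # type: ignore[arg-type]
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Same geometry, new intensities."""
        return replace(self, data=np.asarray(data, dtype=np.float32))

    def same_grid_as(self, other: "VolumeGrid | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine)
        )


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid with the same geometry contract as :class:`VolumeGrid`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValidationError(f"expected a 3D mask, got {data.ndim}D")
        data = data.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValidationError("spacing must be strictly positive")
        affine = self.affine
        if affine is None:
            affine = default_affine(spacing)  # type: ignore[arg-type]
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValidationError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return replace(self, data=np.asarray(data).astype(bool))

    def same_grid_as(self, other: "VolumeGrid | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine)
        )


@dataclass(frozen=True)
class BranchLabelVolume:
    """Integer branch level per skeleton voxel.

    ``-1`` marks non-skeleton voxels; ``0`` the trunk; ``k >= 1`` branch
    level ``k``.  ``main_component`` is the component id flagged as the
    main trunk (largest component by voxel count), or ``None`` if empty.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    main_component: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValidationError("label volume must be 3D")
        data = data.astype(np.int16)
        spacing = tuple(float(s) for s in self.spacing)
        affine = self.affine
        if affine is None:
            affine = default_affine(spacing)  # type: ignore[arg-type]
        affine = np.asarray(affine, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def skeleton_mask(self) -> BinaryMask:
        return BinaryMask(self.data >= 0, self.spacing, self.affine)

    def same_grid_as(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def require_same_grid(a, b, what: str = "inputs") -> None:
    if a.shape != b.shape:
        raise ValidationError(f"{what} have mismatched shapes {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValidationError(f"{what} have mismatched spacings {a.spacing} vs {b.spacing}")
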