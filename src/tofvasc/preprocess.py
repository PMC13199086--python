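"""Body masking, intensity normalization, denoising, per-slice normalization.

These stages prepare a whole-body FLASH-TOF magnitude volume for vessel
enhancement: delimit the animal's body, map within-body intensities onto a
robust [0, 1] scale, smooth noise, and remove the slice-to-slice intensity
modulation caused by crosstalk/saturation in sequential multi-slice TOF
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError, ProcessingError, ValidationError
from .grids import BinaryMask, VolumeGrid, require_same_grid
from .segment import CONN26, otsu_threshold


@dataclass(frozen=True)
class PreprocessParams:
    """Preprocessing knobs.

    close_radius_vox : morphological closing ball radius in voxels.
    denoise_sigma_mm : Gaussian smoothing sigma in mm (~1 in-plane voxel).
    robust_percentiles : (lo, hi) percentiles for robust [0,1] rescaling.
    min_slice_mask_voxels : slices with fewer within-mask voxels are exempt
        from per-slice normalization.
    """

    close_radius_vox: int = 2
    denoise_sigma_mm: float = 0.12
    robust_percentiles: tuple[float, float] = (1.0, 99.0)
    min_slice_mask_voxels: int = 50

    def __post_init__(self) -> None:
        if self.close_radius_vox < 0:
            raise ParameterError("close_radius_vox must be >= 0")
        if self.denoise_sigma_mm <= 0:
            raise ParameterError("denoise_sigma_mm must be > 0")
        lo, hi = self.robust_percentiles
        if not (0 <= lo < hi <= 100):
            raise ParameterError("robust_percentiles must satisfy 0 <= lo < hi <= 100")
        if self.min_slice_mask_voxels < 1:
            raise ParameterError("min_slice_mask_voxels must be >= 1")


def _ball(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (xx**2 + yy**2 + zz**2) <= r**2


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a boolean array."""
    labels, n = ndimage.label(mask, structure=CONN26)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def compute_body_mask(volume: VolumeGrid, params: PreprocessParams | None = None) -> BinaryMask:
    """Threshold + morphological cleanup body mask.

    Otsu's criterion on all voxels picks the threshold; the mask is closed
    with a ball, holes are filled in 3D, and only the largest 26-connected
    component is kept.
    """
    params = params or PreprocessParams()
    data = volume.data
    if np.all(data == data.flat[0]):
        raise DegenerateInputError("cannot compute a body mask from a constant volume")
    t = otsu_threshold(data.ravel())
    mask = data >= t
    if params.close_radius_vox > 0:
        mask = ndimage.binary_closing(mask, structure=_ball(params.close_radius_vox))
    mask = ndimage.binary_fill_holes(mask)
    mask = largest_component(mask)
    if not mask.any():
        raise ProcessingError("body mask is empty after morphological cleanup")
    return BinaryMask(mask, volume.spacing, volume.affine)


def normalize_within_mask(
    volume: VolumeGrid, mask: BinaryMask, params: PreprocessParams | None = None
) -> VolumeGrid:
    """Robust percentile rescaling of within-mask intensities to [0, 1].

    Values are mapped linearly so that the ``p_lo``/``p_hi`` percentiles of
    within-mask intensity land on 0 and 1, then clipped; voxels outside the
    mask become 0.
    """
    params = params or PreprocessParams()
    require_same_grid(volume, mask, "volume and mask")
    inside = volume.data[mask.data]
    if inside.size == 0:
        raise ValidationError("mask is empty")
    lo, hi = np.percentile(inside, params.robust_percentiles)
    if hi == lo:
        raise DegenerateInputError("degenerate intensity range within mask (p_hi == p_lo)")
    out = np.clip((volume.data - lo) / (hi - lo), 0.0, 1.0)
    out[~mask.data] = 0.0
    return volume.with_data(out)


def gaussian_denoise(volume: VolumeGrid, params: PreprocessParams | None = None) -> VolumeGrid:
    """Separable 3D Gaussian smoothing with sigma given in mm.

    Per-axis voxel sigma is ``denoise_sigma_mm / spacing_axis``; boundaries
    are handled by edge replication.
    """
    params = params or PreprocessParams()
    if params.denoise_sigma_mm <= 0:
        raise ParameterError("denoise sigma must be positive")
    sig_vox = [params.denoise_sigma_mm / s for s in volume.spacing]
    out = ndimage.gaussian_filter(volume.data.astype(np.float64), sigma=sig_vox, mode="nearest")
    return volume.with_data(out)


def voxel_sigmas(sigma_mm: float, spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    """Physical sigma (mm) expressed in voxels per axis."""
    return tuple(sigma_mm / s for s in spacing)  # type: ignore[return-value]


def per_slice_normalize(
    volume: VolumeGrid, mask: BinaryMask, params: PreprocessParams | None = None
) -> VolumeGrid:
    """Equalize within-mask slice medians across the axial (z) axis.

    Each qualifying slice (>= ``min_slice_mask_voxels`` mask voxels) is
    divided by its within-mask median and multiplied by the global
    within-mask median, so overall scale is preserved; sparse slices are
    left unchanged.
    """
    params = params or PreprocessParams()
    require_same_grid(volume, mask, "volume and mask")
    if not mask.data.any():
        raise ValidationError("mask is empty")
    global_median = float(np.median(volume.data[mask.data]))
    out = volume.data.astype(np.float64).copy()
    for z in range(volume.shape[2]):
        m = mask.data[:, :, z]
        if int(np.count_nonzero(m)) < params.min_slice_mask_voxels:
            continue
        m_z = float(np.median(volume.data[:, :, z][m]))
        if m_z == 0:
            raise DegenerateInputError(f"slice {z}: within-mask median is zero")
        out[:, :, z] *= global_median / m_z
    return volume.with_data(out)


def slice_median_cv(volume: VolumeGrid, mask: BinaryMask, min_voxels: int = 50) -> float:
    """Coefficient of variation of within-mask slice medians (drift measure)."""
    medians = []
    for z in range(volume.shape[2]):
        m = mask.data[:, :, z]
        if int(np.count_nonzero(m)) >= min_voxels:
            medians.append(float(np.median(volume.data[:, :, z][m])))
    if not medians:
        raise ValidationError("no slice has enough mask voxels")
    medians_arr = np.asarray(medians)
    return float(np.std(medians_arr) / np.mean(medians_arr))


def preprocess_volume(
    volume: VolumeGrid, params: PreprocessParams | None = None
) -> tuple[VolumeGrid, BinaryMask]:
    """Full preprocessing chain: body mask -> normalize -> denoise -> per-slice normalize."""
    params = params or PreprocessParams()
    body = compute_body_mask(volume, params)
    vol = normalize_within_mask(volume, body, params)
    vol = gaussian_denoise(vol, params)
    vol = per_slice_normalize(vol, body, params)
    return vol, body
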