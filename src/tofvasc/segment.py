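"""Hybrid thresholding of the fused probability map and 3D skeletonization.

Vessels occupy a tiny fraction of the body volume in 3D angiography, so
segmentation combines an Otsu-derived threshold with a percentile floor:
the stricter of the two governs.  Small components are removed and the
vessel mask is reduced to a one-voxel-wide, topology-preserving skeleton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .errors import DegenerateInputError, ParameterError
from .grids import BinaryMask, VolumeGrid, require_same_grid

#: 26-connectivity structuring element — the package-wide foreground convention
#: for components, skeletons and graphs.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentParams:
    """percentile: floor on the threshold as a within-body order statistic;
    min_component_voxels: components smaller than this are speckle;
    histogram_bins: equal-width bins for the Otsu search."""

    percentile: float = 99.0
    min_component_voxels: int = 27
    histogram_bins: int = 256

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ParameterError("percentile must lie in (0, 100)")
        if self.min_component_voxels < 1:
            raise ParameterError("min_component_voxels must be >= 1")
        if self.histogram_bins < 2:
            raise ParameterError("histogram_bins must be >= 2")


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Bin-edge threshold maximizing between-class variance.

    Values are histogrammed into ``bins`` equal-width bins over
    ``[min, max]``; each interior bin edge is a candidate threshold ``t``
    splitting values into ``< t`` and ``>= t``; the edge maximizing
    ``w0*w1*(mu0-mu1)^2`` is returned, ties broken toward the lowest edge.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateInputError("otsu_threshold requires at least two distinct values")
    counts, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]  # counts strictly below each interior edge
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (csum[-1] + counts[-1] * centers[-1] - csum) / w1
        score = w0 * w1 * (mu0 - mu1) ** 2
    score = np.where((w0 == 0) | (w1 == 0), -np.inf, score)
    best = int(np.argmax(score))  # argmax returns the first (lowest) maximizer
    return float(edges[1 + best])


def hybrid_threshold_segment(
    prob: VolumeGrid, body: BinaryMask, params: SegmentParams | None = None
) -> BinaryMask:
    """Threshold the fused probability map within the body mask.

    The threshold is ``max(otsu, percentile_p)`` of within-body values with
    inclusive ``>=`` comparison, so both criteria must be met.  A constant
    within-body map yields an empty mask with a warning rather than an error.
    """
    params = params or SegmentParams()
    require_same_grid(prob, body, "probability map and body mask")
    inside = prob.data[body.data]
    if inside.size == 0:
        raise DegenerateInputError("body mask is empty")
    if float(inside.min()) == float(inside.max()):
        warnings.warn("probability map is constant within the body mask; returning empty mask")
        return BinaryMask(np.zeros(prob.shape, dtype=bool), prob.spacing, prob.affine)
    t_otsu = otsu_threshold(inside, params.histogram_bins)
    t_pct = float(np.percentile(inside, params.percentile))
    t = max(t_otsu, t_pct)
    out = (prob.data >= t) & body.data
    return BinaryMask(out, prob.spacing, prob.affine)


def remove_small_components(mask: BinaryMask, params: SegmentParams | None = None) -> BinaryMask:
    """Delete 26-connected components with fewer than ``min_component_voxels`` voxels."""
    params = params or SegmentParams()
    labels, n = ndimage.label(mask.data, structure=CONN26)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= params.min_component_voxels
    keep[0] = False
    return mask.with_data(keep[labels])


def skeletonize_volume(mask: BinaryMask) -> BinaryMask:
    """Topology-preserving 3D thinning (Lee's method) of a vessel mask.

    Small, highly symmetric blobs can be eroded away completely by the
    thinning pass; any input component left without a skeleton voxel gets
    back its interior-most voxel (max distance transform, lexicographic
    (z, y, x) tie-break), so every component yields at least one
    skeleton voxel.
    """
    skel = skeletonize(mask.data).astype(bool)
    labels, n = ndimage.label(mask.data, structure=CONN26)
    if n:
        surviving = np.unique(labels[skel])
        lost = set(range(1, n + 1)) - set(int(v) for v in surviving)
        if lost:
            edt = ndimage.distance_transform_edt(mask.data)
            for comp in sorted(lost):
                coords = np.argwhere(labels == comp)
                depth = edt[coords[:, 0], coords[:, 1], coords[:, 2]]
                best = np.flatnonzero(depth == depth.max())
                zyx = coords[best][:, ::-1]
                pick = coords[best[np.lexsort(zyx.T[::-1])[0]]]
                skel[tuple(pick)] = True
    return mask.with_data(skel)
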