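"""Static QA renders: color-coded maximum-intensity projections.

Replaces interactive QA with reproducible images: MIPs of the grayscale
volume along each axis with the branch-level color overlay (trunk red,
first-order green, second-order blue, higher orders magenta, tumor
purple), plus an oblique "angled" projection.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .branches import COLOR_SCHEME, TUMOR_COLOR
from .errors import ValidationError
from .grids import BinaryMask, BranchLabelVolume, VolumeGrid


def _mip_rgb(
    volume: np.ndarray,
    labels: np.ndarray,
    tumor: np.ndarray | None,
    axis: int,
) -> np.ndarray:
    """Grayscale MIP with label overlay projected along ``axis``."""
    lo, hi = float(volume.min()), float(volume.max())
    gray = (volume - lo) / (hi - lo) if hi > lo else np.zeros_like(volume)
    mip = gray.max(axis=axis)
    rgb = np.stack([mip] * 3, axis=-1)
    if tumor is not None and tumor.any():
        t_proj = tumor.max(axis=axis)
        rgb[t_proj] = TUMOR_COLOR
    # project the smallest (most proximal) level present along the ray
    masked = np.where(labels >= 0, labels, np.iinfo(np.int16).max)
    lv_proj = masked.min(axis=axis)
    for lv, color in COLOR_SCHEME.items():
        sel = lv_proj == lv if lv < 3 else (lv_proj >= 3) & (lv_proj < np.iinfo(np.int16).max)
        rgb[sel] = color
    return np.clip(rgb, 0.0, 1.0)


def _oblique(volume: np.ndarray, labels: np.ndarray, tumor: np.ndarray | None) -> np.ndarray:
    """Angled view: 45-degree rotation about y before a z-axis MIP."""
    from scipy.ndimage import rotate

    vol_r = rotate(volume, 45.0, axes=(0, 2), order=1, reshape=True, mode="constant", cval=0.0)
    lab_r = rotate(
        labels.astype(np.int16), 45.0, axes=(0, 2), order=0, reshape=True,
        mode="constant", cval=-1,
    )
    tum_r = None
    if tumor is not None:
        tum_r = (
            rotate(tumor.astype(np.uint8), 45.0, axes=(0, 2), order=0, reshape=True,
                   mode="constant", cval=0) > 0
        )
    return _mip_rgb(vol_r, lab_r, tum_r, axis=2)


def render_views(
    volume: VolumeGrid,
    labels: BranchLabelVolume | None,
    tumor: BinaryMask | None,
    out_prefix: str | Path,
) -> list[Path]:
    """Write top/side/front MIPs plus an angled view as PNGs.

    With ``labels=None`` (or an all-background label volume) the renders
    are plain grayscale MIPs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if labels is not None and labels.shape != volume.shape:
        raise ValidationError("label volume grid does not match the image grid")
    if tumor is not None and tumor.shape != volume.shape:
        raise ValidationError("tumor mask grid does not match the image grid")
    lab = labels.data if labels is not None else np.full(volume.shape, -1, dtype=np.int16)
    tum = tumor.data if tumor is not None else None
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    views = {
        "top": _mip_rgb(volume.data, lab, tum, axis=2),
        "side": _mip_rgb(volume.data, lab, tum, axis=0),
        "front": _mip_rgb(volume.data, lab, tum, axis=1),
        "angled": _oblique(volume.data, lab, tum),
    }
    paths = []
    for name, img in views.items():
        path = out_prefix.parent / f"{out_prefix.name}_{name}.png"
        plt.imsave(path, np.transpose(img, (1, 0, 2)), origin="lower")
        paths.append(path)
    return paths
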