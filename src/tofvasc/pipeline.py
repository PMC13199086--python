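"""End-to-end vessel analysis: preprocess -> enhance -> segment -> label.

``run_pipeline`` executes the whole workflow on one volume, writes every
intermediate artifact (body mask, fused probability map, vessel mask,
skeleton, branch labels, per-component CSV, QA renders) plus a manifest
that fully reconstructs the run's parameterization; it is deterministic
given inputs and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from . import io as vio
from .branches import component_summary, label_branches
from .config import PipelineConfig
from .enhance import fuse_maps, orthogonal_support_maps, vesselness
from .errors import TofVascError
from .grids import BinaryMask, BranchLabelVolume, VolumeGrid
from .preprocess import (
    compute_body_mask,
    gaussian_denoise,
    normalize_within_mask,
    per_slice_normalize,
)
from .render import render_views
from .segment import (
    hybrid_threshold_segment,
    otsu_threshold,
    remove_small_components,
    skeletonize_volume,
)

log = logging.getLogger("tofvasc")


@dataclass
class PipelineResult:
    body_mask: BinaryMask
    fused: VolumeGrid
    vessel_mask: BinaryMask
    skeleton: BinaryMask
    labels: BranchLabelVolume
    manifest: dict


def _digest(path: Path | None) -> str | None:
    if path is None:
        return None
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline_on_volume(
    volume: VolumeGrid,
    config: PipelineConfig | None = None,
    tumor: BinaryMask | None = None,
) -> PipelineResult:
    """Run every stage in memory; raises a stage-tagged error on failure."""
    config = config or PipelineConfig()
    manifest: dict = {
        "software": {"name": "tofvasc", "version": __version__},
        "config": config.to_dict(),
        "stages": {},
        "timing": {},  # wall-clock seconds; excluded from determinism checks
    }
    stage = "body_mask"
    try:
        t0 = time.time()
        body = compute_body_mask(volume, config.preprocess)
        manifest["stages"][stage] = {"voxels": body.n_voxels}
        manifest["timing"][stage] = time.time() - t0
        log.info("body mask: %d voxels", body.n_voxels)

        stage = "preprocess"
        t0 = time.time()
        pre = normalize_within_mask(volume, body, config.preprocess)
        pre = gaussian_denoise(pre, config.preprocess)
        pre = per_slice_normalize(pre, body, config.preprocess)
        manifest["stages"][stage] = {}
        manifest["timing"][stage] = time.time() - t0

        stage = "enhance"
        t0 = time.time()
        vmap = vesselness(pre, body, config.vesselness)
        supports = orthogonal_support_maps(vmap, config.fusion)
        fused = fuse_maps(vmap, supports, config.fusion)
        manifest["stages"][stage] = {"fusion_weights": list(config.fusion.weights)}
        manifest["timing"][stage] = time.time() - t0

        stage = "segment"
        t0 = time.time()
        inside = fused.data[body.data]
        otsu_val = float(otsu_threshold(inside, config.segment.histogram_bins))
        pct_val = float(np.percentile(inside, config.segment.percentile))
        vessel = hybrid_threshold_segment(fused, body, config.segment)
        vessel = remove_small_components(vessel, config.segment)
        skeleton = skeletonize_volume(vessel)
        manifest["timing"][stage] = time.time() - t0
        manifest["stages"][stage] = {
            "otsu_threshold": otsu_val,
            "percentile_threshold": pct_val,
            "threshold_used": max(otsu_val, pct_val),
            "vessel_voxels": vessel.n_voxels,
            "skeleton_voxels": skeleton.n_voxels,
        }
        log.info("vessel mask: %d voxels, skeleton: %d", vessel.n_voxels, skeleton.n_voxels)

        stage = "branches"
        t0 = time.time()
        labels, skel, trunks = label_branches(skeleton)
        level_counts = {
            int(k): int(v)
            for k, v in zip(*np.unique(labels.data[labels.data >= 0], return_counts=True))
        }
        manifest["stages"][stage] = {
            "n_components": len(skel.components),
            "level_voxels": level_counts,
        }
        manifest["timing"][stage] = time.time() - t0
    except TofVascError:
        manifest["FAILED"] = stage
        raise
    result = PipelineResult(body, fused, vessel, skeleton, labels, manifest)
    result.manifest["component_summary"] = component_summary(labels, skel, trunks).to_dict(
        orient="records"
    )
    return result


def run_pipeline(
    input_volume: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    tumor_mask: str | Path | None = None,
) -> Path:
    """File-to-files wrapper: read NIfTI, run all stages, write artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    volume = vio.read_volume(input_volume)
    tumor = None
    if tumor_mask is not None:
        tumor = vio.resample_mask_to_grid(vio.read_mask(tumor_mask), volume)
    try:
        result = run_pipeline_on_volume(volume, config, tumor)
    except TofVascError as exc:
        (outdir / "manifest.json").write_text(
            json.dumps({"FAILED": True, "error": str(exc)}, indent=2)
        )
        raise
    vio.write_volume(result.body_mask, outdir / "body_mask.nii.gz")
    vio.write_volume(result.fused, outdir / "fused_probability.nii.gz")
    vio.write_volume(result.vessel_mask, outdir / "vessel_mask.nii.gz")
    vio.write_volume(result.skeleton, outdir / "skeleton.nii.gz")
    vio.write_volume(result.labels, outdir / "branch_labels.nii.gz")
    import pandas as pd

    pd.DataFrame(result.manifest["component_summary"]).to_csv(
        outdir / "components.csv", index=False
    )
    render_views(volume, result.labels, tumor, outdir / "qa")
    manifest = dict(result.manifest)
    manifest["inputs"] = {
        "volume": str(input_volume),
        "volume_sha256": _digest(Path(input_volume)),
        "tumor_mask": str(tumor_mask) if tumor_mask else None,
        "tumor_mask_sha256": _digest(Path(tumor_mask)) if tumor_mask else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
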