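"""Pipeline orchestration and the phantom benchmark harness.

``run_channel_analysis`` is the in-memory core: it takes one channel's
per-sample tissue volumes through background subtraction, artifact
masking, warping, z-scoring, smoothing, permutation statistics, FDR and
cluster-extent thresholding, back-warped density validation, and regional
composition.  ``run_pipeline`` is the file-based wrapper driven by a
(YAML-able) :class:`PipelineConfig`; ``run_phantom_benchmark`` turns the
whole analysis into a self-validating experiment by scoring recovery of
the phantom's injected effects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .cluster_validate import ValidationReport, validate_all
from .preprocess import (
    apply_keep_mask,
    gaussian_smooth,
    rolling_ball_subtract,
    warp_volume,
    zscore_in_mask,
)
from .regional import CompositionTable, collapse_hierarchy, regional_composition, sunburst_table
from .segment import SegmentationMask, segment_by_threshold
from .volio import (
    AffineTransform,
    AtlasBundle,
    GroupDesign,
    Volume3D,
    read_atlas,
    read_design,
    read_transform,
    read_volume,
    write_volume,
)
from .voxelstats import ClusterSet, VoxelStatMap, extract_clusters, fdr_threshold, permutation_pvalues

logger = logging.getLogger("voxmap")


@dataclasses.dataclass
class ChannelParams:
    """Analysis parameters for one immunolabel channel.

    Defaults follow the published protocol where one exists (q, minimum
    cluster extent, permutation design); the phantom benchmark overrides
    the problem-size parameters (see docs/methods.md).
    """

    channel: str
    direction: str = "group1_greater"
    rolling_ball_radius_px: int = 20
    kernel_um: float = 100.0
    q: float = 0.2
    min_cluster_vox: int = 400
    connectivity: int = 6
    metric: str = "label_density_pct"
    alpha: float = 0.05
    n_perm: int = 18000
    seed: int = 0
    seg_threshold: float = 50.0
    seg_min_vox: int = 5


@dataclasses.dataclass
class PipelineConfig:
    design_path: str
    atlas_labels_path: str
    hierarchy_path: str
    out_dir: str
    channels: list[ChannelParams]
    phantom: ph.PhantomConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        channels = [ChannelParams(**c) for c in raw.pop("channels")]
        phantom_cfg = raw.pop("phantom", None)
        if phantom_cfg is not None:
            phantom_cfg = _phantom_config_from_dict(phantom_cfg)
        return cls(channels=channels, phantom=phantom_cfg, **raw)


def _phantom_config_from_dict(d: dict) -> ph.PhantomConfig:
    d = dict(d)
    d["channels"] = [ph.ChannelSpec(**c) for c in d.get("channels", [])]
    d["effects"] = [ph.Effect(**e) for e in d.get("effects", [])]
    if "background" in d:
        d["background"] = ph.BackgroundSpec(**d["background"])
    if "artifact" in d:
        d["artifact"] = ph.ArtifactSpec(**d["artifact"])
    for key in ("grid_shape", "voxel_size_um", "group_names"):
        if key in d:
            d[key] = tuple(d[key])
    return ph.PhantomConfig(**d)


@dataclasses.dataclass
class ChannelResult:
    stat: VoxelStatMap
    clusters: ClusterSet
    report: ValidationReport
    composition: CompositionTable | None
    p_threshold: float


def run_channel_analysis(
    volumes: Mapping[str, Volume3D],
    brain_masks: Mapping[str, Volume3D],
    artifact_masks: Mapping[str, Volume3D | None],
    transforms: Mapping[str, AffineTransform],
    design: GroupDesign,
    atlas: AtlasBundle,
    params: ChannelParams,
    segmentations: Mapping[str, SegmentationMask] | None = None,
    restriction_masks: Mapping[str, Volume3D] | None = None,
) -> ChannelResult:
    """Full single-channel analysis on in-memory volumes.

    ``volumes`` maps sample_id to the channel's tissue-space volume.  If
    ``segmentations`` is None, the internal threshold segmenter is applied
    to the background-subtracted, artifact-masked tissue image.
    """
    atlas_shape = tuple(atlas.labels.shape)
    sample_ids = [str(s) for s in design.table["sample_id"]]
    atlas_stack: dict[str, Volume3D] = {}
    warped_brain: dict[str, np.ndarray] = {}
    seg: dict[str, SegmentationMask] = {}
    tissue_grids: dict[str, tuple] = {}

    for sid in sample_ids:
        t0 = time.perf_counter()
        vol = volumes[sid]
        tissue_grids[sid] = (tuple(vol.shape), tuple(vol.spacing_um))
        sub = rolling_ball_subtract(vol, params.rolling_ball_radius_px)
        keep = np.asarray(brain_masks[sid].values).astype(bool)
        art = artifact_masks.get(sid)
        if art is not None:
            keep = keep & ~np.asarray(art.values).astype(bool)
        masked = apply_keep_mask(sub, vol.like(keep))
        if segmentations is None:
            seg[sid] = segment_by_threshold(masked, params.seg_threshold, params.seg_min_vox)
        warped = warp_volume(
            masked, transforms[sid], atlas_shape, atlas.spacing_um, interpolation="linear"
        )
        bm = warp_volume(
            brain_masks[sid].like(np.asarray(brain_masks[sid].values).astype(np.uint8)),
            transforms[sid], atlas_shape, atlas.spacing_um, interpolation="nearest",
        )
        bm_bool = np.asarray(bm.values) > 0
        z = zscore_in_mask(warped, warped.like(bm_bool))
        smooth = gaussian_smooth(z, params.kernel_um)
        atlas_stack[sid] = smooth
        warped_brain[sid] = bm_bool
        logger.info("preprocess sample=%s channel=%s dt=%.2fs", sid, params.channel, time.perf_counter() - t0)

    if segmentations is not None:
        seg = dict(segmentations)

    common = np.logical_and.reduce([warped_brain[s] for s in sample_ids])
    mask_vol = Volume3D(common, atlas.spacing_um, space="atlas")
    stat = permutation_pvalues(
        [atlas_stack[s] for s in sample_ids],
        design,
        params.direction,
        params.n_perm,
        params.seed,
        mask_vol,
        sample_order=sample_ids,
    )
    p_thr, significant, _ = fdr_threshold(stat, params.q)
    clusters = extract_clusters(
        significant,
        params.min_cluster_vox,
        connectivity=params.connectivity,
        direction=params.direction,
        t_map=stat.t_map,
        q=params.q,
        p_threshold=p_thr,
    )
    report = validate_all(
        clusters, seg, transforms, tissue_grids, design,
        metric=params.metric, alpha=params.alpha, restriction_masks=restriction_masks,
    )
    composition = None
    valid_ids = report.valid_cluster_ids
    if valid_ids:
        comp = regional_composition(clusters.union_mask(valid_ids), atlas, cluster_ids=valid_ids)
        composition = collapse_hierarchy(comp, atlas)
    return ChannelResult(stat, clusters, report, composition, p_thr)


# ---------------------------------------------------------------------------
# File-based pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, ChannelResult]:
    """Run every configured channel from files and write all stage outputs.

    Outputs per channel: t/p/p_adj/cluster-label NIfTI volumes, cluster CSV,
    validation CSV and (if any cluster is valid) composition and sunburst
    CSVs, plus a manifest recording parameters, seeds and output hashes.
    Rerunning with an identical config reproduces every output byte-for-byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = read_design(config.design_path)
    atlas = read_atlas(config.atlas_labels_path, config.hierarchy_path)
    sample_ids = [str(s) for s in design.table["sample_id"]]

    results: dict[str, ChannelResult] = {}
    manifest: dict = {
        "channels": {},
        "design": str(config.design_path),
        "atlas": str(config.atlas_labels_path),
    }
    for params in config.channels:
        volumes, brain_masks, artifact_masks, transforms = {}, {}, {}, {}
        for sid in sample_ids:
            row = design.row(sid)
            try:
                volumes[sid] = read_volume(str(row[f"vol_{params.channel}"]), sample_id=sid)
                brain_masks[sid] = read_volume(str(row["brain_mask"]))
                transforms[sid] = read_transform(str(row["transform"]))
            except (KeyError, FileNotFoundError) as exc:
                raise RuntimeError(
                    f"stage=load sample={sid} channel={params.channel}: {exc}"
                ) from exc
            art = row.get("artifact_mask", None)
            artifact_masks[sid] = read_volume(str(art)) if isinstance(art, str) and art else None
        res = run_channel_analysis(
            volumes, brain_masks, artifact_masks, transforms, design, atlas, params
        )
        results[params.channel] = res

        prefix = out / params.channel
        write_volume(res.stat.t_map, f"{prefix}_tmap.nii")
        write_volume(res.stat.p_map, f"{prefix}_pmap.nii")
        write_volume(res.stat.p_adj_map, f"{prefix}_padj.nii")
        write_volume(res.clusters.labels, f"{prefix}_clusters.nii")
        res.clusters.records.to_csv(f"{prefix}_clusters.csv", index=False)
        res.report.to_frame().to_csv(f"{prefix}_validation.csv", index=False)
        if res.composition is not None:
            res.composition.table.to_csv(f"{prefix}_composition.csv", index=False)
            sunburst_table(res.composition, atlas).to_csv(f"{prefix}_sunburst.csv", index=False)
        manifest["channels"][params.channel] = {
            "params": dataclasses.asdict(params),
            "p_threshold": res.p_threshold,
            "n_perm_used": res.stat.n_perm,
            "exhaustive": res.stat.exhaustive,
            "outputs": {
                p.name: _sha256(p) for p in sorted(out.glob(f"{params.channel}_*")) if p.is_file()
            },
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results


# ---------------------------------------------------------------------------
# Phantom benchmark harness


@dataclasses.dataclass
class RecoveryMetrics:
    """Recovery of injected phantom effects by the full pipeline."""

    n_runs: int
    null_false_positive_rate: float  # fraction of runs with any valid cluster
    effect_sensitivity: float  # fraction of (run, effect region) pairs hit
    mean_overlap: float  # mean covered fraction of effect regions, hits and misses
    runs_with_any_valid: int
    top_region_hits: int  # runs where the largest valid cluster's top
    # composition region is a true effect region or its parent
    per_run: list[dict]


def _effect_direction(effect: ph.Effect, group_names: tuple[str, str]) -> str:
    # group 1 of the contrast is the lexicographically first label (the
    # GroupDesign convention), independent of design row order
    increase = effect.multiplier > 1.0
    affected_is_g1 = effect.group == min(group_names)
    if increase == affected_is_g1:
        return "group1_greater"
    return "group2_greater"


def run_phantom_benchmark(
    phantom_config: ph.PhantomConfig,
    atlas: AtlasBundle,
    params: ChannelParams,
    n_runs: int,
    overlap_fraction: float = 0.1,
) -> RecoveryMetrics:
    """Generate seeded cohorts, run the pipeline, score against ground truth.

    An effect region counts as *hit* in a run when a valid cluster with the
    effect's expected direction covers more than ``overlap_fraction`` of the
    region's volume.  With no configured effects the metric of interest is
    the null false-positive rate (runs with any valid cluster).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    effects = [e for e in phantom_config.effects if e.multiplier != 1.0]
    per_run = []
    hits = 0
    overlaps: list[float] = []
    any_valid = 0
    for r in range(n_runs):
        cfg = dataclasses.replace(phantom_config, master_seed=phantom_config.master_seed + 1000 * r)
        design, volumes, truth = ph.simulate_cohort(cfg, atlas)
        sample_ids = [str(s) for s in design.table["sample_id"]]
        chan_vols = {sid: volumes[sid][params.channel] for sid in sample_ids}
        brain_masks = {
            sid: Volume3D(atlas.labels > 0, cfg.voxel_size_um) for sid in sample_ids
        }
        artifact_masks = {
            sid: Volume3D(truth.artifact_masks[sid].astype(np.uint8), cfg.voxel_size_um)
            for sid in sample_ids
        }
        transforms = {sid: AffineTransform.identity() for sid in sample_ids}
        res = run_channel_analysis(
            chan_vols, brain_masks, artifact_masks, transforms, design, atlas, params
        )
        valid_ids = res.report.valid_cluster_ids
        if valid_ids:
            any_valid += 1
        run_rec = {"run": r, "n_valid_clusters": len(valid_ids), "region_hits": {}}
        for e in effects:
            direction = _effect_direction(e, cfg.group_names)
            region = atlas.labels == int(e.region_id)
            region_n = int(region.sum())
            ids_dir = [
                int(row.cluster_id)
                for row in res.clusters.records.itertuples()
                if row.cluster_id in valid_ids and row.direction == direction
            ]
            cov = 0.0
            if ids_dir:
                union = np.asarray(res.clusters.union_mask(ids_dir).values)
                cov = float((union & region).sum() / region_n)
            overlaps.append(cov)
            hit = cov > overlap_fraction
            hits += hit
            run_rec["region_hits"][int(e.region_id)] = {"overlap": cov, "hit": bool(hit)}
        if valid_ids:
            largest_valid = min(
                valid_ids,
                key=lambda c: -int(
                    res.clusters.records.loc[res.clusters.records["cluster_id"] == c, "n_voxels"].iloc[0]
                ),
            )
            comp = regional_composition(res.clusters.mask(largest_valid), atlas)
            run_rec["top_region_largest"] = int(comp.table.iloc[0]["region_id"])
        if res.composition is not None and len(res.composition.table):
            run_rec["top_region"] = int(res.composition.table.iloc[0]["region_id"])
        per_run.append(run_rec)
    n_pairs = n_runs * len(effects)
    effect_targets = {int(e.region_id) for e in effects}
    effect_targets |= {p for r in list(effect_targets) if (p := atlas.parent_of(r)) is not None}
    top_hits = sum(
        1 for rec in per_run if rec.get("top_region_largest") in effect_targets
    )
    return RecoveryMetrics(
        n_runs=n_runs,
        null_false_positive_rate=any_valid / n_runs,
        effect_sensitivity=(hits / n_pairs) if n_pairs else float("nan"),
        mean_overlap=(float(np.mean(overlaps)) if overlaps else float("nan")),
        runs_with_any_valid=any_valid,
        top_region_hits=top_hits,
        per_run=per_run,
    )
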