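"""Back-warped cluster validation.

Significant clusters found in atlas space are warped back to each sample's
full-resolution tissue grid, where a direct density measurement decides
whether the voxel-wise difference reflects a real difference in label:

* label density = 100 * (segmented voxels inside cluster) / (cluster voxels)
* cell density  = 6-connected components of (cells inside cluster) per mm^3

A cluster is valid if an unpaired one-tailed t-test on the per-sample
densities is significant in the direction inherited from the voxel-wise
contrast that produced the cluster.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sstats

from .preprocess import SpatialError, warp_volume
from .segment import SegmentationMask
from .volio import AffineTransform, GroupDesign, Volume3D
from .voxelstats import ClusterSet

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)

METRICS = ("label_density_pct", "cell_density_per_mm3")


class UndefinedDensityError(ValueError):
    """Density requested over an empty cluster."""


@dataclasses.dataclass
class ValidationRecord:
    cluster_id: int
    metric: str
    per_sample: dict[str, float]
    group_means: dict[str, float]
    t: float
    p_one_tailed: float
    alpha: float
    valid: bool
    direction: str


@dataclasses.dataclass
class ValidationReport:
    records: list[ValidationRecord]
    metric: str
    alpha: float

    @property
    def valid_cluster_ids(self) -> list[int]:
        return [r.cluster_id for r in self.records if r.valid]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "cluster_id": r.cluster_id,
                "metric": r.metric,
                "t": r.t,
                "p_one_tailed": r.p_one_tailed,
                "alpha": r.alpha,
                "valid": r.valid,
                "direction": r.direction,
            }
            row.update({f"mean_{g}": v for g, v in r.group_means.items()})
            row.update({f"sample_{s}": v for s, v in r.per_sample.items()})
            rows.append(row)
        cols = ["cluster_id", "metric", "t", "p_one_tailed", "alpha", "valid", "direction"]
        return pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)


def warp_cluster_to_tissue(
    cluster_mask: Volume3D,
    t: AffineTransform,
    target_shape: tuple[int, int, int],
    target_spacing_um: tuple[float, float, float],
) -> Volume3D:
    """Nearest-neighbour pull-back of an atlas-space cluster mask to tissue.

    ``t`` is the tissue->atlas transform of the sample; the pull-back uses
    its inverse so each tissue voxel looks up its atlas-space label.
    """
    src = cluster_mask.like(np.asarray(cluster_mask.values).astype(np.uint8))
    out = warp_volume(
        src, t.inverse(), tuple(target_shape), tuple(target_spacing_um),
        interpolation="nearest", target_space="tissue",
    )
    return out.like(np.asarray(out.values).astype(bool))


def label_density(seg: SegmentationMask, cluster: Volume3D) -> float:
    """Percent of cluster voxels occupied by segmented label."""
    if seg.mask.shape != cluster.shape:
        raise SpatialError(f"segmentation grid {seg.mask.shape} != cluster grid {cluster.shape}")
    cl = np.asarray(cluster.values).astype(bool)
    total = int(cl.sum())
    if total == 0:
        raise UndefinedDensityError("label density over an empty cluster is undefined")
    inside = int((np.asarray(seg.mask.values) & cl).sum())
    return 100.0 * inside / total


def cell_count(cells: SegmentationMask, cluster: Volume3D) -> int:
    """Number of 6-connected cell components intersected with the cluster."""
    if cells.mask.shape != cluster.shape:
        raise SpatialError(f"cell grid {cells.mask.shape} != cluster grid {cluster.shape}")
    cl = np.asarray(cluster.values).astype(bool)
    _, n = ndimage.label(np.asarray(cells.mask.values) & cl, structure=_STRUCT_6)
    return int(n)


def cell_density(cells: SegmentationMask, cluster: Volume3D) -> float:
    """6-connected cell components per mm^3 of cluster volume."""
    cl = np.asarray(cluster.values).astype(bool)
    total = int(cl.sum())
    if total == 0:
        raise UndefinedDensityError("cell density over an empty cluster is undefined")
    vol_mm3 = total * cluster.voxel_volume_mm3
    return cell_count(cells, cluster) / vol_mm3


def one_tailed_t(
    values_g1: Sequence[float],
    values_g2: Sequence[float],
    direction: str = "group1_greater",
) -> tuple[float, float]:
    """Pooled-variance two-sample t and one-tailed p in the stated direction.

    Degenerate cases: zero pooled variance with equal means gives (0, 1);
    zero pooled variance with a difference gives p=0 when the difference is
    in the tested direction and p=1 otherwise.
    """
    x1 = np.asarray(values_g1, dtype=float)
    x2 = np.asarray(values_g2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need >= 2 values per group")
    n1, n2 = len(x1), len(x2)
    diff = x1.mean() - x2.mean()
    if direction == "group2_greater":
        diff = -diff
    sp2 = (((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()) / (n1 + n2 - 2)
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return (np.inf if diff > 0 else -np.inf), (0.0 if diff > 0 else 1.0)
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(sstats.t.sf(t, df=n1 + n2 - 2))
    return float(t), p


def validate_cluster(
    values_g1: Mapping[str, float],
    values_g2: Mapping[str, float],
    direction: str,
    alpha: float,
    cluster_id: int = 0,
    metric: str = "label_density_pct",
    group_names: tuple[str, str] = ("group1", "group2"),
) -> ValidationRecord:
    """One-tailed unpaired t-test on per-sample densities; valid iff p < alpha."""
    g1 = [float(v) for v in values_g1.values()]
    g2 = [float(v) for v in values_g2.values()]
    t, p = one_tailed_t(g1, g2, direction)
    per_sample = {**{str(k): float(v) for k, v in values_g1.items()},
                  **{str(k): float(v) for k, v in values_g2.items()}}
    return ValidationRecord(
        cluster_id=cluster_id,
        metric=metric,
        per_sample=per_sample,
        group_means={group_names[0]: float(np.mean(g1)), group_names[1]: float(np.mean(g2))},
        t=t,
        p_one_tailed=p,
        alpha=alpha,
        valid=bool(p < alpha),
        direction=direction,
    )


def validate_all(
    clusters: ClusterSet,
    segmentations: Mapping[str, SegmentationMask],
    transforms: Mapping[str, AffineTransform],
    tissue_grids: Mapping[str, tuple[tuple[int, int, int], tuple[float, float, float]]],
    design: GroupDesign,
    metric: str = "label_density_pct",
    alpha: float = 0.05,
    restriction_masks: Mapping[str, Volume3D] | None = None,
) -> ValidationReport:
    """Validate every extracted cluster against per-sample densities.

    ``segmentations``, ``transforms`` and ``tissue_grids`` map sample_id to
    that sample's artifacts; ``tissue_grids`` gives (shape, spacing_um) of
    the native grid.  ``restriction_masks`` optionally limits cell counting
    to designated tissue-space regions per sample (e.g. regions containing
    catecholaminergic neurons); cluster volume still uses the full cluster.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    g1_name, g2_name = design.groups
    if len(clusters.records) == 0:
        return ValidationReport(records=[], metric=metric, alpha=alpha)
    sample_ids = [str(s) for s in design.table["sample_id"]]
    for s in sample_ids:
        if s not in segmentations:
            raise KeyError(f"no segmentation bound for sample {s!r}")
        if s not in transforms:
            raise KeyError(f"no transform bound for sample {s!r}")
        if s not in tissue_grids:
            raise KeyError(f"no tissue grid bound for sample {s!r}")

    records: list[ValidationRecord] = []
    for row in clusters.records.itertuples():
        cid = int(row.cluster_id)
        direction = str(row.direction)
        atlas_mask = clusters.mask(cid)
        dens: dict[str, float] = {}
        for s in sample_ids:
            shape, spacing = tissue_grids[s]
            tissue_mask = warp_cluster_to_tissue(atlas_mask, transforms[s], shape, spacing)
            if metric == "label_density_pct":
                dens[s] = label_density(segmentations[s], tissue_mask)
            else:
                counting_mask = tissue_mask
                if restriction_masks is not None and s in restriction_masks:
                    restricted = np.asarray(tissue_mask.values) & np.asarray(
                        restriction_masks[s].values
                    ).astype(bool)
                    counting_mask = tissue_mask.like(restricted)
                total = int(np.asarray(tissue_mask.values).sum())
                if total == 0:
                    raise UndefinedDensityError(
                        f"cluster {cid} maps to an empty tissue mask for sample {s!r}"
                    )
                n_cells = cell_count(segmentations[s], counting_mask)
                dens[s] = n_cells / (total * tissue_mask.voxel_volume_mm3)
        g1_vals = {s: dens[s] for s in design.samples(g1_name)}
        g2_vals = {s: dens[s] for s in design.samples(g2_name)}
        records.append(
            validate_cluster(
                g1_vals, g2_vals, direction, alpha,
                cluster_id=cid, metric=metric, group_names=(g1_name, g2_name),
            )
        )
    return ValidationReport(records=records, metric=metric, alpha=alpha)
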