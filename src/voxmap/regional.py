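"""Regional composition of valid clusters with hierarchical collapse.

A valid-cluster mask is intersected with the atlas label volume to tally
per-leaf-region voxel counts; voxels on atlas label 0 go to an "undefined"
row.  The reporting rule: if the top-k (default 4) largest regions jointly
exceed the dominance fraction (default 80%) of the total cluster volume,
report as-is; otherwise merge every region one level up into its parent and
re-test, recursing until the condition holds or only roots remain.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SpatialError
from .volio import AtlasBundle, Volume3D

UNDEFINED_ID = 0

_COLUMNS = ["region_id", "abbreviation", "parent_id", "voxel_count", "volume_mm3", "fraction"]


@dataclasses.dataclass
class CompositionTable:
    table: pd.DataFrame  # columns: _COLUMNS
    cluster_ids: list[int]
    collapse_applied: bool = False

    def __post_init__(self) -> None:
        t = self.table
        missing = set(_COLUMNS) - set(t.columns)
        if missing:
            raise ValueError(f"composition table missing columns {sorted(missing)}")
        if len(t) and abs(t["fraction"].sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {t['fraction'].sum()}")

    @property
    def total_volume_mm3(self) -> float:
        return float(self.table["volume_mm3"].sum())


def regional_composition(
    valid_mask: Volume3D, atlas: AtlasBundle, cluster_ids: list[int] | None = None
) -> CompositionTable:
    """Tally mask voxels per leaf atlas region (label 0 -> 'undefined' row)."""
    if tuple(valid_mask.shape) != tuple(atlas.labels.shape):
        raise SpatialError(
            f"mask grid {valid_mask.shape} != atlas grid {atlas.labels.shape}"
        )
    m = np.asarray(valid_mask.values).astype(bool)
    voxel_mm3 = valid_mask.voxel_volume_mm3
    labels = atlas.labels[m]
    if labels.size == 0:
        return CompositionTable(pd.DataFrame(columns=_COLUMNS), cluster_ids or [])
    counts = np.bincount(labels)
    abbrev = dict(zip(atlas.hierarchy["region_id"].astype(int), atlas.hierarchy["abbreviation"]))
    total = labels.size
    rows = []
    for rid in np.flatnonzero(counts):
        rid = int(rid)
        c = int(counts[rid])
        rows.append(
            {
                "region_id": rid,
                "abbreviation": abbrev.get(rid, "undefined") if rid != UNDEFINED_ID else "undefined",
                "parent_id": atlas.parent_of(rid) if rid != UNDEFINED_ID else None,
                "voxel_count": c,
                "volume_mm3": c * voxel_mm3,
                "fraction": c / total,
            }
        )
    table = pd.DataFrame(rows).sort_values("voxel_count", ascending=False, kind="stable")
    return CompositionTable(table.reset_index(drop=True), cluster_ids or [])


def _dominance_holds(table: pd.DataFrame, top_k: int, dominance_fraction: float) -> bool:
    if len(table) == 0:
        return True
    top = table["fraction"].nlargest(top_k).sum()
    return bool(top > dominance_fraction)


def collapse_hierarchy(
    comp: CompositionTable,
    atlas: AtlasBundle,
    top_k: int = 4,
    dominance_fraction: float = 0.8,
) -> CompositionTable:
    """Apply the top-k / dominance reporting rule, collapsing level by level.

    Each collapse step merges every region into its immediate parent (roots
    and the undefined row stay put) and the dominance condition is re-tested;
    the recursion stops when it holds or nothing can merge further.  Total
    volume is conserved exactly at every level.
    """
    table = comp.table.copy()
    collapsed = False
    abbrev = dict(zip(atlas.hierarchy["region_id"].astype(int), atlas.hierarchy["abbreviation"]))
    while not _dominance_holds(table, top_k, dominance_fraction):
        new_ids = []
        for rid in table["region_id"]:
            rid = int(rid)
            parent = atlas.parent_of(rid) if rid != UNDEFINED_ID else None
            new_ids.append(parent if parent is not None else rid)
        if [int(r) for r in table["region_id"]] == new_ids:
            break  # all at roots; cannot merge further
        table = table.assign(region_id=new_ids)
        table = (
            table.groupby("region_id", as_index=False)
            .agg(voxel_count=("voxel_count", "sum"), volume_mm3=("volume_mm3", "sum"), fraction=("fraction", "sum"))
        )
        table["abbreviation"] = [
            abbrev.get(int(r), "undefined") if int(r) != UNDEFINED_ID else "undefined"
            for r in table["region_id"]
        ]
        table["parent_id"] = [
            atlas.parent_of(int(r)) if int(r) != UNDEFINED_ID else None for r in table["region_id"]
        ]
        table = table[_COLUMNS].sort_values("voxel_count", ascending=False, kind="stable").reset_index(drop=True)
        collapsed = True
    return CompositionTable(table, comp.cluster_ids, collapse_applied=collapsed)


def _ancestor_path(atlas: AtlasBundle, region_id: int) -> list[str]:
    if region_id == UNDEFINED_ID:
        return ["undefined"]
    abbrev = dict(zip(atlas.hierarchy["region_id"].astype(int), atlas.hierarchy["abbreviation"]))
    path = [abbrev.get(region_id, str(region_id))]
    cur = region_id
    while True:
        p = atlas.parent_of(cur)
        if p is None:
            break
        path.append(abbrev.get(p, str(p)))
        cur = p
    return list(reversed(path))


def sunburst_table(comp: CompositionTable, atlas: AtlasBundle) -> pd.DataFrame:
    """Plot-ready hierarchical table: one row per reported node with its
    root-to-node ancestor path, region id, volume and fraction."""
    rows = []
    for r in comp.table.itertuples():
        rows.append(
            {
                "path": "/".join(_ancestor_path(atlas, int(r.region_id))),
                "region_id": int(r.region_id),
                "abbreviation": r.abbreviation,
                "voxel_count": int(r.voxel_count),
                "volume_mm3": float(r.volume_mm3),
                "fraction": float(r.fraction),
            }
        )
    return pd.DataFrame(
        rows, columns=["path", "region_id", "abbreviation", "voxel_count", "volume_mm3", "fraction"]
    )


def write_sunburst(comp: CompositionTable, atlas: AtlasBundle, path: str | Path) -> None:
    sunburst_table(comp, atlas).to_csv(path, index=False)


def read_sunburst(path: str | Path, atlas: AtlasBundle, cluster_ids: list[int] | None = None) -> CompositionTable:
    """Reconstruct a CompositionTable from an emitted sunburst CSV."""
    df = pd.read_csv(path)
    table = pd.DataFrame(
        {
            "region_id": df["region_id"].astype(int),
            "abbreviation": df["abbreviation"],
            "parent_id": [
                atlas.parent_of(int(r)) if int(r) != UNDEFINED_ID else None for r in df["region_id"]
            ],
            "voxel_count": df["voxel_count"].astype(int),
            "volume_mm3": df["volume_mm3"].astype(float),
            "fraction": df["fraction"].astype(float),
        }
    )
    return CompositionTable(table, cluster_ids or [])
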