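"""Atlas-space voxel-wise two-group inference.

Per-voxel pooled-variance Student t statistics, one-sided permutation
p-values obtained by relabelling samples, Benjamini-Hochberg FDR
thresholding over in-mask voxels, and connected-component cluster
extraction with an extent threshold.

Permutation conventions:

* The null is built by permuting group labels across samples.  When the
  number of distinct label assignments C(n, n1) is no larger than the
  requested permutation count, all assignments are enumerated and the
  p-value is the exact proportion (including the identity assignment)
  with permuted t >= observed t.  Otherwise ``n_perm`` random assignments
  are drawn and p = (1 + #{t_perm >= t_obs}) / (n_perm + 1), which never
  returns 0.
* Tests are one-sided per direction; the decrease contrast is run as a
  separate analysis with the sign flipped.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .volio import GroupDesign, Volume3D

DIRECTIONS = ("group1_greater", "group2_greater")


class DesignError(ValueError):
    pass


@dataclasses.dataclass
class VoxelStatMap:
    t_map: Volume3D
    p_map: Volume3D
    p_adj_map: Volume3D | None
    analysis_mask: Volume3D
    direction: str
    n_perm: int
    seed: int
    exhaustive: bool = False


@dataclasses.dataclass
class ClusterSet:
    """Labelled significant-voxel clusters in atlas space.

    ``labels`` is 0 where no cluster; cluster ids are contiguous from 1,
    ordered by descending voxel count.  ``records`` has one row per cluster:
    cluster_id, n_voxels, volume_mm3, direction, peak_abs_t.
    """

    labels: Volume3D
    records: pd.DataFrame
    q: float | None = None
    p_threshold: float | None = None
    min_size_vox: int = 1
    connectivity: int = 6

    @property
    def cluster_ids(self) -> list[int]:
        return [int(c) for c in self.records["cluster_id"]]

    def mask(self, cluster_id: int) -> Volume3D:
        return self.labels.like(np.asarray(self.labels.values) == cluster_id)

    def union_mask(self, cluster_ids: Sequence[int] | None = None) -> Volume3D:
        lab = np.asarray(self.labels.values)
        if cluster_ids is None:
            return self.labels.like(lab > 0)
        return self.labels.like(np.isin(lab, list(cluster_ids)))


def _stack_to_matrix(stack: Sequence[Volume3D], mask: np.ndarray) -> np.ndarray:
    """(n_samples, n_mask_voxels) float64 matrix of in-mask values."""
    return np.stack([np.asarray(v.values, dtype=np.float64)[mask] for v in stack])


def _pooled_t(x: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t along axis 0; zero pooled variance -> t=0."""
    n1, n2 = len(g1), len(g2)
    x1, x2 = x[g1], x[g2]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    ss1 = ((x1 - m1) ** 2).sum(axis=0)
    ss2 = ((x2 - m2) ** 2).sum(axis=0)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, 0.0)


def voxelwise_t(
    stack_g1: Sequence[Volume3D],
    stack_g2: Sequence[Volume3D],
    mask: Volume3D,
) -> Volume3D:
    """Per-voxel two-sample Student t map (positive = group 1 mean higher)."""
    if len(stack_g1) < 2 or len(stack_g2) < 2:
        raise DesignError("need >= 2 samples per group")
    shape = mask.shape
    for v in list(stack_g1) + list(stack_g2):
        if v.shape != shape:
            raise DesignError(f"sample grid {v.shape} != mask grid {shape}")
    m = np.asarray(mask.values).astype(bool)
    x = _stack_to_matrix(list(stack_g1) + list(stack_g2), m)
    n1 = len(stack_g1)
    idx = np.arange(x.shape[0])
    t = _pooled_t(x, idx[:n1], idx[n1:])
    out = np.zeros(shape, dtype=np.float64)
    out[m] = t
    return mask.like(out)


def _assignments(n: int, n1: int, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    """Group-1 index sets for the null: exhaustive if feasible, else sampled.

    Returns (assignments[M, n1], exhaustive_flag); row 0 is the identity
    assignment in the exhaustive case.
    """
    total = math.comb(n, n1)
    if total <= n_perm:
        combos = np.array(list(itertools.combinations(range(n), n1)), dtype=np.int64)
        # move the identity assignment first (cosmetic; p is order-free)
        ident = np.arange(n1)
        pos = np.flatnonzero((combos == ident).all(axis=1))[0]
        combos[[0, pos]] = combos[[pos, 0]]
        return combos, True
    rng = np.random.default_rng(seed)
    draws = np.empty((n_perm, n1), dtype=np.int64)
    for i in range(n_perm):
        draws[i] = rng.choice(n, size=n1, replace=False)
    return draws, False


def permutation_pvalues(
    stacks: Sequence[Volume3D],
    design: GroupDesign,
    direction: str,
    n_perm: int,
    seed: int,
    mask: Volume3D,
    sample_order: Sequence[str] | None = None,
) -> VoxelStatMap:
    """One-sided permutation p-values for a two-group voxel-wise contrast.

    ``stacks`` must be ordered as ``sample_order`` (default: the design
    table's row order).  Group 1 is the design's first group.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    order = list(sample_order) if sample_order is not None else [
        str(s) for s in design.table["sample_id"]
    ]
    if len(stacks) != len(order):
        raise DesignError("one volume per design sample required")
    g1_name, _ = design.groups
    group_of = {str(r.sample_id): str(r.group) for r in design.table.itertuples()}
    is_g1 = np.array([group_of[s] == g1_name for s in order])
    n, n1 = len(order), int(is_g1.sum())
    if n1 < 2 or n - n1 < 2:
        raise DesignError("need >= 2 samples per group")

    m = np.asarray(mask.values).astype(bool)
    x = _stack_to_matrix(stacks, m)
    # reorder so samples 0..n1-1 are group 1: identity assignment = arange(n1)
    x = np.concatenate([x[is_g1], x[~is_g1]], axis=0)
    sign = 1.0 if direction == "group1_greater" else -1.0

    idx_all = np.arange(n)
    t_obs = sign * _pooled_t(x, idx_all[:n1], idx_all[n1:])

    assignments, exhaustive = _assignments(n, n1, n_perm, seed)
    count_ge = np.zeros(x.shape[1], dtype=np.int64)
    full = set(range(n))
    for row in assignments:
        g1 = row
        g2 = np.fromiter(full.difference(row.tolist()), dtype=np.int64, count=n - n1)
        t_perm = sign * _pooled_t(x, g1, g2)
        count_ge += t_perm >= t_obs
    if exhaustive:
        p = count_ge / len(assignments)
    else:
        p = (1.0 + count_ge) / (n_perm + 1.0)

    shape = mask.shape
    t_vol = np.zeros(shape)
    p_vol = np.ones(shape)
    t_vol[m] = t_obs
    p_vol[m] = p
    return VoxelStatMap(
        t_map=mask.like(t_vol),
        p_map=mask.like(p_vol),
        p_adj_map=None,
        analysis_mask=mask.like(m),
        direction=direction,
        n_perm=len(assignments) if exhaustive else n_perm,
        seed=seed,
        exhaustive=exhaustive,
    )


def fdr_threshold(stat: VoxelStatMap, q: float) -> tuple[float, Volume3D, Volume3D]:
    """Benjamini-Hochberg step-up over in-mask voxels.

    Returns (largest raw-p cutoff satisfying the BH condition at level q,
    or 0.0 if none; boolean significance volume; step-up adjusted-p volume).
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0,1), got {q}")
    m = np.asarray(stat.analysis_mask.values).astype(bool)
    if not m.any():
        raise ValueError("empty analysis mask")
    p = np.asarray(stat.p_map.values, dtype=np.float64)[m]
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    cutoff = float(p[reject].max()) if reject.any() else 0.0
    sig = np.zeros(stat.p_map.shape, dtype=bool)
    sig[m] = reject
    adj = np.ones(stat.p_map.shape, dtype=np.float64)
    adj[m] = p_adj
    stat.p_adj_map = stat.p_map.like(adj)
    return cutoff, stat.p_map.like(sig), stat.p_adj_map


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def extract_clusters(
    significant: Volume3D,
    min_size_vox: int,
    connectivity: int = 6,
    direction: str = "group1_greater",
    t_map: Volume3D | None = None,
    q: float | None = None,
    p_threshold: float | None = None,
) -> ClusterSet:
    """Connected components of the significance mask, extent-thresholded.

    Components smaller than ``min_size_vox`` are discarded; survivors are
    relabelled 1..K by descending voxel count (ties broken by original
    scan-order label for determinism).
    """
    if min_size_vox < 1:
        raise ValueError(f"min_size_vox must be >= 1, got {min_size_vox}")
    sig = np.asarray(significant.values).astype(bool)
    lab, n = ndimage.label(sig, structure=_structure(connectivity))
    voxel_mm3 = significant.voxel_volume_mm3
    records = []
    out = np.zeros_like(lab, dtype=np.int32)
    if n > 0:
        sizes = np.bincount(lab.ravel())[1:]  # size of original label k at index k-1
        keep = np.flatnonzero(sizes >= min_size_vox) + 1
        order = keep[np.argsort(-sizes[keep - 1], kind="stable")]
        tvals = np.asarray(t_map.values) if t_map is not None else None
        for new_id, old in enumerate(order, start=1):
            sel = lab == old
            out[sel] = new_id
            records.append(
                {
                    "cluster_id": new_id,
                    "n_voxels": int(sizes[old - 1]),
                    "volume_mm3": float(sizes[old - 1] * voxel_mm3),
                    "direction": direction,
                    "peak_abs_t": float(np.abs(tvals[sel]).max()) if tvals is not None else np.nan,
                }
            )
    rec = pd.DataFrame(
        records,
        columns=["cluster_id", "n_voxels", "volume_mm3", "direction", "peak_abs_t"],
    )
    return ClusterSet(
        labels=significant.like(out),
        records=rec,
        q=q,
        p_threshold=p_threshold,
        min_size_vox=min_size_vox,
        connectivity=connectivity,
    )
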