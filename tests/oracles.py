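"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the package's own code paths: the permutation
oracle enumerates label assignments with plain Python arithmetic, the BH
oracle is a literal step-up loop, and the component oracle is a BFS flood
fill.
"""

from collections import deque
from itertools import combinations

import numpy as np


def pooled_t_scalar(g1, g2):
    """Two-sample pooled-variance t from first principles (plain floats)."""
    n1, n2 = len(g1), len(g2)
    m1 = sum(g1) / n1
    m2 = sum(g2) / n2
    ss1 = sum((x - m1) ** 2 for x in g1)
    ss2 = sum((x - m2) ** 2 for x in g2)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    denom = (sp2 * (1.0 / n1 + 1.0 / n2)) ** 0.5
    if denom == 0:
        return 0.0
    return (m1 - m2) / denom


def exhaustive_perm_p(values, n1, direction="group1_greater"):
    """Exact one-sided permutation p for a single voxel.

    Enumerates every assignment of n1 of the samples to group 1 (including
    the identity) and returns the proportion with permuted t >= observed t.
    """
    n = len(values)
    sign = 1.0 if direction == "group1_greater" else -1.0
    idx = list(range(n))
    t_obs = sign * pooled_t_scalar([values[i] for i in idx[:n1]], [values[i] for i in idx[n1:]])
    count = 0
    total = 0
    for combo in combinations(range(n), n1):
        rest = [i for i in range(n) if i not in combo]
        t = sign * pooled_t_scalar([values[i] for i in combo], [values[i] for i in rest])
        count += t >= t_obs
        total += 1
    return count / total


def bh_stepup(pvals, q):
    """Literal Benjamini-Hochberg step-up: cutoff, reject flags, adjusted p."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    k_max = 0
    for k in range(1, m + 1):
        if ranked[k - 1] <= k * q / m:
            k_max = k
    cutoff = float(ranked[k_max - 1]) if k_max else 0.0
    reject = p <= cutoff if k_max else np.zeros(m, dtype=bool)
    adj_sorted = ranked * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return cutoff, reject, adj


_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill_components(mask, connectivity=6):
    """Component count and sorted sizes by BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    seen = np.zeros_like(mask)
    sizes = []
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            v = queue.popleft()
            size += 1
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[i] < shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        sizes.append(size)
    return len(sizes), sorted(sizes, reverse=True)
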