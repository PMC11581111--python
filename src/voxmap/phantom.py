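"""Synthetic two-group phantom cohorts with known ground truth.

The generator emulates the statistical structure of a cleared-hemisphere
immunolabel study: an ellipsoidal "brain" partitioned into hierarchical
atlas regions; per-channel volumes composed of a smooth autofluorescence
background, rasterized label objects, capillary/edge artifacts and i.i.d.
noise; and configurable group effects (object-density or label-intensity
multipliers restricted to designated atlas regions and one group).

Object shapes are the simplest ones exercising every downstream operator:

* ``aggregate`` -- solid bright spheres (plaque-like),
* ``shell``     -- spherical shells around a random subset of a companion
  aggregate channel's objects (reactive-microglia-like),
* ``fiber``     -- random-walk tubes (catecholaminergic-fiber-like),
* ``cell``      -- small well-separated spheres placed only in atlas leaves
  flagged ``catecholaminergic``.

Determinism: the per-sample random stream is seeded from a stable hash of
(master_seed, group, sample_index), so identical configs reproduce cohorts
bit-exactly and adding samples never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import (
    AffineTransform,
    AtlasBundle,
    GroupDesign,
    Volume3D,
    write_design,
    write_hierarchy,
    write_transform,
    write_volume,
)

OBJECT_KINDS = ("aggregate", "shell", "fiber", "cell")
EFFECT_KINDS = ("density_multiplier", "intensity_multiplier")


class ConfigError(ValueError):
    pass


class SizingError(ValueError):
    """Grid too small to host the requested region count."""


@dataclasses.dataclass
class ChannelSpec:
    """One immunolabel channel of the phantom.

    ``density_per_mm3`` is the expected object count per mm^3 of region
    (for fibers: of fiber start points); ``radius_um`` is the object radius
    (for shells: the shell thickness around the source object).
    """

    name: str
    kind: str
    baseline_intensity: float
    density_per_mm3: float
    radius_um: float
    source_channel: str | None = None  # required for kind == "shell"
    shell_fraction: float = 0.6  # fraction of source objects that get a shell
    fiber_length_um: float = 400.0

    def __post_init__(self) -> None:
        if self.kind not in OBJECT_KINDS:
            raise ConfigError(f"unknown object kind {self.kind!r}")
        if self.kind == "shell" and not self.source_channel:
            raise ConfigError(f"shell channel {self.name!r} needs a source_channel")
        if self.radius_um <= 0 or self.baseline_intensity < 0 or self.density_per_mm3 < 0:
            raise ConfigError(f"invalid channel parameters for {self.name!r}")


@dataclasses.dataclass
class Effect:
    region_id: int
    channel: str
    kind: str
    multiplier: float
    group: str

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ConfigError(f"unknown effect kind {self.kind!r}")
        if self.multiplier < 0:
            raise ConfigError("effect multiplier must be >= 0")


@dataclasses.dataclass
class BackgroundSpec:
    amplitude: float = 20.0
    correlation_length_um: float = 80.0


@dataclasses.dataclass
class ArtifactSpec:
    n_capillaries: int = 30
    intensity: float = 150.0
    capillary_length_um: tuple[float, float] = (200.0, 600.0)
    edge_rim: bool = True


@dataclasses.dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (96, 80, 64)
    voxel_size_um: tuple[float, float, float] = (10.0, 10.0, 10.0)
    n_per_group: int = 4
    master_seed: int = 0
    channels: list[ChannelSpec] = dataclasses.field(default_factory=list)
    effects: list[Effect] = dataclasses.field(default_factory=list)
    background: BackgroundSpec = dataclasses.field(default_factory=BackgroundSpec)
    artifact: ArtifactSpec = dataclasses.field(default_factory=ArtifactSpec)
    noise_sd: float = 5.0
    group_names: tuple[str, str] = ("case", "control")

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ConfigError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ConfigError("voxel_size_um must be positive")
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ConfigError("channel names must be unique")
        for e in self.effects:
            if e.channel not in names:
                raise ConfigError(f"effect references unknown channel {e.channel!r}")
            if e.group not in self.group_names:
                raise ConfigError(f"effect references unknown group {e.group!r}")

    def validate_against_atlas(self, atlas: AtlasBundle) -> None:
        known = set(atlas.hierarchy["region_id"].astype(int))
        for e in self.effects:
            if int(e.region_id) not in known:
                raise ConfigError(f"effect region {e.region_id} not in atlas hierarchy")


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth of a generated cohort."""

    inventory: list[dict]  # sample_id, channel, center (voxel), radius_um
    gt_masks: dict[str, dict[str, np.ndarray]]  # sample_id -> channel -> bool
    artifact_masks: dict[str, np.ndarray]  # sample_id -> bool
    effects: list[Effect]
    expected_density: dict  # (region_id, channel, group) -> expected label-density %

    def objects_in_region(self, sample_id: str, channel: str, atlas: AtlasBundle, region_id: int) -> int:
        n = 0
        for rec in self.inventory:
            if rec["sample_id"] != sample_id or rec["channel"] != channel:
                continue
            c = tuple(int(v) for v in rec["center"])
            if int(atlas.labels[c]) == int(region_id):
                n += 1
        return n


def default_config(master_seed: int = 0, n_per_group: int = 4) -> PhantomConfig:
    """Study-like default conditions (see docs for rationale)."""
    return PhantomConfig(
        master_seed=master_seed,
        n_per_group=n_per_group,
        channels=[
            ChannelSpec("abeta", "aggregate", baseline_intensity=100.0, density_per_mm3=2000.0, radius_um=20.0),
            ChannelSpec("iba1", "shell", baseline_intensity=80.0, density_per_mm3=0.0, radius_um=10.0, source_channel="abeta"),
            ChannelSpec("th", "fiber", baseline_intensity=60.0, density_per_mm3=150.0, radius_um=6.0),
            ChannelSpec("th_cell", "cell", baseline_intensity=120.0, density_per_mm3=800.0, radius_um=10.0),
        ],
    )


# ---------------------------------------------------------------------------
# Toy atlas


def _farthest_point_sample(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k rows of ``points`` spread out by greedy farthest-point sampling."""
    first = rng.integers(len(points))
    chosen = [first]
    d = np.linalg.norm(points - points[first], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return points[chosen]


def build_toy_atlas(
    grid_shape: tuple[int, int, int],
    n_parents: int,
    children_per_parent: int,
    seed: int,
    voxel_size_um: tuple[float, float, float] = (10.0, 10.0, 10.0),
    min_voxels_per_leaf: int = 64,
) -> AtlasBundle:
    """Partition an ellipsoidal brain into contiguous leaf regions.

    Parents are nearest-seed (Voronoi) cells of farthest-point-sampled
    seeds inside the ellipsoid; each parent cell is subdivided the same way
    into its children, so every leaf is connected.  Region ids: root 1,
    parents 2..n_parents+1, leaves 101, 102, ...; every fourth leaf is
    flagged ``catecholaminergic`` (eligible for cell-channel objects).
    """
    shape = tuple(int(s) for s in grid_shape)
    if any(s < 16 for s in shape):
        raise SizingError(f"grid_shape must be >= 16 per axis, got {shape}")
    if n_parents < 2 or children_per_parent < 1:
        raise ConfigError("need n_parents >= 2 and children_per_parent >= 1")
    rng = np.random.default_rng(seed)
    centre = (np.array(shape) - 1) / 2.0
    semi = np.array(shape) * 0.45
    idx = np.indices(shape).reshape(3, -1).T
    inside = (((idx - centre) / semi) ** 2).sum(axis=1) <= 1.0
    brain_pts = idx[inside]
    n_leaves = n_parents * children_per_parent
    if len(brain_pts) < min_voxels_per_leaf * n_leaves:
        raise SizingError(
            f"grid {shape} hosts {len(brain_pts)} brain voxels; "
            f"{n_leaves} leaves need >= {min_voxels_per_leaf * n_leaves}"
        )
    pts = brain_pts.astype(np.float64)
    parent_seeds = _farthest_point_sample(pts, n_parents, rng)
    d = np.linalg.norm(pts[:, None, :] - parent_seeds[None, :, :], axis=2)
    parent_assign = np.argmin(d, axis=1)

    labels = np.zeros(shape, dtype=np.int32)
    rows = [{"region_id": 1, "abbreviation": "root", "name": "whole brain", "parent_id": None, "depth": 0, "flags": ""}]
    leaf_id = 101
    for p in range(n_parents):
        pid = 2 + p
        rows.append(
            {"region_id": pid, "abbreviation": f"P{p + 1}", "name": f"parent {p + 1}",
             "parent_id": 1, "depth": 1, "flags": ""}
        )
        ppts = pts[parent_assign == p]
        if children_per_parent == 1:
            child_assign = np.zeros(len(ppts), dtype=int)
        else:
            child_seeds = _farthest_point_sample(ppts, children_per_parent, rng)
            dc = np.linalg.norm(ppts[:, None, :] - child_seeds[None, :, :], axis=2)
            child_assign = np.argmin(dc, axis=1)
        for c in range(children_per_parent):
            cpts = ppts[child_assign == c].astype(int)
            labels[cpts[:, 0], cpts[:, 1], cpts[:, 2]] = leaf_id
            flagged = (leaf_id - 101) % 4 == 0
            rows.append(
                {"region_id": leaf_id, "abbreviation": f"L{leaf_id - 100}",
                 "name": f"leaf {leaf_id - 100}", "parent_id": pid, "depth": 2,
                 "flags": "catecholaminergic" if flagged else ""}
            )
            leaf_id += 1
    hierarchy = pd.DataFrame(rows)
    return AtlasBundle(labels=labels, hierarchy=hierarchy, spacing_um=tuple(float(s) for s in voxel_size_um))


# ---------------------------------------------------------------------------
# Sample synthesis


def _sample_seed(master_seed: int, group: str, sample_index: int) -> np.random.SeedSequence:
    """Stable per-sample seed; cohort-size changes never shift streams."""
    return np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32(group.encode()), int(sample_index)]
    )


def _sphere_offsets(radius_um: float, spacing_um: Sequence[float]) -> np.ndarray:
    """(K,3) integer voxel offsets covering a physical sphere at the origin."""
    r_vox = [max(0, int(np.floor(radius_um / s))) for s in spacing_um]
    ranges = [np.arange(-r, r + 1) for r in r_vox]
    g = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    phys = g * np.asarray(spacing_um)
    keep = (phys**2).sum(axis=1) <= radius_um**2
    return g[keep]


def _stamp(canvas: np.ndarray, centers: np.ndarray, offsets: np.ndarray, value: float | np.ndarray) -> None:
    """Max-composite spheres (``offsets``) at integer ``centers`` into canvas."""
    shape = canvas.shape
    for i, c in enumerate(centers):
        vox = c[None, :] + offsets
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        v = vox[ok]
        val = value[i] if isinstance(value, np.ndarray) else value
        canvas[v[:, 0], v[:, 1], v[:, 2]] = np.maximum(canvas[v[:, 0], v[:, 1], v[:, 2]], val)


def _smooth_background(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing_um: Sequence[float],
    spec: BackgroundSpec,
) -> np.ndarray:
    field = rng.standard_normal(shape)
    sigma = [spec.correlation_length_um / s for s in spacing_um]
    field = ndimage.gaussian_filter(field, sigma=sigma, mode="nearest")
    sd = field.std()
    if sd > 0:
        field /= sd
    return np.clip(spec.amplitude * (1.0 + field / 3.0), 0.0, None)


def _capillary_artifacts(
    rng: np.random.Generator,
    brain: np.ndarray,
    spacing_um: Sequence[float],
    spec: ArtifactSpec,
) -> np.ndarray:
    """Boolean artifact mask: thin bright line segments plus an edge rim."""
    mask = np.zeros(brain.shape, dtype=bool)
    brain_idx = np.argwhere(brain)
    if len(brain_idx) == 0:
        return mask
    step = min(spacing_um)
    for _ in range(spec.n_capillaries):
        start = brain_idx[rng.integers(len(brain_idx))].astype(float)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        length_um = rng.uniform(*spec.capillary_length_um)
        n_steps = max(2, int(length_um / step))
        t = np.linspace(0.0, length_um, n_steps)
        pts = start[None, :] + (t[:, None] * direction[None, :]) / np.asarray(spacing_um)
        vox = np.floor(pts + 0.5).astype(int)
        ok = np.all((vox >= 0) & (vox < np.array(brain.shape)), axis=1)
        vox = vox[ok]
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    if spec.edge_rim:
        rim = brain & ~ndimage.binary_erosion(brain, iterations=2)
        mask |= rim
    return mask & brain


def _effect_multipliers(
    config: PhantomConfig, channel: str, group: str
) -> tuple[dict[int, float], dict[int, float]]:
    """(density multiplier, intensity multiplier) per region for one group."""
    dens: dict[int, float] = {}
    inten: dict[int, float] = {}
    for e in config.effects:
        if e.channel != channel or e.group != group:
            continue
        target = dens if e.kind == "density_multiplier" else inten
        target[int(e.region_id)] = target.get(int(e.region_id), 1.0) * e.multiplier
    return dens, inten


def _region_voxels(atlas: AtlasBundle) -> dict[int, np.ndarray]:
    out = {}
    for leaf in atlas.leaf_ids:
        out[leaf] = np.argwhere(atlas.labels == leaf)
    return out


def simulate_sample(
    config: PhantomConfig,
    atlas: AtlasBundle,
    group: str,
    sample_index: int,
    _region_cache: dict[int, np.ndarray] | None = None,
) -> tuple[dict[str, Volume3D], dict]:
    """Generate one sample's channel volumes plus its ground-truth slice.

    Returns ``(volumes, truth)`` where truth holds the per-channel
    ground-truth object masks, the object inventory, the brain mask and the
    artifact mask for this sample.
    """
    if group not in config.group_names:
        raise ConfigError(f"unknown group {group!r}; design groups are {config.group_names}")
    config.validate_against_atlas(atlas)
    shape = tuple(int(s) for s in config.grid_shape)
    if shape != tuple(atlas.labels.shape):
        raise ConfigError(f"config grid {shape} != atlas grid {atlas.labels.shape}")
    spacing = tuple(float(s) for s in config.voxel_size_um)
    voxel_mm3 = float(np.prod(spacing)) * 1e-9
    sample_id = f"{group}_{sample_index:02d}"

    ss = _sample_seed(config.master_seed, group, sample_index)
    # independent substreams: artifacts, then one per channel, then noise
    streams = ss.spawn(2 + len(config.channels))
    rng_art = np.random.default_rng(streams[0])
    rng_noise = np.random.default_rng(streams[1])

    brain = atlas.labels > 0
    regions = _region_cache if _region_cache is not None else _region_voxels(atlas)
    flagged = set(
        int(r) for r, f in zip(atlas.hierarchy["region_id"], atlas.hierarchy["flags"])
        if "catecholaminergic" in str(f)
    )
    artifact = _capillary_artifacts(rng_art, brain, spacing, config.artifact)

    volumes: dict[str, Volume3D] = {}
    gt_masks: dict[str, np.ndarray] = {}
    inventory: list[dict] = []
    agg_centers: dict[str, np.ndarray] = {}  # for shell channels

    for ch, stream in zip(config.channels, streams[2:]):
        rng = np.random.default_rng(stream)
        dens_mult, inten_mult = _effect_multipliers(config, ch.name, group)
        obj = np.zeros(shape, dtype=np.float64)
        gt = np.zeros(shape, dtype=bool)
        offsets = _sphere_offsets(ch.radius_um, spacing)
        centers_list: list[np.ndarray] = []

        if ch.kind in ("aggregate", "cell"):
            eligible = [r for r in regions if ch.kind == "aggregate" or r in flagged]
            placed_phys: list[np.ndarray] = []
            min_sep_um = 2 * ch.radius_um + 2 * max(spacing)  # cells stay 6-disconnected
            for rid in eligible:
                vox = regions[rid]
                rate = ch.density_per_mm3 * len(vox) * voxel_mm3 * dens_mult.get(rid, 1.0)
                n_obj = rng.poisson(rate)
                if n_obj == 0:
                    continue
                intensity = ch.baseline_intensity * inten_mult.get(rid, 1.0)
                if ch.kind == "cell":
                    centers = []
                    attempts = 0
                    while len(centers) < n_obj and attempts < 20 * n_obj:
                        cand = vox[rng.integers(len(vox))]
                        cand_phys = cand * np.asarray(spacing)
                        if all(np.linalg.norm(cand_phys - p) >= min_sep_um for p in placed_phys):
                            centers.append(cand)
                            placed_phys.append(cand_phys)
                        attempts += 1
                    centers = np.array(centers, dtype=int) if centers else np.empty((0, 3), dtype=int)
                else:
                    centers = vox[rng.integers(len(vox), size=n_obj)]
                if len(centers):
                    _stamp(obj, centers, offsets, intensity)
                    gt_stamp = np.zeros(shape, dtype=np.float64)
                    _stamp(gt_stamp, centers, offsets, 1.0)
                    gt |= gt_stamp > 0
                    centers_list.append(centers)
                    for c in centers:
                        inventory.append(
                            {"sample_id": sample_id, "channel": ch.name,
                             "center": [int(v) for v in c], "radius_um": ch.radius_um}
                        )
        elif ch.kind == "fiber":
            step_um = min(spacing)
            for rid in regions:
                vox = regions[rid]
                rate = ch.density_per_mm3 * len(vox) * voxel_mm3 * dens_mult.get(rid, 1.0)
                n_fib = rng.poisson(rate)
                for _ in range(n_fib):
                    start = vox[rng.integers(len(vox))].astype(float)
                    direction = rng.standard_normal(3)
                    direction /= np.linalg.norm(direction)
                    n_steps = max(2, int(ch.fiber_length_um / step_um))
                    pts = [start.copy()]
                    pos = start.copy()
                    for _ in range(n_steps - 1):
                        direction = direction + 0.2 * rng.standard_normal(3)
                        direction /= np.linalg.norm(direction)
                        pos = pos + direction * step_um / np.asarray(spacing)
                        pts.append(pos.copy())
                    centers = np.floor(np.array(pts) + 0.5).astype(int)
                    ok = np.all((centers >= 0) & (centers < np.array(shape)), axis=1)
                    centers = centers[ok]
                    keep = brain[centers[:, 0], centers[:, 1], centers[:, 2]]
                    centers = centers[keep]
                    if len(centers):
                        _stamp(obj, centers, offsets, ch.baseline_intensity)
                        tube = np.zeros(shape, dtype=np.float64)
                        _stamp(tube, centers, offsets, 1.0)
                        gt |= tube > 0
                        inventory.append(
                            {"sample_id": sample_id, "channel": ch.name,
                             "center": [int(v) for v in centers[0]], "radius_um": ch.radius_um}
                        )
        elif ch.kind == "shell":
            src = agg_centers.get(ch.source_channel)
            if src is None:
                raise ConfigError(
                    f"shell channel {ch.name!r} needs aggregate channel "
                    f"{ch.source_channel!r} generated before it"
                )
            src_spec = next(c for c in config.channels if c.name == ch.source_channel)
            outer = _sphere_offsets(src_spec.radius_um + ch.radius_um, spacing)
            inner = set(map(tuple, _sphere_offsets(src_spec.radius_um, spacing)))
            shell_off = np.array([o for o in outer if tuple(o) not in inner], dtype=int)
            n_take = int(round(ch.shell_fraction * len(src)))
            if n_take > 0 and len(src) > 0:
                take = rng.choice(len(src), size=min(n_take, len(src)), replace=False)
                centers = src[take]
                # intensity effects keyed to the region of each shell's centre
                vals = np.array(
                    [ch.baseline_intensity * inten_mult.get(int(atlas.labels[tuple(c)]), 1.0) for c in centers]
                )
                _stamp(obj, centers, shell_off, vals)
                tube = np.zeros(shape, dtype=np.float64)
                _stamp(tube, centers, shell_off, 1.0)
                gt |= tube > 0
                for c in centers:
                    inventory.append(
                        {"sample_id": sample_id, "channel": ch.name,
                         "center": [int(v) for v in c], "radius_um": src_spec.radius_um + ch.radius_um}
                    )

        if ch.kind == "aggregate":
            agg_centers[ch.name] = (
                np.concatenate(centers_list) if centers_list else np.empty((0, 3), dtype=int)
            )

        # voxel-wise intensity effects for spatially extended objects (fibers)
        if ch.kind == "fiber" and inten_mult:
            field = np.ones(shape)
            for rid, mult in inten_mult.items():
                field[atlas.labels == rid] = mult
            obj *= field

        img = _smooth_background(rng, shape, spacing, config.background) * brain
        img = img + obj
        img[artifact] = np.maximum(img[artifact], config.artifact.intensity)
        if config.noise_sd > 0:
            img = img + rng_noise.normal(0.0, config.noise_sd, size=shape)
        img = np.clip(img, 0.0, None)
        volumes[ch.name] = Volume3D(
            img.astype(np.float32), spacing, space="tissue", sample_id=sample_id
        )
        gt_masks[ch.name] = gt

    truth = {
        "sample_id": sample_id,
        "group": group,
        "inventory": inventory,
        "gt_masks": gt_masks,
        "brain_mask": brain,
        "artifact_mask": artifact,
    }
    return volumes, truth


def expected_label_density(
    config: PhantomConfig, atlas: AtlasBundle, region_id: int, channel: str, group: str
) -> float:
    """Analytic expected label density (%) in a region, ignoring overlap.

    density_per_mm3 * multiplier * single-object volume * 100, capped at 100;
    a small-occupancy approximation (objects are assumed non-overlapping).
    """
    ch = next(c for c in config.channels if c.name == channel)
    dens_mult, _ = _effect_multipliers(config, channel, group)
    spacing = config.voxel_size_um
    n_vox_obj = len(_sphere_offsets(ch.radius_um, spacing))
    obj_mm3 = n_vox_obj * float(np.prod(spacing)) * 1e-9
    rate = ch.density_per_mm3 * dens_mult.get(int(region_id), 1.0)
    return float(min(100.0, 100.0 * rate * obj_mm3))


def simulate_cohort(
    config: PhantomConfig,
    atlas: AtlasBundle,
    out_dir: str | Path | None = None,
) -> tuple[GroupDesign, dict[str, dict[str, Volume3D]], PhantomTruth]:
    """Generate the full two-group cohort; optionally write it to disk.

    Returns (design, {sample_id: {channel: Volume3D}}, truth).  Rerunning
    with the same config and master seed is bit-identical.
    """
    if config.n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2 for a two-group design")
    config.validate_against_atlas(atlas)
    region_cache = _region_voxels(atlas)
    rows = []
    all_volumes: dict[str, dict[str, Volume3D]] = {}
    inventory: list[dict] = []
    gt_masks: dict[str, dict[str, np.ndarray]] = {}
    artifact_masks: dict[str, np.ndarray] = {}

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"output location {out} not writable: {exc}") from exc

    expected: dict = {}
    for leaf in atlas.leaf_ids:
        for ch in config.channels:
            for g in config.group_names:
                if ch.kind in ("aggregate", "cell"):
                    expected[(leaf, ch.name, g)] = expected_label_density(config, atlas, leaf, ch.name, g)

    for group in config.group_names:
        for i in range(config.n_per_group):
            sample_index = i if group == config.group_names[0] else config.n_per_group + i
            volumes, truth = simulate_sample(config, atlas, group, sample_index, region_cache)
            sid = truth["sample_id"]
            all_volumes[sid] = volumes
            inventory.extend(truth["inventory"])
            gt_masks[sid] = truth["gt_masks"]
            artifact_masks[sid] = truth["artifact_mask"]
            row = {"sample_id": sid, "group": group}
            if out is not None:
                # design rows carry file names relative to the design CSV so a
                # cohort directory is relocatable and reruns byte-identical
                for ch_name, vol in volumes.items():
                    write_volume(vol, out / f"{sid}_{ch_name}.nii.gz")
                    row[f"vol_{ch_name}"] = f"{sid}_{ch_name}.nii.gz"
                write_volume(
                    Volume3D(truth["brain_mask"].astype(np.uint8), config.voxel_size_um),
                    out / f"{sid}_brain_mask.nii.gz",
                )
                row["brain_mask"] = f"{sid}_brain_mask.nii.gz"
                write_volume(
                    Volume3D(truth["artifact_mask"].astype(np.uint8), config.voxel_size_um),
                    out / f"{sid}_artifact_mask.nii.gz",
                )
                row["artifact_mask"] = f"{sid}_artifact_mask.nii.gz"
                write_transform(AffineTransform.identity(), out / f"{sid}_transform.txt")
                row["transform"] = f"{sid}_transform.txt"
                for ch_name, gm in truth["gt_masks"].items():
                    write_volume(
                        Volume3D(gm.astype(np.uint8), config.voxel_size_um),
                        out / f"{sid}_gt_{ch_name}.nii.gz",
                    )
            rows.append(row)

    design = GroupDesign(pd.DataFrame(rows))
    truth_all = PhantomTruth(
        inventory=inventory,
        gt_masks=gt_masks,
        artifact_masks=artifact_masks,
        effects=list(config.effects),
        expected_density=expected,
    )
    if out is not None:
        write_design(design, out / "design.csv")
        write_hierarchy(atlas.hierarchy, out / "hierarchy.csv")
        write_volume(atlas.label_volume(), out / "atlas_labels.nii.gz")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "inventory": inventory,
                    "effects": [dataclasses.asdict(e) for e in config.effects],
                    "expected_density": {f"{k[0]}|{k[1]}|{k[2]}": v for k, v in expected.items()},
                },
                fh,
                indent=1,
            )
    return design, all_volumes, truth_all
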