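"""Volume, atlas, transform and design I/O with strict metadata validation.

Conventions used throughout the package:

* Arrays are indexed ``(x, y, z)`` with 0-based voxel indices.
* The physical position of a voxel is ``index * spacing_um`` at its centre,
  in micrometres.
* Affine transforms map tissue-space physical coordinates (um) to
  atlas-space physical coordinates (um), as homogeneous 4x4 matrices.
* Volumes carry a ``space`` tag (``"tissue"`` or ``"atlas"``) so that
  stages can refuse to mix spaces silently.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

SPACES = ("tissue", "atlas")


class FormatError(ValueError):
    """Malformed file or missing/invalid spatial metadata."""


class ValidationError(ValueError):
    """A loaded object violates its type invariants."""


@dataclasses.dataclass
class Volume3D:
    """A 3D scalar grid with physical voxel spacing and a space tag."""

    values: np.ndarray
    spacing_um: tuple[float, float, float]
    space: str = "tissue"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"volume must be 3D, got ndim={self.values.ndim}")
        if any(s <= 0 for s in self.values.shape):
            raise ValidationError(f"volume shape must be positive, got {self.values.shape}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValidationError(f"spacing must be 3 positive reals, got {self.spacing_um}")
        if self.space not in SPACES:
            raise ValidationError(f"space must be one of {SPACES}, got {self.space!r}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValidationError("volume contains NaN/inf values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in cubic millimetres."""
        sx, sy, sz = self.spacing_um
        return (sx * sy * sz) * 1e-9

    def like(self, values: np.ndarray, space: str | None = None) -> "Volume3D":
        """New volume with the same grid metadata but different values."""
        return Volume3D(
            values=values,
            spacing_um=self.spacing_um,
            space=self.space if space is None else space,
            sample_id=self.sample_id,
        )


@dataclasses.dataclass
class AtlasBundle:
    """Integer region-label volume plus its region hierarchy table.

    ``labels`` uses 0 for outside-brain / undefined voxels.  The hierarchy
    table has columns ``region_id, abbreviation, name, parent_id, depth,
    flags``; ``parent_id`` is empty (NaN / <=0) for roots and the links must
    form a forest.  Leaf regions are those never referenced as a parent.
    """

    labels: np.ndarray
    hierarchy: pd.DataFrame
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("atlas labels must be integer-valued")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        validate_hierarchy(self.hierarchy)
        present = set(np.unique(self.labels)) - {0}
        known = set(self.hierarchy["region_id"].astype(int))
        missing = present - known
        if missing:
            raise ValidationError(f"labels present in volume but not in hierarchy: {sorted(missing)}")

    @property
    def leaf_ids(self) -> list[int]:
        parents = set(self.hierarchy["parent_id"].dropna().astype(int))
        return [int(r) for r in self.hierarchy["region_id"] if int(r) not in parents]

    def parent_of(self, region_id: int) -> int | None:
        row = self.hierarchy.loc[self.hierarchy["region_id"] == region_id]
        if row.empty:
            return None
        p = row["parent_id"].iloc[0]
        if pd.isna(p) or int(p) <= 0:
            return None
        return int(p)

    def label_volume(self) -> Volume3D:
        return Volume3D(self.labels, self.spacing_um, space="atlas")


@dataclasses.dataclass
class AffineTransform:
    """4x4 homogeneous matrix: tissue physical um -> atlas physical um."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"transform must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValidationError("last row of affine must be (0,0,0,1)")
        if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
            raise ValidationError("affine matrix is singular or near-singular")
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        """Map (N,3) physical points through the transform."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        hom = np.c_[pts, np.ones(len(pts))]
        out = hom @ self.matrix.T
        return out[:, :3]


@dataclasses.dataclass
class GroupDesign:
    """Two-group sample table with per-sample file bindings.

    ``table`` rows: sample_id, group, plus arbitrary path columns
    (channel volumes, brain mask, artifact mask, transform).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "group"):
            if col not in t.columns:
                raise ValidationError(f"design table missing column {col!r}")
        groups = list(pd.unique(t["group"]))
        if len(groups) != 2:
            raise ValidationError(f"design must have exactly two groups, got {groups}")
        counts = t["group"].value_counts()
        if (counts < 2).any():
            raise ValidationError(f"each group needs >= 2 samples, got {counts.to_dict()}")
        if t["sample_id"].duplicated().any():
            raise ValidationError("sample_ids must be unique")

    @property
    def groups(self) -> tuple[str, str]:
        """The two group labels; group 1 is the lexicographically first so
        contrast directions do not depend on row order."""
        g = sorted(str(x) for x in pd.unique(self.table["group"]))
        return (g[0], g[1])

    def samples(self, group: str) -> list[str]:
        return [str(s) for s in self.table.loc[self.table["group"] == group, "sample_id"]]

    def row(self, sample_id: str) -> pd.Series:
        rows = self.table.loc[self.table["sample_id"] == sample_id]
        if rows.empty:
            raise KeyError(f"unknown sample_id {sample_id!r}")
        return rows.iloc[0]


# ---------------------------------------------------------------------------
# NIfTI volume I/O


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI; spacing stored in the affine, in um."""
    path = Path(path)
    affine = np.diag(list(vol.spacing_um) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.values), affine)
    img.header.set_xyzt_units(3)  # micrometres
    img.header["descrip"] = f"space={vol.space}".encode()
    nib.save(img, str(path))


def read_volume(path: str | Path, sample_id: str = "") -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise FormatError(f"{path}: nonpositive or missing voxel spacing {zooms}")
    descrip = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
    space = "tissue"
    if descrip.startswith("space="):
        tag = descrip.split("=", 1)[1].strip()
        if tag in SPACES:
            space = tag
    values = np.asanyarray(img.dataobj)
    return Volume3D(values=values, spacing_um=tuple(float(z) for z in zooms), space=space, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Tabular / matrix I/O


def validate_hierarchy(h: pd.DataFrame) -> None:
    required = {"region_id", "abbreviation", "name", "parent_id", "depth"}
    missing = required - set(h.columns)
    if missing:
        raise FormatError(f"hierarchy missing columns: {sorted(missing)}")
    ids = h["region_id"].astype(int)
    if ids.duplicated().any():
        raise ValidationError("duplicate region_id in hierarchy")
    known = set(ids)
    parent = {}
    for _, row in h.iterrows():
        rid = int(row["region_id"])
        p = row["parent_id"]
        if pd.isna(p) or (isinstance(p, str) and not p.strip()) or int(p) <= 0:
            continue
        p = int(p)
        if p == rid:
            raise ValidationError(f"region {rid} is its own parent")
        if p not in known:
            raise ValidationError(f"region {rid} has unknown parent {p}")
        parent[rid] = p
    # forest check: following parent links must terminate without revisiting
    for rid in parent:
        seen = {rid}
        cur = rid
        while cur in parent:
            cur = parent[cur]
            if cur in seen:
                raise ValidationError(f"cycle in hierarchy parent links through region {rid}")
            seen.add(cur)


def read_hierarchy(path: str | Path) -> pd.DataFrame:
    h = pd.read_csv(path)
    if "flags" not in h.columns:
        h["flags"] = ""
    h["flags"] = h["flags"].fillna("")
    validate_hierarchy(h)
    return h


def write_hierarchy(h: pd.DataFrame, path: str | Path) -> None:
    h.to_csv(path, index=False)


def read_design(path: str | Path) -> GroupDesign:
    """Read a design CSV; relative file paths resolve against its directory."""
    path = Path(path)
    t = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    base = path.parent
    for col in t.columns:
        if col in ("sample_id", "group"):
            continue
        t[col] = [
            str(base / v) if isinstance(v, str) and v and not Path(v).is_absolute() else v
            for v in t[col]
        ]
    return GroupDesign(t)


def write_design(design: GroupDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


def read_transform(path: str | Path) -> AffineTransform:
    """Read a plain-text row-major 4x4 affine matrix."""
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise FormatError(f"{path}: expected 4x4 matrix, got shape {m.shape}")
    return AffineTransform(m)


def write_transform(t: AffineTransform, path: str | Path) -> None:
    np.savetxt(path, t.matrix, fmt="%.10g")


def write_atlas(atlas: AtlasBundle, labels_path: str | Path, hierarchy_path: str | Path) -> None:
    write_volume(atlas.label_volume(), labels_path)
    write_hierarchy(atlas.hierarchy, hierarchy_path)


def read_atlas(labels_path: str | Path, hierarchy_path: str | Path) -> AtlasBundle:
    vol = read_volume(labels_path)
    labels = np.rint(np.asarray(vol.values)).astype(np.int32)
    return AtlasBundle(labels=labels, hierarchy=read_hierarchy(hierarchy_path), spacing_um=vol.spacing_um)
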