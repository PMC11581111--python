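"""Binary label-mask production.

The study design assumes per-sample segmentations of the immunolabel
(plaques, reactive microglia, fibres, cells).  Those are normally made by
a trained pixel classifier; here a threshold-plus-size-filter segmenter is
provided as a simple internal stand-in, and externally produced masks are
accepted on the same terms.

Connectivity conventions: the size filter inside segmentation uses
26-connectivity (a generous object definition before filtering); cell
*counting* during cluster validation uses 6-connectivity (see
``cluster_validate``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import SpatialError
from .volio import Volume3D, read_volume

LABEL_KINDS = ("aggregate", "reactive_microglia", "fiber", "cell", "artifact")

_STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclasses.dataclass
class SegmentationMask:
    mask: Volume3D
    label_kind: str
    source: str = "internal_threshold"

    def __post_init__(self) -> None:
        if self.label_kind not in LABEL_KINDS:
            raise ValueError(f"label_kind must be one of {LABEL_KINDS}, got {self.label_kind!r}")
        if self.mask.values.dtype != bool:
            self.mask = self.mask.like(np.asarray(self.mask.values).astype(bool))


def segment_by_threshold(
    vol: Volume3D,
    intensity_threshold: float,
    min_object_vox: int = 1,
    label_kind: str = "aggregate",
) -> SegmentationMask:
    """Threshold then drop 26-connected objects smaller than ``min_object_vox``.

    Monotone in the threshold: raising it never adds voxels.
    """
    if min_object_vox < 1:
        raise ValueError(f"min_object_vox must be >= 1, got {min_object_vox}")
    binary = np.asarray(vol.values) > intensity_threshold
    if min_object_vox > 1 and binary.any():
        labels, n = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_object_vox
        keep[0] = False
        binary = keep[labels]
    return SegmentationMask(vol.like(binary), label_kind=label_kind, source="internal_threshold")


def reactive_mask(
    vol: Volume3D,
    intensity_threshold: float,
    aggregate_mask: SegmentationMask | None = None,
    dilation_vox: int = 2,
    min_object_vox: int = 1,
) -> SegmentationMask:
    """Reactive-microglia stand-in: above threshold OR near aggregates.

    A voxel counts as reactive either because its label intensity is high or
    because it lies within ``dilation_vox`` voxels of a segmented aggregate
    (microglia clustered around plaques).
    """
    base = segment_by_threshold(vol, intensity_threshold, min_object_vox).mask.values
    if aggregate_mask is not None:
        if aggregate_mask.mask.shape != vol.shape:
            raise SpatialError("aggregate mask grid does not match volume grid")
        halo = ndimage.binary_dilation(
            aggregate_mask.mask.values, structure=_STRUCT_26, iterations=dilation_vox
        )
        base = base | (halo & (np.asarray(vol.values) > 0))
    return SegmentationMask(vol.like(base), label_kind="reactive_microglia", source="internal_threshold")


def load_external_mask(
    path: str | Path,
    label_kind: str,
    expected_shape: tuple[int, int, int] | None = None,
    expected_spacing_um: tuple[float, float, float] | None = None,
) -> SegmentationMask:
    """Load a 0/1 (or integer) NIfTI mask, validating its grid if known."""
    vol = read_volume(path)
    if expected_shape is not None and tuple(vol.shape) != tuple(expected_shape):
        raise SpatialError(f"mask grid {vol.shape} does not match expected {expected_shape}")
    if expected_spacing_um is not None and not np.allclose(vol.spacing_um, expected_spacing_um):
        raise SpatialError(
            f"mask spacing {vol.spacing_um} does not match expected {expected_spacing_um}"
        )
    return SegmentationMask(vol.like(np.asarray(vol.values) != 0), label_kind=label_kind, source="external")
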