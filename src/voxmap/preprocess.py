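"""Per-sample image conditioning.

The pipeline order is: rolling-ball background subtraction -> artifact /
keep masking -> warp to atlas space -> per-brain z-scoring within an
exclusion mask -> Gaussian smoothing.  Every stage is a pure function of
its inputs.

Notes on two interpretation choices (both configurable by calling the
stages directly):

* The rolling-ball background is a slice-wise 2D grayscale opening with a
  disk footprint, applied along the z axis (axis 2) -- the classical
  definition for z-stack acquisitions; the radius is in pixels.
* The smoothing kernel parameter is the Gaussian *sigma* in physical
  micrometres (the convention of fslmaths' ``-s``), converted per axis to
  voxels, so anisotropic grids are handled correctly.  FWHM is the other
  plausible reading; callers wanting FWHM semantics should divide by
  2*sqrt(2*ln 2) ~= 2.3548 before calling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening

from .volio import AffineTransform, Volume3D


class SpatialError(ValueError):
    """Grids or spaces of two volumes are incompatible."""


class DegenerateInputError(ValueError):
    """Input is valid in type but statistically degenerate (e.g. zero variance)."""


def rolling_ball_subtract(vol: Volume3D, radius_px: int) -> Volume3D:
    """Subtract a slice-wise morphological background estimate.

    Background per z-slice = grayscale opening with a disk of ``radius_px``
    pixels; output = input - background, clamped at 0.
    """
    if radius_px < 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px}")
    nx, ny, _ = vol.shape
    if 2 * radius_px + 1 > min(nx, ny):
        raise ValueError(
            f"rolling-ball radius {radius_px}px exceeds slice extent {nx}x{ny}"
        )
    data = np.asarray(vol.values, dtype=np.float64)
    footprint = disk(radius_px)
    out = np.empty_like(data)
    for k in range(data.shape[2]):
        background = opening(data[:, :, k], footprint)
        out[:, :, k] = data[:, :, k] - background
    np.clip(out, 0.0, None, out=out)
    return vol.like(out)


def apply_keep_mask(vol: Volume3D, keep: Volume3D) -> Volume3D:
    """Zero out voxels where ``keep`` is false; others pass unchanged."""
    if keep.shape != vol.shape:
        raise SpatialError(f"mask shape {keep.shape} != volume shape {vol.shape}")
    keep_bool = np.asarray(keep.values).astype(bool)
    return vol.like(np.where(keep_bool, vol.values, 0.0))


def _pullback_coords(
    t: AffineTransform,
    target_shape: tuple[int, int, int],
    target_spacing_um: tuple[float, float, float],
    source_spacing_um: tuple[float, float, float],
) -> np.ndarray:
    """Source voxel coordinates (3, *target_shape) for each target voxel.

    ``t`` maps source physical coordinates to target physical coordinates;
    values are pulled through its inverse.
    """
    inv = t.inverse().matrix
    idx = np.indices(target_shape, dtype=np.float64)
    phys = idx * np.asarray(target_spacing_um, dtype=float).reshape(3, 1, 1, 1)
    src_phys = np.einsum("ij,jxyz->ixyz", inv[:3, :3], phys) + inv[:3, 3].reshape(3, 1, 1, 1)
    return src_phys / np.asarray(source_spacing_um, dtype=float).reshape(3, 1, 1, 1)


def warp_volume(
    vol: Volume3D,
    t: AffineTransform,
    target_shape: tuple[int, int, int],
    target_spacing_um: tuple[float, float, float],
    interpolation: str = "linear",
    target_space: str = "atlas",
) -> Volume3D:
    """Resample ``vol`` onto a target grid by pulling through ``t``'s inverse.

    ``t`` maps the volume's physical coordinates to the target space's
    physical coordinates.  Out-of-domain voxels are 0.  Integer-labelled
    volumes (masks, atlases, cluster labels) must use nearest.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    data = np.asarray(vol.values)
    if interpolation == "linear" and np.issubdtype(data.dtype, np.integer):
        raise ValueError("linear interpolation requested for an integer-labelled volume; use nearest")
    if any(s <= 0 for s in target_shape) or any(s <= 0 for s in target_spacing_um):
        raise ValueError("target grid spec must have positive shape and spacing")
    coords = _pullback_coords(t, tuple(target_shape), tuple(target_spacing_um), vol.spacing_um)
    if interpolation == "nearest":
        # round-half-up gather; keeps binary masks exactly binary
        idx = np.floor(coords + 0.5).astype(np.int64)
        valid = np.ones(target_shape, dtype=bool)
        for ax in range(3):
            valid &= (idx[ax] >= 0) & (idx[ax] < data.shape[ax])
        idx_clipped = [np.clip(idx[ax], 0, data.shape[ax] - 1) for ax in range(3)]
        out = np.where(valid, data[idx_clipped[0], idx_clipped[1], idx_clipped[2]], 0)
        out = out.astype(data.dtype, copy=False)
    else:
        out = ndimage.map_coordinates(
            data.astype(np.float64), coords, order=1, mode="constant", cval=0.0
        )
    return Volume3D(out, tuple(target_spacing_um), space=target_space, sample_id=vol.sample_id)


def zscore_in_mask(vol: Volume3D, mask: Volume3D) -> Volume3D:
    """Z-score in-mask voxels (population sd); out-of-mask voxels become 0."""
    if mask.shape != vol.shape:
        raise SpatialError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    m = np.asarray(mask.values).astype(bool)
    if m.sum() < 2:
        raise DegenerateInputError("z-score mask must contain >= 2 voxels")
    vals = np.asarray(vol.values, dtype=np.float64)[m]
    mu = vals.mean()
    sd = vals.std()  # population sd (ddof=0)
    if sd == 0:
        raise DegenerateInputError("zero variance inside z-score mask")
    out = np.zeros(vol.shape, dtype=np.float64)
    out[m] = (np.asarray(vol.values, dtype=np.float64)[m] - mu) / sd
    return vol.like(out)


def gaussian_smooth(vol: Volume3D, kernel_um: float) -> Volume3D:
    """Gaussian smoothing with sigma = ``kernel_um`` per axis (physical units).

    Sigma is converted to voxels using each axis's spacing, so anisotropic
    grids smooth isotropically in physical space.
    """
    if kernel_um <= 0:
        raise ValueError(f"kernel_um must be positive, got {kernel_um}")
    sigma_vox = [kernel_um / s for s in vol.spacing_um]
    out = ndimage.gaussian_filter(
        np.asarray(vol.values, dtype=np.float64), sigma=sigma_vox, mode="nearest"
    )
    return vol.like(out)
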