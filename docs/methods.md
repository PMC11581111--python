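# Methods

## The analysis

`voxmap` implements a whole-brain voxel-wise mapping analysis for
cleared-tissue light-sheet immunofluorescence volumes, of the kind used to
localize amyloid plaques (6E10), reactive microglia (Iba1) and
catecholaminergic fibers/cells (TH) in mouse models of amyloidosis against
non-carrier controls. The pipeline is, per immunolabel channel:

1. **Background subtraction** — slice-wise rolling-ball: a grayscale opening
   with a disk footprint per z-slice estimates the smooth autofluorescence
   background; the result is `max(image − background, 0)`. The protocol
   default radius is 20 px; phantom-scale analyses use 4 px (see problem
   sizes below).
2. **Artifact / signal-of-interest masking** — voxels flagged by an artifact
   mask (capillary staining, tissue edges) or outside the keep mask are set
   to exactly 0.
3. **Warping to atlas space** — each sample's affine (4×4, physical
   micrometre coordinates) pulls the tissue volume onto the atlas grid;
   trilinear interpolation for intensities, nearest-neighbour for any
   integer-labelled volume.
4. **Per-brain z-scoring** — within a supplied brain/exclusion mask, using
   the population standard deviation; out-of-mask voxels are 0. The
   exclusion mask is an input: the library does not decide which atlas
   regions (ventricles, olfactory bulb, undefined) to exclude.
5. **Smoothing** — Gaussian, sigma given in micrometres and converted per
   axis to voxels, so anisotropic grids smooth isotropically in physical
   space. The protocol's "100 µm kernel" is read as a *sigma* (the
   convention of fslmaths' `-s`); FWHM is the other defensible reading and
   callers wanting it should divide by 2.3548.
6. **Voxel-wise inference** — per-voxel pooled-variance Student t between
   the two groups; one-sided permutation p-values by relabelling samples.
   When C(n, n1) ≤ the requested permutation count, all label assignments
   are enumerated and p is the exact proportion (including the identity)
   with permuted t ≥ observed t; otherwise p = (1+b)/(M+1) over M sampled
   assignments, which never returns 0. Increase and decrease contrasts are
   run as separate one-sided analyses. Protocol default is 18,000
   permutations; at phantom sizes (4 vs 4) the exact path (70 assignments)
   always triggers.
7. **FDR** — Benjamini–Hochberg step-up over in-mask voxels at level q
   (protocol defaults 0.2 for plaque/microglia channels, 0.4 for TH), via
   `statsmodels.multipletests`; the returned threshold is the largest raw p
   passing the step-up condition (0 if none).
8. **Cluster extent thresholding** — connected components of the
   significance mask (6-connectivity by default — the only connectivity the
   protocol states anywhere; 26 by flag), dropping components below the
   extent threshold (defaults 400 voxels, or 100 for TH-like channels), ids
   assigned by descending size.
9. **Back-warped validation** — each cluster is pulled back onto every
   sample's native grid (nearest-neighbour) and a direct density is
   measured: label density = 100 × segmented∩cluster / cluster voxels, or
   cell density = 6-connected components of cells∩cluster per mm³ of
   cluster. A cluster is *valid* when a pooled-variance one-tailed t-test
   on the per-sample densities is significant at alpha = 0.05 in the
   direction inherited from the voxel-wise contrast. Cell counting may be
   restricted to designated regions (e.g. those containing
   catecholaminergic somata) while the denominator keeps the full cluster.
   No multiplicity correction is applied across clusters.
10. **Regional composition** — valid-cluster voxels are tallied per atlas
    leaf region (atlas label 0 becomes an "undefined" row). If the top 4
    regions jointly exceed 80 % of the cluster volume the leaf table is
    reported; otherwise every region merges one level into its parent and
    the condition is re-tested, recursing until it holds or only roots
    remain. Total attributed volume is conserved exactly at every level.

Segmentations normally come from an externally trained pixel classifier;
the built-in stand-in thresholds the background-subtracted, artifact-masked
image and removes 26-connected objects below a minimum size. A
reactive-microglia variant adds voxels within a small dilation of the
aggregate segmentation (microglia clustered around plaques).

### Degenerate statistics

Voxels with zero pooled variance get t = 0. In the validation t-test,
groups with internal variance but equal means give t = 0, one-tailed
p = 0.5; zero pooled variance with equal means gives p = 1; zero pooled
variance with a nonzero difference gives p = 0 in the favoured direction
and 1 otherwise. Z-scoring a zero-variance region raises a degenerate-input
error rather than emitting NaNs; no pipeline stage may emit NaN.

### Conventions

Voxel indices are 0-based; a voxel's physical position is `index × spacing`
at its centre; all warps act on physical coordinates in micrometres.
Out-of-domain warped voxels are 0, matching the masking convention.
Nearest-neighbour resampling rounds half up (`floor(x + 0.5)`), so
axis-aligned integer-factor resampling of boxes scales voxel counts
exactly. "Group 1" of a contrast is the lexicographically first group
label, making directions independent of design-table row order.

## The phantom

The synthetic cohort generator emulates the statistical structure the
analysis assumes, not light-sheet optics. A toy atlas partitions an
ellipsoidal hemisphere into contiguous leaf regions (farthest-point-sampled
Voronoi cells, subdivided per parent), with a two-level hierarchy and a
subset of leaves flagged as eligible for cell objects. Each channel volume
is

    smooth background × brain + rasterized objects + artifacts + N(0, σ²),

clipped at 0. Objects: solid spheres (plaque-like aggregates), spherical
shells around a random subset of a companion channel's aggregates
(reactive-microglia-like), random-walk tubes (fibers), and small
well-separated spheres restricted to flagged leaves (cells; placement
enforces a minimum separation so ground-truth counts equal 6-connected
component counts). Group effects multiply either the per-region Poisson
object rate (`density_multiplier`) or the label intensity
(`intensity_multiplier`) for the affected group only; multiplier 1 means no
difference. Artifacts are thin bright capillary-like line segments plus a
bright rim at the tissue edge, with the exact artifact mask emitted as
ground truth.

Default conditions (chosen once, as a desk-scale analogue of a cleared
hemisphere): 96×80×64 voxels at 10 µm isotropic spacing (the acquisition
this emulates is finer, ~3.5–6 µm, but the analysis is resolution-agnostic
and spacing is configurable, including anisotropic); n = 4 per group;
aggregate density 2000 objects/mm³ of radius 20 µm and intensity 100 on a
background of amplitude 20 with 80 µm correlation length; noise σ = 5;
30 capillary segments at intensity 150; cells at 800/mm³, radius 10 µm;
fibers at 150 starts/mm³, radius 6 µm, length 400 µm. Per-sample seeds are
a stable hash of (master seed, group, sample index), so cohorts are
bit-reproducible and enlarging a cohort never perturbs existing samples.

What the phantom does **not** emulate: stripe/shadow artifacts, depth
attenuation, stitching seams, registration error (transforms are exact),
classifier segmentation error, and anatomically realistic region shapes.
Passing phantom benchmarks therefore demonstrates that the statistical
machinery is correct and calibrated under the generator's assumptions — not
that any particular biological dataset would yield the same clusters.

## Benchmark problem sizes

The self-validating benchmark (`run_phantom_benchmark`) runs the full
pipeline on seeded cohorts and scores recovery: a configured effect region
counts as *hit* when a valid cluster of the expected direction covers more
than 10 % of the region (configurable); under a null configuration the
metric is the fraction of runs producing any valid cluster. Benchmark
analyses use a 4 px rolling-ball radius and a 50 µm smoothing sigma —
phantom leaf regions are ~250–300 µm across and the kernel must stay below
the structure of interest — with q = 0.2, minimum cluster extent 100
voxels, and 1,000 requested permutations (the 4-vs-4 design enumerates all
70 assignments exactly). With a ×3 aggregate-density effect in 2 of 12
leaves these settings recover every effect region with correct direction
and localisation in 10/10 seeded runs while zero-effect cohorts yield no
valid clusters (see `scripts/acceptance.py`).

## Known limitations

* Affine transforms only; nonlinear registration is out of scope and must
  be applied upstream.
* The rolling-ball background is the classical 2D slice-wise opening; a
  full 3D ball is not offered.
* The threshold segmenter is a deliberately simple stand-in for a trained
  pixel classifier; external masks are the intended production path.
* Exactness of permutation p-values holds for small designs (total
  assignments ≤ requested permutations); large designs use Monte-Carlo
  sampling with the (b+1)/(M+1) convention.
* The choice among candidate FDR q values is a user decision; the library
  does not automate "most stringent q producing clusters".
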