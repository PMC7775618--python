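# Methods

## Model and pipeline

A bundle is a set of streamlines {vᵢ(t) | i = 1…n}, each an ordered
sequence of 3D scanner-space coordinates in mm, with t = 1…mᵢ. All
geometry is computed in mm space; TRK files are converted out of their
voxel-order convention at read time, and anisotropic voxel headers are
rejected (the descriptors assume one isotropic spacing) unless the user
forces a voxel size.

The processing order mirrors how the descriptors are meant to be used
on real tractography: candidate streamlines are first labeled against a
co-registered reference bundle set by shortest Hausdorff distance and
filtered at a 16 mm cutoff; the surviving bundle is cleaned by
topology-informed pruning; the cleaned bundle is then measured.

### Recognition

The symmetric Hausdorff distance between two polylines' point sets is
the larger of the two directed nearest-point maxima. Because the
discrete Hausdorff distance depends on point density, both candidate
and reference streamlines are resampled to a common maximum step
(default 1 mm) before comparison; the candidate inherits the label of
the reference bundle containing its nearest trajectory. Ties between
equidistant reference bundles resolve to the first bundle name in
sorted order, so results do not depend on insertion or iteration order.
The choice of the symmetric (rather than directed) form is a
convention of this package; both forms coincide for well-matched
trajectories and the tests cover the symmetric form only.

### Topology-informed pruning

Genuine white-matter streamlines travel in bundles or sheets; noisy
ones wander through voxels few other streamlines touch. Each pruning
iteration recomputes the voxel-wise streamline density on the source
grid (a streamline touching a voxel several times counts once) and
removes every streamline passing through a voxel with count ≤ 1. The
cutoff of 1 is the minimal reading of "low density" and is exposed as a
parameter; removal is whole-streamline, never partial trimming. Up to
20 iterations run by default, with early stop at a fixed point. If an
iteration would empty the bundle — the thin-bundle pathology — the run
either raises with the offending iteration number or, with
`keep_last`, returns the previous state with a warning.

### Voxelization

Streamlines are resampled so every consecutive-point gap is strictly
smaller than the target spacing (new points by linear interpolation on
existing segments, so arc length and endpoints are preserved exactly;
endpoints are kept bit-identical). Coordinates are then multiplied by
an integer scale (default 2) relative to the source grid and rounded
half-away-from-zero; duplicates are removed. The effective spacing is
voxel_size/scale — 0.5 mm on a 1 mm grid — and the per-voxel volume is
its cube (0.125 mm³), 8× smaller than the source voxel. Surface voxels
are foreground voxels with at least one zero neighbor, computed as the
binary-erosion residue with a zero border (default 6-connectivity;
26 available). Connected components (default 26-connectivity, since
end-surface sheets often touch diagonally) are ordered largest-first
with lexicographic tie-break.

### End surfaces

Streamline storage direction is arbitrary, so endpoints are split into
the two bundle ends with a constrained two-cluster iteration: k-means
with k = 2 modified so the two endpoints of one streamline always land
in different clusters. Initialization assigns every first point to
cluster 1 and every last point to cluster 2; each pass recomputes the
cluster means in mm space and, per streamline, keeps or swaps its
endpoint pairing according to which assignment has the smaller summed
distance to the means (exact ties keep the current assignment, for
stability). Iteration stops when no endpoint moves; non-convergence
within `max_iter` (default 100) returns the current state with a
warning flag. The converged clusters are voxelized with the same
scale-2 convention as the bundle, giving E₁/E₂; E₁ is the cluster with
the larger mean on the axis of largest inter-mean separation (axis
ties prefer z, then y, then x). One degenerate case is worth knowing:
with exactly two anti-parallel streamlines the initial cluster means
coincide and every pairing ties, so the iteration stays at its
(mixed) initialization — with three or more streamlines the symmetry
is broken and mixed orientations are corrected.

The disk-model radius uses the fact that a uniform distribution over a
disk of radius r has mean distance 2r/3 to the center; the estimate is
1.5 × the mean voxel distance to the surface centroid. The trunk is the
sub-bundle whose E₁ endpoint voxel lies in the largest connected
component of E₁ and whose E₂ endpoint voxel lies in that of E₂ (exact
voxel membership, no dilation); its volume is the voxelized volume of
that subset.

### Statistics

Test-retest reliability is ICC(1,1): with n subjects and k = 2
sessions, ICC = (MS_between − MS_within)/(MS_between + MS_within) from
the one-way ANOVA decomposition. Values ≥ 0.75 are "good", [0.5, 0.75)
"moderate", < 0.5 "poor"; negative estimates are reported as computed.
Asymmetry uses two-sided paired t-tests with star thresholds 0.05 /
0.01 / 0.001, a percentage difference 100·(a − b)/a with a the
larger-mean (dominant) side, and Cohen's d. The d denominator defaults
to the paired form sd(differences), matching paired-t reporting; a
pooled-sd form is available via `d_form="pooled"`. No multiple-testing
correction is applied by default. Between-subject variation is
|x − median|/median per subject, summarized by median and quartiles.

## Synthetic bundles

The generators replace a tracking pipeline for testing: straight
cylinders (parallel streamlines, transverse positions uniform over the
cross-section disk by sqrt-radius inversion), circular-arc tubes
("C-shaped" bundles), paired test-retest copies (independent Gaussian
jitter and streamline drops), and planted stray streamlines offset
well outside the core. Ground-truth descriptors are attached from
closed forms (cylinder: volume πD²L/4, surface πDL + πD²/2,
end-surface radius D/2; arc of angle θ: curl = θ/(2 sin(θ/2))), never
from the pipeline under test. Default axial point spacing is 0.4 mm,
below the 0.5 mm effective spacing, so voxel traces are connected
without extra resampling. The generators emulate bundle geometry and
test-retest perturbation structure only; they do not emulate crossing
fibers, curvature-dependent tracking failure, partial-volume effects
or spatially correlated scanner noise, so passing tests demonstrate
correctness of the measurement machinery, not tractography accuracy on
real data.

Test and benchmark problem sizes are chosen so that cylinders are
covered at roughly four expected streamlines per voxel column
(coverage ≈ 98%, emulating dense cleaned bundles); disk calibration
checks use 1–2 × 10⁵ point samples.

## Numerical behavior and known limitations

- Voxel-occupancy estimates measure the streamline envelope dilated by
  up to half a voxel per side: at dense coverage the volume of a
  cylinder of radius R is overestimated by ≈ 2h/R (h = effective
  spacing), i.e. +21% at D = 5 mm, +13% at D = 10 mm, +8.6% at
  D = 15 mm at h = 0.5 mm; diameter errors are roughly half. With
  partial coverage the undercount offsets part of the dilation.
  Thin-bundle volumes and diameters should therefore be read as
  envelope measures, not tube measures.
- Surface-voxel counting overestimates curved surface areas (a voxel
  staircase is longer than the smooth surface it approximates); the
  cylinder lateral surface is overestimated by up to ~25%. Surface
  triangulation would reduce this and is out of scope.
- The surface count of a sparsely covered bundle is the most
  phase-sensitive quantity under sub-voxel translation, since ragged
  boundary voxels flip in and out of the surface set.
- Curl refuses bundles with mean span below 0.1 mm (closed loops)
  rather than returning a huge value.
- ICC is undefined for zero total variance and fewer than 3 subjects;
  the paired t-test is flagged degenerate when the difference variance
  is zero.
- All stages are deterministic given inputs and configuration; the only
  randomness lives in the synthetic generators, which take explicit
  seeds.
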