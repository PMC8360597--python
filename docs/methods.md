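# Methods

## The model

At each time index *t*, the masked fMRI acquisition is a finite set of
voxels with stereotactic coordinates (x, y, z) and a BOLD amplitude
f(x, y, z, t).  Each voxel is embedded as the point
(x, y, z, f_norm(x, y, z, t)) in 4-D Euclidean "stereotactic hyperspace",
so that voxels of very different amplitude are far apart even when
anatomically adjacent.  Per-timepoint topology is summarized by the
persistent homology of this point cloud: each homology class (component,
loop, or void) has a birth radius and a death radius, and
persistence = death − birth measures the geometric scale of the feature.
Loops (H1) are the objects of interest: a loop of distinctly elevated
amplitude wrapped around a depressed region (or vice versa) appears as a
high-persistence H1 class.

The dynamics of this structure over an acquisition are captured by a
*vineyard*: the per-timepoint diagrams stacked along a time axis, with an
edge between every pair of H1 features at consecutive indices shaded by the
3-D Hausdorff distance between their representative loops.  A *vine* is a
spatially constrained, temporally coherent chain of features, possibly
intermittent.  Whether a vine is task-responsive is decided by a
block-permutation test on the vine-stripped diagrams using a Wasserstein
within-group cohesion statistic.

## Normalization

Amplitudes are unitless, coordinates are spatial; before they can share a
Euclidean metric, the amplitude axis is rescaled by the unique increasing
linear map whose image minimum equals a0 (the average of the per-axis
coordinate minima) and whose image maximum equals a1 (the average of the
per-axis maxima).  The normalized amplitude range therefore equals the
average of the three spatial coordinate ranges, with no free parameters.
Two deliberate choices:

* **Series-wide extremes.**  f_min and f_max are taken over all time
  indices jointly.  Per-timepoint normalization would pin every diagram to
  the same amplitude range and erase exactly the cross-time dynamics the
  vineyard is built to expose.
* **Contract over closed form.**  The construction is *defined* by the
  min→a0 / max→a1 contract.  The shorthand formula
  f_new = (f − a0)/(a1 − a0) sometimes quoted for this construction does
  not satisfy the contract for general amplitude ranges (f in [100, 200]
  with a0 = 0, a1 = 10 would land in [10, 20], not [0, 10]); the contract
  is what is implemented and tested.
* **Degenerate input.**  A constant-amplitude series maps to the midpoint
  (a0 + a1)/2, the symmetric limit of the linear map as f_max → f_min.

Consequences that are tested rather than assumed: multiplying all spatial
coordinates by c > 0 and re-normalizing scales every hyperspace distance —
and hence every birth and death radius — by exactly c (equivariance under
a change of spatial units).  `scale_amplitude` dials the amplitude scale
about its mean: dialed very high, the cloud degenerates toward a line and
H1/H2 trivialize (no class above a 1e-6 relative persistence floor);
dialed very low, the cloud collapses onto the bare voxel lattice, where
every square of adjacent voxels contributes a loop born at radius 0.5
(half the voxel spacing) and dying at √2/2.  The √2/2 death follows from
the Rips geometry of a unit square; a death at 2× the birth radius, which
is sometimes informally stated for this configuration, is not what the
mathematics gives, and the tests pin (0.5, √2/2).

## Persistence computation

The Vietoris–Rips filtration stands in for the Čech construction, with the
**radius convention**: a simplex enters at half its diameter, i.e. when
balls of radius r centred at its vertices pairwise intersect.  The
filtration is truncated at r_max (default 12, matching the scale of a
masked ROI in voxel units): classes still alive there are reported as
truncated, never given a fake death, and raising r_max can only add
information — existing finite pairs never move (tested).

Persistence pairs are computed by the standard left-to-right column
reduction of the boundary matrix over GF(2), with simplices totally
ordered by (radius, dimension, lexicographic vertex tuple).  The
tie-breaking matters: lattice data produce massive radius ties, and the
total order makes the reduction — and every representative — reproducible
bit for bit.  Zero-persistence pairs are dropped.  Representatives: a
finite H1/H2 class takes the cycle stored in the reduced column of the
simplex that kills it; a truncated class takes the chain accumulated for
its birth column (the V-column of the R = ∂V bookkeeping).
Representatives are not canonical (no choice is), but these are
deterministic, and the H1 ones are verified to be even-degree closed edge
sets living below the death radius.

H2 is opt-in (max_dim = 2) with a hard 400-point cap because it requires
enumerating 3-simplices; H1 runs cap at 2500 points.  Correctness is
checked two independent ways: an oracle that recovers the full diagram
from persistent Betti numbers (GF(2) kernel/rank linear algebra, no
pairing algorithm shared with the implementation) on hundreds of random
clouds in dimensions 0–2, and closed-form worked examples (unit square,
displaced-center cube shell, cylinder lattice).

## Vineyards and vines

Edges link **all** cross pairs of H1 features at consecutive time indices;
the shade is the linear clamp 1 − d/d_ref with d_ref = 4 stereotactic
units by default.  Only monotone darkness is semantically required; the
linear clamp is the simplest monotone choice and makes shade 0 an exact
prunability criterion (shade-0 edges may be dropped from storage with no
loss).  Hausdorff distances are computed in 3-D stereotactic space only —
the amplitude coordinate is excluded, because the question the vineyard
answers is *anatomical* proximity of loops.

`extract_vine` strips each diagram to the H1 features whose representative
centroid lies in a chosen stereotactic box and whose persistence (r_max −
birth for truncated features) reaches the floor, default 0.8.  Centroid
membership rather than all-vertices membership is used so a single stray
vertex does not evict a loop.  Empty time indices are retained as empty
diagrams: intermittent presence is signal.

Manual vine selection is not reproducible, so `rank_vines` provides a
deterministic surrogate: features are chained whenever consecutive-index
representatives are within d_link (default d_ref/2), chains are scored by
(total persistence) × (number of distinct time indices), and each chain is
returned as its representative bounding box padded by d_link/2.  It is
validated only against synthetic ground truth, where the top-ranked box
reliably covers the embedded loop.

## The permutation test

For two conditions (default encoding vs retrieval; consolidation blocks
are excluded from both groups), the statistic is

    S = Σ_groups  mean over unordered within-group pairs of W_q(D_i, D_j)^q

with q = 2 and sup-norm ground metric.  W_q is computed exactly by optimal
assignment on the diagonal-augmented cost matrix; unmatched points pay
(death − birth)/2, their sup-norm distance to the diagonal, so an empty
diagram is simply a diagram all of whose partner's points go to the
diagonal.  Small S means label-aligned cohesion, so the p-value counts
permuted statistics ≤ the observed one, with the plus-one estimator
(1 + #{S_perm ≤ S_obs}) / (1 + n_perm).  Labels are permuted at the level
of whole contiguous blocks of the two tested conditions only, preserving
within-block temporal autocorrelation; with 8 blocks per condition there
are C(16, 8) = 12870 distinct assignments.  The underlying framework names
its ingredients but not one canonical formula; the within-group
mean-pairwise form above is the closest published joint-loss variant and
is flagged as a reconstruction.  n_perm defaults to 4999; every run
records its seed and is bit-reproducible.

## Synthetic data

The generators emulate the study conditions end to end with no download:

* `make_design()` — 4 conditions × 9 samples per 27 s block at TR = 3 s ×
  8 cycles = 288 time indices (encoding, consolidation, retrieval,
  consolidation).
* `task_series` — lattice amplitudes = baseline + iid Gaussian noise
  (sd 0.1 by default; an AR(1) option exists for autocorrelation-sensitive
  checks), plus a ring of elevated amplitude around a depressed core with
  ring-minus-core contrast 4 lattice units during encoding and 0 otherwise.
  The contrast default was chosen so that the loop's persistence clears the
  0.8 vine floor with comfortable margin on a 7×7×1 grid (measured ≈ 0.97
  at contrast 4 vs ≈ 0.82 at contrast 3, which noise would straddle);
  "switched on only during encoding" mirrors the task-responsive loop the
  workflow is designed to find.
* `bumpy_cube` — the 27-point displaced-center cube: at ball radius 0.6
  the 26-point shell is one single-linkage component (the displaced center
  is isolated) and encloses a positive-persistence H2 void.
* `cylinder_cloud` — a tube-surface lattice whose first homology is
  one-dimensional: exactly one dominant H1 class.
* `ring_volume` — high-amplitude core, low amplitude on and beyond the
  surrounding ring.  Two levels, not three: an intermediate exterior level
  would create a second large annulus loop and destroy the single-dominant-
  loop ground truth the fixture exists to provide.

What the generators do *not* model: hemodynamic response shape, spatial
autocorrelation, scanner noise spectra, drift.  Passing tests therefore
demonstrate that the machinery recovers planted topological structure
under iid (or AR(1)) Gaussian noise at realistic contrast — not that real
acquisitions contain such structure.

## Problem sizes and numerical choices

All validation runs are desk-scale by construction: grids of ≤ a few
hundred voxels so a full per-timepoint Rips H1 reduction takes
milliseconds to seconds.  Specifically: the cylinder check uses a 12 × 5
lattice of radius 3; the null-calibration study uses 200 replicates of a
5×5×1 grid with 3-sample blocks and 8 cycles (96 indices) — 8 blocks per
tested condition are retained because with fewer blocks the permutation
distribution (C(2k, k) values) is too coarse to calibrate a 0.05-level
test, and the measured null rejection rate at α = 0.05 is 0.03; the
power and end-to-end checks run the full 288-index design on a 7×7×1 grid
and reject with p ≈ 0.001–0.002.  Diagrams fed to vineyards use a
persistence floor of 0.3 to discard lattice-square clutter (persistence
≈ 0.21) while keeping any loop that could reach the 0.8 vine floor.

Other numerics: exact float equality is used to drop zero-persistence
pairs (tied radii are computed from identical distance entries, so the
equality is exact); amplitude bounds are validated with closed intervals;
the constant-amplitude degenerate case maps to the midpoint; Wasserstein
on two empty diagrams is 0.

## Known limitations

* Representative cycles, and hence vineyard shading and `rank_vines`
  chains, are deterministic but not stable under perturbation; averaging
  over sampled representatives would be the robust extension and is not
  implemented.
* One vine, one test: no omnibus multi-condition statistic and no
  multiple-testing correction across candidate vines — testing the
  top-ranked vine on the same data used to rank it inflates significance,
  so confirmatory p-values should come from a region fixed a priori.
* Whole-brain Rips persistence is out of computational reach by design;
  the point caps enforce ROI-scale inputs.
* The NIfTI adapter is a convenience; the CSV table path is the reference
  representation.
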