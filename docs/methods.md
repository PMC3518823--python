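# Methods

## Model and assumptions

A streamline is an ordered 3-D polyline in millimeters; the curve it
traces is directionless, so a streamline and its point-reversal are the
same object.  The package models streamlines as piecewise-linear: arc
length, resampling and all distances are computed on the polyline itself,
never on a fitted spline.  Clustering assumes nothing about anatomy — a
"bundle" is any group of streamlines mutually close under the MDF metric
at the chosen threshold, which may or may not coincide with an anatomical
tract.

The clustering pass is **online and order-dependent**: each streamline is
placed once, by comparing against the running centroids of the clusters
created so far, and never moved.  When bundles are separable — intra-bundle
MDF below θ around any running centroid, inter-bundle MDF above θ — every
processing order yields the same partition (tested).  Otherwise the
partition depends on order; the permutation-stability driver quantifies
how much, and OMA between shuffled runs is the agreement measure.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| θ (clustering threshold) | mm | 10 (CLI) | MDF radius below which a streamline joins a cluster; strictly `<`. There is no universal value: small θ splits, large θ merges. |
| K (discretization) | points | 12 | points per streamline after equal-arc resampling; 2K distances per MDF. K=12 trades shape fidelity against memory and speed; even K=3 clusters usefully. |
| adjacency θ (metrics) | mm | = clustering θ | non-strict `<=` MDF radius for coverage/overlap/bundle adjacency. |
| min length filter | mm | 0 (off) | drop short streamlines before clustering; 40 mm is a typical whole-brain choice. |
| MAM variant | — | min (attachment), mean (general) | `min` pulls fragments toward full-length bundles; `max` is the classical mean-Hausdorff flavor. |

Streamline ids are 1-based everywhere, including label files.

## Numerical choices

* **Join rule is strict** (`m < θ`), so a distance exactly θ starts a new
  cluster; **adjacency is non-strict** (`<= θ`).  The asymmetry is kept
  deliberately so each statistic matches its definition exactly.
* **Ties**: argmin over clusters takes the lowest cluster index; a
  direct/flipped distance tie keeps the direct orientation.  Both rules
  make runs bit-reproducible.
* **Centroids are never cached**: `v = h/n` is recomputed at each
  comparison, so a cluster's centroid always reflects all members inserted
  so far.
* **Flip bookkeeping**: the orientation used when adding each member is
  recorded, so `h/n` provably equals the mean of the flip-corrected
  members (asserted against a from-scratch recomputation in the tests).
* **Rectangular assignment** for OMA conceptually zero-pads the
  cross-classification matrix to square; zero-agreement matches are
  dropped from the returned mapping.  OMA is normalized by the total
  streamline count Σx — the only normalizer that makes OMA(a, a) = 100%.
* **Overlap undefined** (no covered streamlines) returns NaN rather than
  raising, so tabulated reports can carry the sentinel.
* **Resampling residuals.** Equal-arc resampling places points at equal
  arc positions *of the input polyline*; the chords of the output cut
  corners, so output chord lengths are equal only up to the input's
  sampling density (≈4·10⁻⁴ relative spread for a 2-turn helix sampled at
  200 points, ≈2.5·10⁻⁶ at 2000).  For the same reason resampling is
  exactly idempotent only on polylines whose segments are already equal
  chords (straight lines, unit-step polylines); on dense smooth curves it
  is idempotent to the sampling resolution.  Tests assert the exact
  property at its fixed points and the approximate one at realistic
  tolerances.  Endpoints are preserved bit-exactly in all cases.
* **Degenerate inputs**: zero-length streamlines resample to K copies of
  the shared point; an empty tractography clusters to an empty map;
  single-point "streamlines" are rejected.
* `.trk` files store float32, so round-trips are exact to ~10⁻⁴ mm; the
  text polyline format uses `repr` doubles and is lossless.

## Synthetic phantoms

The generators emulate the geometric situations that stress the
algorithm, not diffusion physics or brain anatomy:

* **three_bundle_phantom** (450 streamlines, 200 points each, ~100 mm
  scale): a pencil of helices with linearly varying pitch (radius 5 mm,
  2 turns, pitch 4.5–6.0 mm/rad) sharing a start point; a fan of rays on
  a corrugated sheet with sinusoidal lateral bending, rotated to climb the
  helix axis; and a plain corrugated fan placed ~45 mm away.  The
  geometry was fixed so that all three bundles separate cleanly at
  θ = 1 mm (minimum inter-bundle MDF ≈ 5 mm) while the helix and bent-ray
  bundles merge at θ = 8 mm and the distant fan never mixes.  The linear
  parameter spacing makes the envelope independent of N, which is what
  lets the distance-evaluation count scale linearly when N doubles.
* **dense_phantom** (750 streamlines): the same three families with
  member parameters drawn from beta distributions over widened ranges, so
  each bundle has a dense core and sparse fringes.  This reproduces the
  density inhomogeneity of real tractographies that makes uniform random
  subsampling a poor summary — the regime in which centroids achieve
  strictly higher coverage and strictly lower overlap than an equal-count
  random subset.
* **parallel_line_grid**: uniformly spaced straight lines, the analytic
  best/worst case.  Clustering in spatial order partitions the grid into
  equal consecutive runs (run length ⌈2θ/spacing − 1⌉).  The out-of-phase
  partition is obtained by clustering the grid extended with half a run
  of extra lines and restricting to the original ids, which shifts every
  boundary by half a run width; the OMA of that pair is exactly 50% up to
  edge runs, and 100% for coincident partitions.
* **truncate_copies**: clips each source streamline to random arc-length
  sub-intervals — the "broken streamline" fixture for the short/long
  strategies.

What passing these tests does *not* show: robustness to scanner noise,
curvature distributions of real white matter, crossing/kissing fiber
configurations, or inter-subject variability.  The phantoms are
single-parameter families with known ground truth; real tractographies
are not.

## Short-streamline strategies

Because MDF matches corresponding points, a fragment of a long streamline
is far from it under MDF — short and long streamlines cluster apart.  Two
post-hoc remedies are provided: (1) `assign_short_streamlines` attaches
each short streamline (optionally pre-clustered at a caller-chosen
threshold — no default is imposed) to the long cluster minimizing the MAM
min distance, resampling to the long K before updating the running sums;
(2) `expand_cluster` grows a bundle from one representative: MDF
neighborhood → sub-clustering → MAM-min sweep of the whole tractography,
returning the union of the first and last stages.

## Problem sizes

The test suite and the acceptance script run at desk scale: a 400-line
grid for the agreement limits, 10,000 random triples for the metric
axioms, 500 random matrices (≤6×6) for the assignment oracle, the
450-streamline phantom for merge/split and centroid checks, the
750-streamline dense phantom for the reduction comparison, and 450 vs 900
streamlines for the evaluation-count scaling.  The whole suite completes
in a few seconds on one CPU.

## Known limitations

* Order dependence is intrinsic; only separable data are
  permutation-invariant.
* MDF requires a common K; comparisons across different discretizations
  must resample first (the metrics refuse mismatched K rather than
  silently resampling).
* Cluster centroids are means of polylines, not medial axes: for strongly
  curved merged clusters the centroid may lie in empty space between
  members.
* The `.trk` writer records an identity voxel-to-world transform;
  downstream tools that expect voxel-grid headers should regrid.
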