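# Methods

This note records the models and procedures implemented in `abcells`,
the assumptions behind them, the defaults that matter, and the places
where the design was genuinely open.

## Geometry and static morphometry

A cell footprint is an implicitly closed simple polygon in pixel
coordinates (x right, y down). Area and perimeter come from the
shoelace formula and the vertex-chain length, converted to micrometers
with the pixel calibration (default 0.5199 µm/px, the calibration of
the reference microscope). Circularity is 4πA/P², which is 1 for a
disc and strictly below 1 otherwise; regular n-gons approach 1 from
below as n grows, which the tests use as a sanity bound.

Shape moments (central moments to order 3, scale-normalized moments,
Hu invariants) are computed **analytically** from the polygon boundary
via Green's theorem rather than from a rasterized mask. The analytic
route is exact at any scale — sub-pixel test geometry stays
well-conditioned — and is strictly invariant to translation, which the
tracker's appearance matching relies on. Intensity statistics, which
need pixel support, use a rasterized mask (pixel-center-in-polygon);
the two supports differ by at most the boundary layer, and a test
cross-checks the analytic moments against a brute-force pixel oracle
at large scale.

The equivalent-ellipse fit takes eigenvalues λ₁ ≥ λ₂ of the second
central moment (covariance) matrix: full axes 4√λ, eccentricity
√(1 − λ₂/λ₁), orientation ½·atan2(2µ₁₁, µ₂₀ − µ₀₂) mapped into
[0, 180). An isotropic region has no meaningful axis; by convention it
reports eccentricity 0 and orientation 0. Orientation is reported over
the full [0, 180) range; no folding to [0, 90] is applied because a
fold silently conflates perpendicular alignments.

The cell boundary's "smoothness index" is implemented as convex-hull
perimeter over polygon perimeter (1 for convex outlines, smaller for
ruffled ones). This is one reasonable convexity-style roughness
measure among several; it was chosen because it needs no tuning
parameter and pairs naturally with solidity (area ratio to the hull).

The tracker's appearance descriptor concatenates 7 intensity
statistics (mean, std, min, max, median, skewness, kurtosis), the 7 Hu
moments, 7 normalized central moments (µ11, µ20, µ02, µ21, µ12, µ30,
µ03), solidity, aspect ratio and fill factor — 24 components — and is
L2-normalized so that cosine similarity is an inner product. Without
an intensity image the 7 intensity slots are zero before
normalization; the block split 7+7+7+3 is a design choice fixing the
total at 24.

Centroids default to the area centroid (first moments). The mean of
boundary vertices is available as a compatibility alternative but is
sensitive to vertex density, so it is not the default.

## Detection ingest

YOLO segmentation text (class id + normalized polygon per line) is
scaled to pixels on read; writing is the exact inverse and round-trips
to 1e-6 relative. The classical fallback runs optional flatfield
division (Gaussian background, σ = min(image side)/8), local adaptive
thresholding, morphological closing, and connected-component
polygonization. Components with pixel area strictly below 100 px² are
dropped — a component of exactly 100 px survives. The adaptive
threshold carries a contrast-relative offset (default 1% of the image
range) so that flat regions do not fire on floating-point noise; being
range-relative it preserves invariance to additive intensity offsets.

Tile stitching translates tile-local detections to global coordinates,
then greedily suppresses near-duplicates (IoU ≥ 0.8, keeping higher
confidence, ties broken by larger area then lower tile index) and
union-merges partial overlaps from *different* tiles
(0.3 ≤ IoU < 0.8), the typical seam case. Both thresholds are
configurable; the defaults are the package's own choice.

## Tracking

Track state holds the last polygon, an exponentially weighted (α = 0.3)
appearance vector re-normalized after every update, an EWMA area, a
velocity estimate (EWMA of centroid displacement), age, missed count,
generation index and parent link. Matching proceeds in passes:

1. **Stage 1** — Hungarian assignment of active tracks to detections
   with adaptive gate g = 50 px + 2‖v‖ and cost ceiling 0.6.
2. **Stage 2** — unmatched active tracks × unmatched detections with
   gates doubled and ceiling 0.8 (handles sudden accelerations and
   shape changes).
3. **Split recovery** — when two detections each overlap one track's
   predicted polygon with IoU ≥ 0.2, the better-overlap detection
   continues the parent id and the other spawns a child with
   generation + 1 and a recorded split event. Single-child inheritance
   (rather than archiving the parent and creating two children) keeps
   id continuity for downstream trajectory analysis; which daughter
   inherits is decided by overlap and is inherently arbitrary between
   near-symmetric daughters, so ground-truth evaluation associates the
   parent id using frames strictly before the division.
4. **Merge arbitration** — a track whose best feasible detection was
   won by a cheaper competitor goes occluded and the event is counted
   as a merge.
5. **Re-identification** — tracks with missed detections are excluded
   from stages 1–2 and can only return through an appearance-gated
   re-ID pass: cosine similarity of EWMA features ≥ 0.9 and distance
   within a gap-scaled gate. Pairs are taken globally in order of
   distance because appearance alone discriminates weakly between
   label-free cells of similar shape. Tracks missing longer than
   30 frames are archived permanently.

Frame metrics report track count, mean matched IoU, split/merge/re-ID
counts and continuity (fraction of previously active tracks matched).
Live id switches are not observable without ground truth, so the live
proxy is the re-ID count; true id switches are computed by the
evaluation harness, which associates predictions to truth per frame by
IoU ≥ 0.5 and counts MOT-style association changes.

Cost weights default to (0.4, 0.3, 0.2, 0.1) for IoU, distance,
appearance and area. All constants live in `TrackerConfig`; none are
claimed to be optimal — they are a working point validated on the
synthetic benchmark (perfect identity preservation at cell separations
above twice the base gate, split recall 1.0 on forced divisions).

## Baseline linker and motility metrics

The centroid-only linker (for mask pipelines without the full tracker)
links mutual nearest neighbors under a 10 µm-per-step bound, treats the
bound as inclusive ("maximum displacement" semantics), bridges gaps of
up to 2 missing frames by linear interpolation (flagged per point,
allowed distance scaling with the elapsed steps), and otherwise starts
new tracks.

Kinematics use µm/frame as the canonical unit with the frame interval
(default 350 s) carried as metadata; a µm/s view is provided. The
twelve trajectory descriptors follow their standard definitions; the
ones with conventions worth stating:

- **MSD** is the from-origin average (1/T)·Σ‖r_k − r₀‖², a single
  scalar per track. The lag-resolved time-averaged MSD is provided
  separately (`msd_lag`) and is what the diffusive-scaling tests fit —
  for an isotropic 2-D random walk with per-axis step σ its slope is
  2σ².
- **Turning angles** are unsigned angles between successive nonzero
  displacement vectors; zero-length steps carry no direction and are
  skipped rather than counted as 0°. A trajectory that never moves
  reports angle metrics as missing (NaN), not zero.
- **Arrest coefficient** is the fraction of steps with speed strictly
  below 0.2 µm/frame ("fell below" is strict, so a cell at exactly the
  threshold is not arrested); it is monotone in the threshold.
- **Meandering index** and **directionality ratio** are the same
  quantity (net displacement over path length) and are reported under
  both names to keep the twelve-column schema; values are in [0, 1]
  with 1 only for straight monotone paths.
- **Shape–motion coupling** is the Pearson correlation of per-frame
  area against the speed into that frame; **velocity
  cross-correlation** is the Pearson correlation of the x and y step
  components. Both are NaN when either variable is constant.
- **Sharp turns** (fraction of turning angles above a threshold,
  default 90°) are available as a separate diagnostic.

Aggregation is two-sided: *dynamic* summaries average instantaneous
values over each track's lifespan (one row per track, the
twelve-metric profile); *static* summaries average instantaneous
values over the cells present at each frame (one row per frame).

## Time-series statistics

Condition series of one metric are compared as a k × T panel. Each
series is smoothed with a centered moving average (window 15, full
windows only), then windows of 15 smoothed frames slide by 1. Within a
window, each frame position is a block and each series a treatment;
the classical Friedman statistic (mid-ranks, tie-corrected, verified
against an independent implementation to 1e-9) is computed and two
significance routes are taken:

- **Bartlett correction.** Per-series lag-1 autocorrelation Q
  (Σ adjacent deviation products / Σ squared deviations) is averaged
  into a panel Q, clamped to [0, 0.99] — negative Q would inflate the
  effective sample size above N, which would be anti-conservative.
  N_eff = N(1−Q)/(1+Q), and the statistic is scaled by N_eff/N before
  the χ²(k−1) lookup. At Q = 0 this reduces exactly to the classical
  test. The correction is applied as variance-style deflation of the
  statistic because "corrected degrees of freedom" has no unique
  χ² analogue for non-integer N_eff. Windows with N_eff < 3 are
  reported untestable (p = NaN) rather than forced through the
  asymptotic approximation.
- **Permutation.** Treatment labels are shuffled independently within
  each block (B = 1000, seeded, add-one estimator
  p = (1 + #{perm ≥ obs})/(B + 1), so p ≥ 1/(B+1) and never 0).

The two routes have different validity domains, and this matters for
interpretation. On raw, exchangeable panels the permutation test is
exactly calibrated (type-I error ≈ α, verified over 500 seeded
panels). On *smoothed* windows, adjacent blocks are strongly
dependent; within-block shuffling breaks that dependence in the null
ensemble, so the permutation p becomes anti-conservative there —
under strong smoothing the N_eff-corrected test is the operative
error control, and simulations show it rejecting an AR(1)-null far
less often than the uncorrected test. Post hoc Conover pairwise
comparisons (rank-sum differences against a t reference with
(N−1)(k−1) df, Holm step-down) are run when the omnibus is
significant at α = 0.05, using the corrected asymptotic p where
testable and the permutation p otherwise.

Bootstrap CIs are percentile intervals of the mean over B = 10 000
seeded resamples; a confidence level of 0 degenerates to the point
estimate. Distributional distances are the two-sample KS statistic
and the 1-D Wasserstein distance; no p-values are attached to them.

## Synthetic data

The generator defines the benchmark conditions for everything above.

- **Motion models** (units px/frame): Brownian (Gaussian steps, σ),
  persistent (constant speed, heading diffusing with wrapped-normal
  noise scaled by (1−φ)·π), directed (fixed drift), arrested
  (two-state Markov switch between Brownian movement and full stop) —
  the last emulating the episodic bursts typical of cultured stem
  cells.
- **Scenes**: cells seeded on a jittered grid without initial overlap,
  rendered as 16-vertex noisy ellipses (aspect 1.2–3), reflecting
  boundaries. Divisions replace the parent with two daughters at 60%
  parent area, offset ±0.6 semi-major axes along the parent's major
  axis; daughters inherit the parent's orientation and aspect ratio
  (fresh boundary noise) so that splits remain geometrically
  recoverable by the IoU ≥ 0.2 rule. Dropouts withhold a cell's
  detection for 1–3 frames and are recorded in the truth. Benchmark
  scenes default to 20 cells × 100 frames at inter-cell spacing above
  twice the tracker's base gate — the regime in which identity errors
  indicate tracker defects rather than irreducible ambiguity.
- **Panels**: X_g(t) = µ_g(t) + φ(X_g(t−1) − µ_g(t−1)) + ε,
  ε ~ N(0, sd²), with per-group offsets optionally switching on at a
  changepoint.

All randomness flows through NumPy's PCG64 generator with explicit
seeds; same seed gives byte-identical outputs. What the generator does
**not** emulate: realistic textures and intensity profiles (appearance
re-ID is therefore tested only in its geometric/shape regime),
cell–cell contact and overlap, segmentation noise correlated with
shape, drift or illumination artifacts beyond an optional constant
gradient, and apoptosis. Passing tests therefore certify the
algorithms under controlled conditions, not end-to-end performance on
real microscopy.

## Numerical and interface choices

- Assignment uses `scipy.optimize.linear_sum_assignment`; infeasible
  pairs carry a sentinel cost and are stripped from the result. Tests
  verify optimality against exhaustive permutation for n ≤ 7.
- Gated pairs skip IoU computation entirely, keeping dense frames
  near-linear in practice.
- Sliding-scan permutation seeds are spawned per window from a single
  `SeedSequence`, so results are reproducible and independent of
  window count.
- Stage outputs are CSV/JSON with fixed headers plus a manifest
  (config hash, seed, input checksums, package version). Overlay PNGs
  and a SQLite mirror of the tables are opt-in.
- Problem sizes in the test-suite simulations (500 calibration panels,
  500 random-walk tracks, 300 bootstrap replicates, 20-cell scenes)
  were chosen to bound the Monte-Carlo error of each asserted band
  while keeping the whole suite quick on one core.

## Known limitations

- The split detector requires daughters to overlap the parent's
  predicted footprint; divisions combined with large jumps or long
  dropouts are missed.
- Appearance re-identification is weakly discriminative for label-free
  cells of similar shape; after simultaneous neighboring dropouts at
  sub-gate separations, identities can be exchanged.
- The Bartlett correction assumes an AR(1) dependence structure; for
  strongly non-AR(1) series N_eff is only a first-order remedy.
- The within-block permutation null ignores across-block dependence
  (see above); its p-values should not be taken at face value on
  heavily smoothed windows.
- Orientation statistics are axial (period 180°); circular means of
  orientations are not provided.
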