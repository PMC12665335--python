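# Methods

## The question and the measurement design

In improvised vocal traditions such as Karnatak rāga ālāpana, singers
gesture continuously while they sing.  Beyond direct, time-locked
coupling between movement and voice, one can ask a *second-order*
question: do melodic phrases (motifs) that **sound** alike tend to
co-occur with gestures that **move** alike?  The package operationalizes
this as a comparison of two pairwise-distance structures.  For every
unordered pair of segmented motifs it computes ten dynamic-time-warping
(DTW) distances — four sonic (f0, Δf0, loudness, spectral centroid) and
six kinematic (hand/head × position/velocity/acceleration, each 3-D) —
and then correlates sonic distance columns with kinematic ones.

A positive rank correlation in a (sonic, kinematic) cell means: pairs of
motifs close in that sonic feature are also close in that kinematic
feature — a co-structuring of sound and movement, whether or not the two
signals couple instant by instant.

## Feature conditioning

Sonic series live on a 100 Hz frame grid (10 ms hop; the frame rate is a
package choice — it resolves fast melodic ornaments while keeping DTW
cheap).  The pipeline order is fixed: pitch tracking → gap interpolation
→ Gaussian smoothing → Δf0.

* **f0** — any monaural pitch track can be ingested; the built-in tracker
  is a frame-wise autocorrelation method (50 ms windows, parabolic lag
  refinement, voicing by normalized peak correlation > 0.5 and a −50 dB
  silence gate).  It is adequate for clean solo voice and for the
  synthetic harmonic fixtures; polyphonic recordings should use a
  dedicated melody extractor upstream.
* **Gap interpolation** — interior unvoiced runs of ≤ 350 ms are filled
  linearly between the flanking voiced values; longer interior gaps mark
  the motif as excluded from the distance table (excluded ids are listed
  in the run log, never silently dropped).  Interpolation precedes
  smoothing so the filter sees a gapless series.
* **Smoothing** — a truncated discrete Gaussian, σ = 2.5 samples, radius
  4σ, reflected edges.  All four sonic series are smoothed with the same
  σ.  The kernel is a convex combination, so smoothing can never leave
  the input's range.
* **Δf0** — the estimated derivative
  `D_i = ((q_i − q_{i−1}) + (q_{i+1} − q_{i−1})/2) / 2`, endpoints
  replicating the nearest interior value.
* **Loudness** — short-time total spectral power (46 ms Hann windows,
  10 ms hop) in dB re the maximum frame power, floored at −80 dB.  The
  reference extent is the parent performance when available, else the
  motif, so motifs within a performance stay comparable.
* **Spectral centroid** — magnitude-weighted mean frequency per frame;
  silent frames carry the previous defined value and are flagged.

Kinematic series (60 Hz) are conditioned per motif:

1. Savitzky–Golay smoothing, order 2, 125 ms window (7 samples at
   60 Hz — nearest odd, rounding down to favour detail).  Quadratic
   trajectories pass through unchanged.
2. A single rigid body-frame transform per motif: yaw rotation aligning
   the time-averaged shoulder line with the mediolateral x-axis, plus a
   translation putting the time-averaged pelvis centroid at the origin.
   Velocities and accelerations receive the rotation only.  A static
   per-motif frame (rather than per-frame rotation) avoids injecting the
   rotation's own time derivatives into the velocity channels.
3. Dominant-hand selection by kinetic energy `KE = Σ ½ m‖v‖²` with equal
   masses; exact ties go to the left hand.
4. x-mirroring of right-dominant motifs so all gestures occupy a common
   "left-hand space".  Head series are never mirrored.  Mirroring and the
   body-frame map are norm-preserving, so speeds and acceleration
   magnitudes are invariant.

When tracker-native velocity/acceleration are absent (always true for
synthetic data), they are derived from position by central differences.

## The alignment distance

The pairwise distance is a dependent multidimensional DTW: all axes of a
feature share one warping path and the local cost is the Euclidean norm
of the frame difference.  Two relaxations adapt it to segmented motifs,
both scaled by L, the longer length in the pair:

* **open endpoints** — the path may start and end within ⌈0.1 L⌉ frames
  of each series' extremes, absorbing segmentation jitter;
* **Sakoe–Chiba band** — cells with `L·|i/n_a − j/n_b| > ⌈0.1 L⌉` are
  excluded.  The band test is symmetric in the two inputs, so
  d(a,b) = d(b,a) holds for unequal lengths.

Steps are the symmetric {(1,0),(0,1),(1,1)} with unit weights.  The
reported distance is the minimum total path cost divided by the path's
cell count (the shortest minimizing path, with a deterministic
diagonal-first tie-break); motif durations vary several-fold and
unnormalized costs would rank pairs mostly by length.  Path
normalization and z-normalization (off by default — body-frame meters
and dB are already commensurate across motifs) are exposed as flags.

The dynamic program is verified against an exhaustive path-enumeration
oracle on short series: both implement the same admissibility rules from
independent code, and agree to 1e-9 over random lengths, dimensions,
band widths and margins.  With zero margin and a full band the distance
equals textbook fixed-endpoint DTW; enlarging the margin or the band can
only lower the unnormalized cost.

The distance is not a metric (the open ends break the triangle
inequality) but satisfies d ≥ 0, d(a,a) = 0 and symmetry.

## Analysis 1 — the co-structuring grid

For a set of table rows, each of the 4×6 (sonic, kinematic) column pairs
yields a Spearman rank correlation (average ranks on ties, two-sided
p-values).  Profiles are computed for the pooled set — motifs first
subsampled without replacement so every performer contributes the
minimum per-performer count — and for each performer (rows where both
motifs are that performer's).  Significance is Bonferroni-corrected at
α = 0.0001 divided by the total cell count of the run (96 for pooled +
three performers); insignificant cells are masked in the heatmap-ready
output.

Rows sharing a motif are not independent; p-values treat rows as
exchangeable, which matches the field's standard second-order
(representational-similarity) practice.  The calibrated control is the
**shuffle null**: every distance column permuted independently within
each (performer_i, performer_j) stratum, preserving all marginals and
row metadata while destroying pair-level coupling.

## Analysis 2 — predicting sound from movement

Each sonic distance column is regressed on kinematic distance columns
(hand = 3 hand columns, head = 3 head columns, all = 6, randomized = all
6 independently permuted across rows) with least-squares gradient
boosting of depth-limited regression trees.  Selection protocol: 80/20
split stratified by performer-pair category (the only categorical
structure in the rows); 48-point grid n_estimators ∈ {50,100,150,200} ×
learning_rate ∈ {0.001,0.01,0.1} × max_depth ∈ {2,4,8,10}; each point
scored by mean R² over 3-fold CV repeated 5 times with the same
stratification; ties broken toward fewer estimators, then shallower
trees; the winner is refit on the full training split and reported as
holdout R².  Holdout rows never touch selection or the final fit.
Because boosting is sequential, the four n_estimators values per
(learning_rate, depth) are scored from one fit's truncated predictions —
identical results at a quarter of the tree fits.

The booster itself (`costructure._boosting`) is a package-authored
exact-split CART boosting implementation (squared-error splits over all
midpoints, depth limit, minimum two samples to split), JIT-compiled for
the grid-search workload of thousands of small fits.  The test suite
cross-checks it against scikit-learn's GradientBoostingRegressor on
matched settings: predictions are identical at shallow depth and agree
to within floating-point tie-breaks elsewhere.

## The synthetic generator

The generator emulates the statistical structure the analyses assume,
not rāga grammar or biomechanics:

* **Latent classes** — each of (default) 6 classes owns smooth prototype
  curves for f0 (180 ± 40 Hz), loudness (−18 ± 5 dB, capped below 0) and
  centroid (1500 ± 350 Hz): Gaussian-smoothed random walks whose
  smoothness gives ~0.5–2 Hz undulation at typical motif durations.
* **Instances** — a motif draws a class, a duration ~ U(1.5, 4) s, and a
  random monotone time warp (bounded derivative, strength 0.3); white
  noise is added (2 Hz on f0, scaled by prototype amplitude for the
  other channels).  Emitted series are *conditioned* — the generator
  applies the same Gaussian/Savitzky–Golay smoothing the real pipeline
  would, because SynthDataset stands in for the pipeline's output.
* **Coupling** — gesture position is
  `λ·(R·s)(warped t) + (1−λ)·independent smooth curve`, where s is the
  standardized (f0, loudness, centroid) prototype value vector and R a
  per-(performer, segment) random rotation: every performer couples
  through their own mix of sonic dimensions, but each dimension keeps an
  equal variance share.  λ = 0 gives melodically uninformative gesture;
  λ = 1 makes gesture a deterministic function of class.  Velocity and
  acceleration are central differences of position, so derivative-level
  coupling is inherited, not separately injected.  The design-level
  *direct* couplings are therefore the value cells
  {f0, loudness, centroid} × {hand_pos, head_pos} plus, via the chain
  rule, Δf0 × {hand_vel, head_vel}.
* **Noise** — kinematic jitter is band-limited (5 mm, ~50 ms
  correlation), the error profile of an IMU-fusion mocap suit; white
  position noise would unrealistically dominate differentiated channels
  at 60 Hz.
* **Hands** — the dominant hand carries the coupled trajectory; the
  nondominant an independent curve rescaled so the kinetic-energy ratio
  equals `hand_dominance_ratio` (default 4; exact on noise-free runs,
  within ~10% under default noise).  Each pseudo-performer is
  left-dominant with probability 0.89.  Independent gesture components
  have fixed absolute-time smoothness (~0.25 s) so that, at λ = 0,
  gesture similarity carries no duration signature.

What the generator does **not** emulate: melodic grammar and ornament
syntax, vocal timbre, per-performer vocal ranges, drift or dropouts in
tracking, and segmentation errors.  Passing tests therefore demonstrate
that the pipeline's machinery is correct and calibrated under the
assumed statistical structure — not that real recordings will show any
particular effect size.

### A known residual at λ = 0

Exact independence of sonic and kinematic distance columns at λ = 0 is
unattainable: motif duration is a covariate of both modalities.  Δf0
amplitudes scale as 1/duration (the same prototype traversed faster has
steeper per-frame derivatives), and derivative-channel DTW distances
decrease with series length (a 0.1 L band widens in absolute frames,
buying alignment freedom), so Δf0 × velocity/acceleration cells retain
|ρ| up to ~0.3 at λ = 0 through duration alone.  Value-channel cells are
clean (|ρ| < ~0.05).  This is a property of banded, path-normalized DTW
over variable-duration segments — real data shares it — and it is why
the calibrated null is the shuffle control, which breaks row pairing and
passes at nominal rates.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script:
the calibration dataset is 3 pseudo-performers × 40 motifs (7,140 pairs)
for grid, null-calibration and power checks; λ-sweeps use 3 × 12; the
regression suite uses 3 × 10 (435 pairs), where the full 48-point
protocol runs in tens of seconds per report.  The combinatorial checks
of the full-scale design (595 motifs → 176,715 pairs) run on the pair
skeleton without recomputing distances.

## Numerical conventions

* Ranks: average on ties (scipy); p-values two-sided.
* DTW cost ties: lexicographic (cost, path length) minimum, predecessors
  preferred diagonal → vertical → horizontal; band membership uses the
  identical floating-point expression in the dynamic program and the
  enumeration oracle.
* Savitzky–Golay windows shorter than the series raise; motifs shorter
  than 7 kinematic frames (~117 ms) are not representable.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; reruns are byte-identical, including CSV
  float formatting (`%.12g`).
* The 2-D embedding export uses metric MDS on the precomputed distance
  matrix, seeded; it is a visualization aid and no statistics are
  computed on embedded coordinates.

## Limitations

* The autocorrelation pitch tracker assumes monophonic, harmonically
  clean input.
* Per-performer profiles require both motifs of a pair to share the
  performer; cross-performer kinematic comparability relies on the
  body-frame + mirroring normalization being sufficient.
* The regression's stratified holdout is per performer set and the
  pair-sharing dependence between rows is acknowledged, not corrected —
  holdout R² is an optimistic estimate of out-of-performance
  generalization.
* With ~600 motifs the full-scale table (176,715 rows × 10 DTW columns)
  is hours of single-core compute; the banded DP is O(band·L) per pair
  and parallelizes trivially across pairs if needed.
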