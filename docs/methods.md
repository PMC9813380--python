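# Methods

## Scope and model

`semgmap` studies how the two segmentation parameters of instantaneous
HD-sEMG activation maps — window length `N` (samples) and hop `R`
(overlap = 1 − R/N) — bias the maps' image features and the geometry of
their low-dimensional embedding. The pipeline operates on 64-channel
monopolar grid recordings (8 × 8 electrodes, 10 mm inter-electrode
distance, 2,048 Hz) of a submaximal isometric contraction and analyzes
the 10,240-sample hold phase. The factorial design crosses window
lengths {50, 100, 150, 250, 500, 1000} ms with overlaps
{0, 25, 50, 75, 90} %, i.e. 30 conditions.

## Synthetic generator

Because every downstream stage needs inputs with known ground truth, the
generator produces recordings from an explicit source model rather than
replaying data:

- **Motor-unit pool.** `n_units` (default 60) units with territory
  centers scattered (SD `spread_mm`, default 10 mm) around a configurable
  active region of the grid. Peak amplitudes are log-normal; recruitment
  thresholds are uniform on [0, 0.8) and sorted jointly with amplitude so
  larger units have strictly higher thresholds (size principle).
  Territory radii are log-normal around 6 mm, in the range reported for
  superficial motor-unit territories.
- **Drive.** A piecewise-linear trapezoid (defaults 6 s up, 6 s hold,
  8 s down, plateau 60 % of maximum); the hold phase is trimmed to
  exactly 10,240 samples for the analysis segment.
- **Firing.** Each recruited unit fires as a Gamma-renewal process
  (shape 5, ISI CV ≈ 0.45) at rate `8 + 30·(drive − threshold)` Hz,
  realized by time-warping a stationary unit-rate renewal process through
  the cumulative intensity.
- **Mixing.** Every discharge contributes a biphasic kernel (first
  derivative of a Gaussian, 10 ms) to all channels, scaled by
  `peak_amp · exp(−d/r)` with `d` the electrode-to-territory distance in
  mm. White measurement noise is added at `noise_rms` (default 0.05 of
  the unit-amplitude scale, a mid-range SNR for surface grids). Bad
  channels can be injected as white noise at `gain ×` the median channel
  RMS.

What the generator deliberately does **not** model: volume-conductor
filtering, fiber conduction-velocity propagation along the grid,
pinnation geometry, force-transducer dynamics, and any non-stationarity
within the hold phase. Consequently the plateau is statistically
stationary: at fixed window length, maps computed at different overlaps
are samples (more or fewer, more or less correlated) of the *same*
per-map distribution. Passing tests therefore demonstrate the pipeline's
bookkeeping, numerics and calibration on grid-like EMG mixtures — not
that real recordings behave identically (see Limitations).

## Preprocessing

Mean removal per channel; plateau segmentation (generator metadata when
present, otherwise the longest run with force ≥ 0.95 × its maximum — by
construction this includes the top 5 % of both ramps); zero-lag
band-pass via forward–backward application of a second-order Butterworth
(20–400 Hz), giving an effective fourth-order zero-phase response with
scipy's odd-reflection padding of three filter lengths. Outlier channels
are flagged when the Z-score of their log channel RMS exceeds 3.0
(log-RMS makes multiplicative gain faults additive; the threshold is
configurable because the original criterion is only "the Z-score").
Repair replaces a flagged channel by the mean of its unflagged neighbors
within Chebyshev radius 1; the pipeline applies it at the map-pixel level
(a raw-signal variant exists), edge and corner channels use the
neighbors available.

## Map generation

`N = round(window_ms · fs / 1000)` and `R = max(1, round(N·(1 −
overlap/100)))`, rounding half-away-from-zero. Windows are rectangular;
the trailing partial window is discarded, so a segment of length `L`
yields `floor((L − N)/R) + 1` maps. Pixel intensity is the RMS with
1/(N−1) normalization (the mean-square variant is available; the choice
is recorded in stack metadata). Each condition's stack is normalized by
its single global maximum over the plateau, so intensities are
dimensionless in [0, 1]. Channel 0 maps to the corner pixel (row 0,
col 0), row-major; columns are the x axis, rows the y axis, mm = index ×
IED.

## Image features

- **LoC** (barycenter): intensity-weighted centroid of pixel positions,
  `Σ I·(i,j) / Σ I`, converted to mm with origin at the corner
  electrode.
- **Entropy**: `p_k = I_k² / Σ I_j²`, `E = −Σ p_k log₂ p_k` (0·log 0 =
  0), 0–6 bits for 64 pixels. The squared-intensity reading treats the
  normalized signal *power* per electrode as the probability mass; a
  `power=1` option uses the intensities directly.
- **Histogram moments**: mean, population variance, standardized
  skewness, Pearson (non-excess) kurtosis of the 64 pixel values;
  skewness and kurtosis are set to 0 when the variance is zero (within
  8 ulp of the mean) so feature tables stay rectangular.

## Embedding geometry

All maps of all conditions are pooled as 64-dimensional vectors and
embedded into 3-D. The `manifold` backend delegates to UMAP with
n_neighbors = 10, min_dist = 0.7, Euclidean metric, 200 epochs and the
remaining hyperparameters at their standard values; it is seeded but
stochastic across library versions. The `linear` backend — the test
suite's default — is the orthogonal projection onto the top three
principal axes with deterministic sign convention, preserving distances
exactly for data of intrinsic dimension ≤ 3.

Each condition's embedded cloud is summarized by the volume of its 3-D
convex hull (degenerate clouds — fewer than four points or coplanar —
get volume 0 and a flag), normalized across conditions to max = 1, and
by the Shannon entropy of the point counts over a 16³ voxelization of
the cloud's bounding box (grid size configurable). "Occupancy entropy"
was chosen as a concrete, testable reading of the heterogeneity of a
point-cloud polyhedron; alternatives (e.g. simplex-volume entropy) would
need the same arbitrary discretization choice. Trends of volume and
entropy against each factor are fitted by degree-3 least squares on the
z-scored response, whose real roots inside the factor range are reported
as zero-crossings; z-scoring makes the crossings the points where the
summary passes its own mean, which is well-defined for strictly positive
quantities.

## Statistics

Two-way fixed-effects ANOVA with interaction on each feature, fitted by
OLS with sequential (Type I) sums of squares so the decomposition
`SS_window + SS_overlap + SS_interaction + SS_residual = SS_total` is
exact for the unbalanced cell counts the design produces (map counts
grow with overlap). Effect size is η² = SS/SS_total, classified small
(< 0.04), medium (0.04–0.64), large (> 0.64). Post-hoc comparisons use
the studentized-range distribution with Kramer's unequal-n standard
error; with equal group sizes this reduces to classic Tukey HSD
(verified against statsmodels). K-medoids is classic PAM (greedy BUILD,
best-improvement SWAP); the number of clusters is the largest discrete
second difference of the within-distance curve (normalized to its k = 1
value), ties resolved toward smaller k — a concrete formalization of
"elbow before convergence". α = 0.05 throughout. For the full pipeline
the clustering input is subsampled to 300 observations per feature
(PAM's swap step is O(k·n²)); the subsample is seeded.

## Determinism and problem sizes

Every stochastic operation takes an explicit integer seed; the pipeline
derives per-stage seeds as `master_seed XOR crc32(stage_name)`, so adding
stages never shifts existing streams. The test suite and the acceptance
script run one synthetic trial at the full study geometry (10,240-sample
plateau, 30 conditions, ≈ 3,900 maps) with the linear backend — enough
for every bookkeeping, oracle and calibration check while keeping the
suite fast; calibration simulations use 500 null replicates (ANOVA) and
200 (Tukey family-wise error).

## Known limitations

- The stationary plateau means overlap changes only how many (and how
  correlated) maps a condition yields, not their marginal distribution.
  Geometry summaries that grow with the number of points (hull volume,
  occupancy entropy) are therefore monotone in overlap here, whereas
  recordings with within-plateau non-stationarity could behave
  differently; conclusions about overlap-driven *distribution* changes in
  real data are outside what the synthetic conditions can establish.
- The convex hull ignores concavity of the embedded clouds; an
  alpha-shape variant would be needed for strongly non-convex manifolds.
- The manifold backend's output is reproducible only for a fixed
  umap-learn version; cross-version numerical identity is not promised.
- Features are computed per map on the normalized stack; no
  between-trial normalization (e.g. MVC-based) is applied.
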