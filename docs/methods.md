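# Methods

This note records the models, conventions, parameter choices and known
limitations behind `behavkit`, in the order data flows through the
package.

## The metadata-linked table

A `BehavTable` pairs a long-format behavioural frame (`id`, `t` in
seconds, variables) with a metadata frame keyed by the same `id`.
Referential integrity is one-directional by design: the metadata may
list specimens with no data (dead-on-arrival animals belong in the
experimental registry), but a data row whose id is unknown to the
metadata is an error — data without provenance is unanalysable.  Every
transformation re-validates the pair, so integrity cannot silently rot.

Time conventions, fixed once and used everywhere:

* time is float seconds relative to an experiment reference (readers
  convert from native units: milliseconds in tracking databases,
  wall-clock timestamps in monitor files);
* windows are half-open `[t_min, t_max)` and bins are labelled by their
  left edge, so consecutive windows/bins partition time with no double
  counting;
* zeitgeber time is `((t − lights_on) mod day_length) / 3600` hours,
  always in `[0, 24)` for a 24-h day.

Dead-animal curation drops a specimen's trailing records when its final
run of zero movement spans ≥ 24 h (configurable).  The 24-h default is
the conventional practice for fly death in long recordings; it is a
declared choice, not a fitted quantity.

## File dialects

The tracking-database reader expects the minimal contract: a key/value
`METADATA` table (machine name, start time), a `ROI_MAP` of regions, and
one `ROI_<n>` table per region with `t` (ms), `x`, `y`, and
`xy_dist_log10x1000` — displacement stored as `round(1000·log10 d)`.
Specimen ids are formed `"<machine>|<region>|<start>"`, which is unique
across a lab's fleet and human-readable.  De-quantization is
`10^(v/1000)`; the worst-case relative error of the encoding is
`10^(1/2000) − 1 ≈ 1.15e-3`, which is the tolerance the round-trip tests
assert.  Real schemas carry more columns (`w`, `h`, `phi`, …); only the
minimal dialect is contractual.

Monitor files are 42 tab-separated fields per reading: index, date,
time, status, six reserved fields, 32 channel counts.  Rows with status
≠ 1 are dropped rather than zero-filled — a zero count is a biological
claim (no beam crossings), which a failed reading cannot support.

The generic reader accepts any table with an id column, a time column
(`s`/`ms`/`min`/`h`) and at least one variable, building a minimal
metadata table when none is supplied.

## Sleep scoring

A bin is *moving* when the maximum of the per-frame velocity proxy in it
exceeds the threshold (max, not mean: a single jump in an otherwise
quiet bin is movement).  The proxy is the displacement variable as
recorded; at ~1 Hz tracking cadence displacement per frame in px is
numerically px/s.  The default threshold of 1.0 px/s is configurable —
it is rig-dependent (pixel scale, arena size) and should be calibrated
per setup.

Sleep is any maximal run of inactive bins spanning ≥ 300 s, the "at
least 5 minutes" rule read inclusively: a run of exactly 30 × 10-s bins
is sleep, 29 bins is not.  Bins with no observations are *missing* —
neither moving nor inactive — and always terminate a run, so sleep is
never inferred across a recording gap.  This is deliberately
conservative; with sparse tracking it undercounts sleep rather than
inventing it.

Population summaries treat specimens, not time bins, as the independent
units: the sleep profile's 95% CI is a seeded percentile bootstrap
(default 1000 resamples) over per-specimen ZT-bin sleep fractions, and
rebound quantification bootstraps the per-specimen delta (rebound minus
baseline minutes over identical clock windows).  Specimens missing data
in either window are excluded and reported, never silently zeroed.
Rebound is reported in minutes; a fraction would hide the window length.

## Chi-squared periodogram

For a candidate period of P bins, with K = ⌊N/P⌋ complete cycles,
column means M_h of the fold, grand mean M̄ over the K·P used bins:

    Q_P = K · Σ_h (M_h − M̄)² / σ̂²,   σ̂² = Σ_i (x_i − M̄)² / (K·P).

Under the white-noise null Q_P ~ χ²(P−1); the significance line is the
χ² quantile at 1 − α/m with Bonferroni correction over the m tested
periods (α = 0.01 default; correction="none" available).  Design
choices:

* the candidate grid is every whole-bin multiple inside the requested
  range (default 16–32 h at 30-min bins → 0.5-h steps): folding
  requires integer bins, and resampling to a finer grid is out of
  scope;
* the incomplete final cycle is discarded (truncation to K·P), keeping
  the null exact rather than approximating partial folds;
* Q is invariant under affine transforms of the series, so counts,
  fractions or z-scores give identical periodograms;
* population curves are the pointwise arithmetic mean of per-specimen Q
  curves.  The χ² null does not apply to an averaged curve; the
  threshold shown alongside is the per-specimen line, for visual
  reference only.

Degenerate inputs are errors, not NaNs: constant series (no variance to
apportion) and series shorter than twice the longest tested period.
Measured null calibration at α = 0.01 on white noise is ≈ 0.5–1%
exceedance (slightly conservative, as expected for the finite-K χ²
approximation).

Actograms are day × time-of-day matrices, double-plotted by default
(each row shows 48 h, so row r's right half equals row r+1's left
half); partial days and the last row's right half are NaN-flagged.

## The constrained sleep-stage HMM

Four states — deep sleep, light sleep, quiet awake, active awake — over
the binary alphabet {inactive, moving}.  Two kinds of structural
constraint, both held *exactly* (not approximately) through training:

* **emissions**: deep and light sleep emit moving with probability 0.
  Sleep is complete inactivity by definition; a "sleep" state that
  moves would be unfalsifiable.
* **transitions**: the adjacency chain deep ↔ light ↔ quiet ↔ active
  with self-loops, plus light → active (startled awakening).  The five
  forbidden entries (deep→quiet, deep→active, quiet→deep, active→deep,
  active→light) encode that stage depth changes gradually.  Besides
  matching the chain topology of the sleep-stage HMC literature this
  model descends from, the asymmetric masks make the states
  identifiable from binary data alone: without them the two awake
  states (and to a lesser degree the two sleep states) can trade places
  at negligible likelihood cost, and parameter recovery fails.  The
  mask lives in the `HmmSpec` and is user-overridable.

Training is Baum–Welch on the pooled sequences of all specimens
(per-group models are obtained by filtering first); missing bins split
sequences so no transition is fitted across a gap.  Structural zeros
survive EM for free — expected transition counts inherit A's zeros
multiplicatively — and free entries are floored at 1e-12 before row
renormalization so a transiently starved state cannot produce NaNs.
Restarts: restart 0 starts from the template (uniform over allowed
entries); the rest draw Dirichlet(1) rows with a random 50–95% of the
transition mass moved to the diagonal.  The sticky initialization
matters: behavioural stages are persistent, and plain random inits
routinely converge to non-persistent local optima well below the truth
basin.  Convergence is an absolute log-likelihood change below `tol`
(1e-6 default, the convention categorical-HMM implementations use);
the best of the seeded restarts by final log-likelihood wins, ties to
the lowest index.  Per-restart log-likelihood trajectories are kept on
the results object because EM monotonicity is an invariant worth
asserting, and a warning flag marks degenerate fitted emissions (free
entries collapsed below 1e-8, e.g. from all-constant input).

The E-step is an explicit-loop scaled forward–backward compiled with
numba (with a pure-numpy fallback); the loops avoid BLAS dispatch on
4×4 products and make minute-resolution, multi-day, multi-fly training
a matter of seconds.

Decoding is Viterbi in log space, ties toward the lowest state index;
posterior marginals via forward–backward are optional.  Headline
figures use the Viterbi path (a single consistent trajectory); for
*occupancy estimation* the posterior marginals are the better
estimator — Viterbi counts are biased toward persistent states (a
measured ~0.04 absolute occupancy bias at the test settings, vs ~0.02
for posteriors).  Stage occupancy by zeitgeber time normalizes within
each (group, ZT-bin) so the four fractions sum to 1.

Analyses at minute resolution (training, decoding, occupancy) follow
the minute-binning convention of the sleep-stage literature; the
movement classifier accepts any regular bin width.

## Curated time-series features

The 22 canonical curated features (the catch22 set: histogram modes,
autocorrelation timescales, automutual information, symbolic motifs,
outlier-inclusion asymmetry, spectral summaries, fluctuation-analysis
scaling, forecasting residuals, …) are authored in this package on
numpy/scipy from their published definitions.  Conventions: features
are computed on the z-scored series; a constant series (not
z-scorable) yields an all-NaN row that is kept and flagged rather than
dropped; series under 10 bins are excluded and reported.  NaN is the
per-cell failure flag throughout — there are no silent missing values.
Two numerical details differ from other implementations of the set and
are fixed here: histogram bin counts for the embedding-distance
exponential fit use the square-root rule, and the periodicity feature
detrends with a cubic polynomial rather than a regression spline.  The
mapping series → 22 values is deterministic and, being length- and
structure-sensitive, a series concatenated with itself generally maps
elsewhere.

Classification is a stratified k-fold (default 5) cross-validated SVM
(RBF kernel, the standard `gamma="scale"` heuristic) on standardized
features, with NaN cells imputed to the column mean; accuracy is the
held-out fraction correct, and every randomization (folds,
permutation nulls) is seeded.  The decision surface is drawn in the
plane of the first two principal axes of the standardized features — a
declared visualization choice; the classifier separating the full
22-dimensional space is what the accuracy reports.  For massive-feature
toolboxes that run elsewhere, the export bundle writes one value per
line per specimen plus a CSV manifest; executing those toolboxes is out
of scope.

## The simulator

Each fly is a four-state Markov chain whose transition matrix mixes a
day regime (little sleep, much movement) and a night regime
(consolidated deep sleep) through a sinusoidal weight

    w(t) = (1 + cos(2π·(t/3600 − peak_zt)/T)) / 2

with T the genotype's circadian period and `peak_zt` (default 15) the
hour at which night-like dynamics — hence deep-sleep propensity —
peak.  Both base matrices respect the HMM template's structural zeros.
Defaults describe a three-genotype design (periods 19 / 24 / 29 h, ten
flies each) over five days at 10-s bins; movement probabilities are 0
for both sleep states, 0.15 for quiet awake and 0.85 for active awake.

Displacement is log-normal: median 5 px (σ = 0.6) when moving — well
above the 1 px/s threshold, so movement classification is meaningful
and imperfect in the realistic direction (~0.4% of moving bins fall
below threshold) — and a median 0.005 px (σ = 0.5) tracker-jitter draw
when still.  Still bins get jitter rather than exact zeros because
video tracking never records a true zero and the log-quantized integer
displacement encoding cannot represent one; the jitter is three orders
of magnitude below threshold and never flips a classification.
Positions are a reflected random walk in a rectangular region.

Mechanical deprivation windows force moving = 1 and state =
active_awake bin by bin (the chain resumes from the forced state, as
under real stimulation).  After each window a sleep-pressure boost adds
up to `rebound_boost` (default 0.5) to w(t), decaying linearly over
`rebound_tau_h` (default 6 h) — the minimal mechanism that produces
rebound sleep for the rebound-quantification analyses.

What the simulator does *not* emulate — and therefore what passing
tests do not show about real data: arena geometry and wall-following,
micro-movements and grooming (awake-state emissions are Bernoulli, not
structured), inter-fly variability in period or sleep drive (all flies
of a genotype share parameters), tracker dropouts (missing data must be
injected explicitly), and any light-driven masking distinct from the
circadian modulation itself.  In particular the HMM's binary-emission
assumption is exactly true in simulation and only approximately true on
real displacement data.

## Problem sizes in the standing checks

The recovery analyses in `scripts/acceptance.py` and the test suite
run at desk scale, chosen to give each check clear statistical power:
period recovery uses 100 flies per genotype over six days (top-peak hit
rate within one 0.5-h grid step, nominal ≥ 95%, measured ≈ 99–100%);
HMM transition recovery uses ten flies × five days of 1-min bins
(measured max error ≈ 0.02–0.04 against a ±0.05 band); deep-sleep
timing uses 30 flies × four days (decoded occupancy argmax within one
30-min bin of the configured ZT15); classification uses 45 flies across
the three genotypes (accuracy ≈ 89–96% against a 33% chance level, with
a seeded label-permutation null ≈ 30%).  Null calibration of the
periodogram uses 200 white-noise replicates × 33 grid periods.

## Known limitations

* The HMM is time-homogeneous while real (and simulated) dynamics are
  circadian-modulated; a fitted A is a time-average, so zt-resolved
  decoded occupancy tracks the true rhythm's shape and timing but not
  its exact level at every bin.  Time-varying or duration-explicit
  (semi-Markov) models are out of scope.
* The movement threshold and the 24-h death criterion are conventions
  to calibrate per rig, not estimated quantities.
* Periodogram resolution is the activity bin width; periods between
  grid points are attributed to the nearest representable fold.
* The feature set's values are faithful to the published definitions
  but not bit-identical to other implementations of the set (see the
  two numerical details above); models trained on features from one
  implementation should not be applied to features from another.
* Interactive plotting, arousal-threshold assays, model selection over
  the number of stages, and out-of-core data are non-goals.

A note on supervision: the phenotyping path here is supervised —
labels come from the metadata, and the permutation null guards against
optimistic accuracy.  No unsupervised clustering of the feature space
is claimed or provided.
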