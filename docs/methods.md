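# Methods

`painconn` implements a connectome-wide analysis of how the duration and
intensity of chronic musculoskeletal pain jointly associate with
ROI-to-ROI resting-state functional connectivity (RSFC) in older adults,
together with a synthetic-cohort generator that makes every inference stage
testable without access to real imaging data.

## The statistical model

For each of the `n(n−1)/2` unique ROI pairs ("edges"; 2,850 for the 76-ROI
atlas), connectivity is the Fisher-transformed weighted Pearson correlation
`z = atanh(r)` of the two denoised ROI time series.  In the pain group the
edge-wise model is, in Wilkinson notation,

    z ~ WPINT * X + sex + age + pain_med + moca + scanner_pain

where WPINT is worst-pain intensity (0–10 rating) and X is worst-pain
duration under one of three codings: `log` (log10 years), `linear` (years),
or `dichotomous` (indicator of > 5 years).  `WPINT * X` expands to both
main effects plus the moderation term `WPINT:X`.

### Elimination ladder

Terms are removed by stepwise backward elimination, from the second-order
term downward, never removing X:

1. Fit the full model at every edge; Benjamini–Hochberg (BH)-correct the
   `WPINT:X` p-values across all edges.  Edges at or below the elimination
   level (default FDR 0.05) freeze the full model.
2. Refit the remaining edges without the interaction; BH-correct the X and
   WPINT p-values separately across those edges (per-term families — the
   joint alternative was a genuinely open choice; separate families keep
   each contrast's FDR interpretable).  Edges whose WPINT survives freeze
   `{X, WPINT}`.
3. Refit the rest with X only and BH-correct its p-value.

Each edge reports the q-values of the terms tested at its terminal step.
A second, stricter threshold (default FDR 0.01, two-tailed) selects edges
for reporting and for deviation profiling.  Effect sizes are Cohen's
`f² = (R²_full − R²_reduced)/(1 − R²_full)` for the duration term and, where
retained, the interaction.

All edge fits are closed-form OLS computed simultaneously across edges
(the design is shared; only the outcome changes); the per-edge fit is
verified against statsmodels in the test suite.

### Johnson–Neyman regions

For an edge retaining the interaction, the simple slope of the predictor P
at moderator value W is `b_P + b_{PW} W` with variance
`v_PP + W² v_WW,int + 2W v_P,int` from the coefficient covariance.  The JN
region is the solution set of

    (b_i² − t²v_ii) W² + 2(b_P b_i − t²v_Pi) W + (b_P² − t²v_PP) > 0

with `t` the two-tailed critical value at the model's residual degrees of
freedom.  The level defaults to the BH q-value the edge's interaction
attained (mirroring a moderation analysis restricted by its own FDR
outcome) and is overridable.  A degenerate leading coefficient (within
1e-14 of the problem scale) falls back to the linear root.  Both the
unclipped region and its intersection with the observed moderator range are
reported.  Participants are split into less/more severe groups at
WPINT ≤ 5 vs > 5 (the JN boundary rounded to a reported rating value).

### Pain-vs-control deviation

The adjusted control reference is the intercept of `z ~ sex + age + moca`
fitted in the pain-free group with covariates centred at the pooled
(pain + control) sample means.  The pain-side adjusted prediction evaluates
the terminal pain-group model along a duration grid (200 points, uniform in
coded units, hence log-spaced in years under the log coding) with shared
covariates at the same pooled means and pain-only covariates at pain-group
reference values (modal medication category, mean scanner pain).  At each
grid point,

    t = (ŷ_pain − μ̂_control) / sqrt(SE_ŷ² + SE_μ̂²)

with Welch–Satterthwaite degrees of freedom by default (the two fits use
disjoint subjects, so the independence underlying this combination is
exact; pooled and normal-approximation df are available behind a switch —
the exact historical variance convention for this contrast is not
documented, so this component is an explicit reconstruction).  The
significance threshold defaults to the q-value from the pain-group
regression; maximal significant grid runs are reported as intervals.

Degenerate cases: covariates constant within the control sample are
dropped (their adjustment is inestimable and the column is collinear with
the intercept); when both standard errors vanish, an exact match reports
t = 0, p = 1 and a nonzero difference reports t = ±∞, p = 0.

## Signal path

The per-subject pipeline entry point is a frames × ROIs table of average
BOLD signals (voxel-level preprocessing is out of scope).

* **Scrubbing.**  Framewise displacement is the Power convention:
  sum of absolute backward-differenced translations plus rotations
  converted to arc length at a 50 mm head radius (the exact FD formula
  used historically is unstated; this is the dominant convention).  A frame
  is flagged when FD > 0.9 mm or the standardised global-signal change
  exceeds 5 SD, both strict.  Subjects keep all frames; those with ≥ 50%
  flagged frames fail the validity gate and are excluded with a logged
  reason, and a median ± 3·IQR screen (type-7 quartiles) flags — never
  removes — sample-level outliers.
* **Nuisance design.**  Six motion parameters and their backward first
  differences (zero at frame 0); one indicator column per flagged frame;
  the first 5 principal-component time courses of the centred white-matter
  and CSF voxel pools (anatomical CompCor); and a session-long boxcar
  convolved with the canonical double-gamma HRF (response peak delay 6 s,
  undershoot delay 16 s, unit dispersions, 1:6 undershoot ratio, 32 s
  kernel) plus its first and second temporal derivatives.  All-zero and
  duplicate columns are dropped; the design must then be full rank.
* **Denoising and filtering.**  Series are converted to percent signal
  (per-ROI division by the temporal mean × 100; non-positive baselines are
  an error), centred, residualised against the design, then ideal-DFT
  band-pass filtered to 0.008–0.09 Hz (bins outside the band zeroed).
  Regress-then-filter is the default order; a "simultaneous" mode filters
  data and design jointly before regression.  Censoring weights are binary
  (0 at flagged frames): the simplest weighting consistent with a weighted
  correlation plus scrubbing, since the historical weighting scheme is
  unstated.
* **Connectivity.**  Weighted Pearson correlation using the censoring
  weights for means and covariances, clipped to ±(1 − 1e-12) before
  `atanh`.  Zero-variance ROIs yield NaN edges that are excluded
  downstream.  Edges are enumerated canonically as (i, j), i < j, row-major
  in ROI-map order, in every output.

## Synthetic cohorts

The generator emulates the study conditions: 40 pain / 21 control older
adults, 76 ROIs in 10 networks, 300 frames at TR = 2 s.

* **Pain history.**  Worst-pain duration is a truncated log-normal on
  [0.25, 56] years with median 5 and log-scale SD 1.9695, a symmetric fit
  to the reported quartiles 1 / 5 / 14.25 years (duration distributions of
  chronic pain are strongly right-skewed; the implied truncated mean/SD of
  ≈ 9.2 / 11.1 years is what the moment-matching tests check against).
  Intensity is a normal(4.8, 2.0) density discretised onto the 1..10
  rating support.
* **Covariates.**  Age truncnorm(71, 7) on [61, 94], 75% female,
  MoCA truncnorm(25, 2.5) on [17, 30] rounded to integers, medication use
  Bernoulli(0.5), scanner pain zero-inflated exponential (42.5% zeros,
  mean 15, capped at 100) matching a strongly right-skewed mild-pain
  profile.  Age/MoCA/scanner-pain parameters are configurable placeholders
  chosen as plausible for a community-dwelling older cohort; only their
  ranges are anchored to reported values.
* **Time series.**  Each subject's ROI series is a stationary multivariate
  AR(1) (lag-1 coefficient 0.3) whose lag-0 population correlation is
  controlled exactly: within-network 0.3 / between-network 0.1 by default,
  with each planted edge set to `tanh` of the subject's linear predictor
  `baseline_z + β_X X + β_W WPINT + β_int X·WPINT`.  Sampling draws
  innovations with covariance `(1 − φ²)C` through a Cholesky factor and
  runs a 50-frame burn-in through an AR filter.  Benign loss of positive
  definiteness is repaired by eigenvalue clipping (floor 1e-6, rescaled to
  unit diagonal); if the repair moves a planted correlation by more than
  0.02 the generator raises an error naming the subject, because the
  requested effect is geometrically incompatible with the background
  structure (a single very strong edge between otherwise-correlated
  networks cannot exist in a valid correlation matrix).  Series are
  emitted in raw scanner-like units, `1000·(1 + 0.01·x)`, so the
  percent-signal conversion is exercised.
* **Motion and noise pools.**  Motion is a Gaussian random walk
  (0.02 mm / 2e-4 rad per-frame increments) with Bernoulli(0.03) step
  artifacts of ±1.5 mm, sized to exceed the scrubbing threshold.  WM/CSF
  pools are 50 voxels sharing 5 latent components plus white noise, with
  optional contamination by the mean ROI signal.
* **Determinism.**  All randomness flows from one seed through
  `SeedSequence` spawning: child 0 drives the covariate table, children
  1..n drive one subject each, so outputs are bitwise reproducible and
  adding subjects never perturbs earlier draws.

What the generator does **not** emulate: voxel-level imaging, physiological
(cardiac/respiratory) noise, frequency-dependent coupling, non-stationarity,
site/scanner effects, or any real covariate–connectivity structure beyond
what is planted.  Passing tests therefore demonstrate correctness of the
statistical machinery under a known model, not robustness to real-data
violations of it.

## Validation experiments and problem sizes

* **Null calibration** (200 replicate cohorts, 20 ROIs / 190 edges,
  300 frames, n = 40/21): empirical FDR of the BH-corrected interaction
  step (which equals the any-rejection rate under the global null), the
  uncorrected per-edge type-I rate, and the significant-grid-point fraction
  of a null deviation profile, each compared to the nominal 0.05 within
  Monte-Carlo error.  Edge count enters the inference only through the
  multiplicity correction, which 190 edges exercises fully.
* **Parameter recovery** (500 replicates per coding, n = 40 pain, 6 ROIs,
  300 frames): planted coefficients per coding — log: β_X 0.10,
  β_W 0.015, β_int 0.02; linear: 0.004 / 0.015 / 0.0008; dichotomous:
  0.15 / 0.015 / 0.03, all on baseline z = 0.1 — sized so the implied z
  stays well inside (−1, 1) across the duration × intensity support.
  95% CI coverage of each planted coefficient is required to lie in
  [0.92, 0.98].
* **Oracle equivalence**: BH q-values against a literal step-up rejection
  scan (1,000 random p-vectors) and against statsmodels; JN regions
  against a 10,001-point dense |t| grid (1,000 random fits); weighted
  correlation with uniform weights against plain Pearson at 1e-12.

`scripts/acceptance.py` additionally runs one study-scale cohort (76 ROIs,
300 frames, 40/21 subjects) through the full file-based pipeline with a
planted log-coding interaction of 0.15 at one edge.  That demonstration
uses an independent (zero-correlation) background so the planted block
embeds exactly, and the effect size comes from a power analysis against the
2,850-edge FDR bar.

## Numerical choices

* Derivatives are backward differences, zero-padded at frame 0; frame k
  occurs at time k·TR, 0-based.
* Correlations are clipped to ±(1 − 1e-12) before `atanh`.
* BH q-values enforce step-up monotonicity; ties share a q-value.
* Covariates enter GLMs uncentred (slopes are centering-invariant);
  centring is applied only when producing adjusted predictions/means.
* Missing data: listwise deletion for GLMs; pairwise deletion for the
  covariate screening table.
* JN boundary classification uses the sign of the leading quadratic
  coefficient; boundaries satisfy |t(W*)| = t_crit to 1e-6.
* CSV output: '.' decimals, 17 significant digits, LF endings; readers
  parse with round-trip float precision.

## Known limitations

* The weighted correlation supports arbitrary weights in [0, 1] but the
  pipeline only produces binary censoring weights; tapered weighting
  schemes are untested beyond unit tests.
* The deviation profile's variance combination is a reconstruction (see
  above); all three df conventions are available but only Welch is
  calibrated in the null experiments.
* The dichotomous coding assumes a single-df interaction contrast.
* No spatial or graph-level inference: edges are treated exchangeably by
  BH, which controls FDR under positive dependence but is not a
  network-based statistic.
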