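# Methods

## Generative observer model

The simulator and the analysis share one functional form: the probability of
a "same" response is a four-parameter Gaussian profile on the
log₁₀-duration axis,

```
p_same(d) = baseline + amplitude · exp( −(log10 d − log10 PSE)² / (2 σ²) ),
σ = log10(1 + Wf).
```

Choosing the generative width as `log10(1 + Wf)` makes the Weber-fraction
map `Wf = 10^σ − 1` exactly invertible: a perfectly recovered fit returns the
observer's true Wf.  Running acts multiplicatively on the peak
(`PSE_run = PSE_rest · running_gain`; a gain below 1 is an overestimation of
duration during exercise) and, separately, on the width
(`wf_running_gain ≥ 1` degrades precision while running).  Responses are
independent Bernoulli draws per trial; no sequential, fatigue, or learning
effects are modeled.

Defaults: amplitude 0.85, baseline 0.05 (the empirical aggregate curves peak
well below 1 and have a non-zero floor from lapses; both are config-exposed).

## Cohort calibration

Per-condition population distributions (PSE and Wf means/SDs for
2 modalities × 2 duration ranges × 2 motor conditions; cohort sizes 29
visual, 23 auditory, 18 overlapping) are fixed calibration constants taken
from the published descriptive tables of the running/time-perception study
this pipeline emulates.  Rest-condition parameters are drawn from normals
truncated at zero (truncation is negligible at the calibrated means/SDs,
consistent with the reported Shapiro–Wilk normality).  Each participant's
running gains are drawn around the run/rest ratio of the condition means,
with spread chosen so the implied run-condition SD matches the table under
the independence assumption `Var(g·x) ≈ g²Var(x) + x̄²Var(g)`.  Gains and
rest parameters are drawn independently — per-subject correlations are not
published, so none are imposed.  The same holds across conditions: one
participant's millisecond and second-range parameters are independent draws,
which understates the within-subject correlation real data would show; see
Limitations.

Heart rate: each participant receives an age (normal, mean 26.4, SD 4.96,
clipped to 18–60), a target of 80 % of the Tanaka age-predicted maximum
`208 − 0.7·age`, and a rest baseline (normal; mean 80 bpm visual sessions,
85 bpm auditory, SD 6).  Traces ramp exponentially with time constant
ramp/3 (95 % of the gap closed at the 3-minute mark), then sit at the target
plus i.i.d. Gaussian noise (SD 2 bpm).  Only the 3-minute attainment and
plateau stability are contractual; the exponential shape is cosmetic.  The
running mean excludes the ramp, giving group modulations of ~65–71 bpm.

## Experiment design

`build_ladder` places `n` (odd, default 7) durations at
`reference · 10^(0.1·k)`, k = −3…3: a constant ≈ 26 % geometric increment
whose 3-decimal roundings reproduce the published test-duration lists (the
largest seconds-range value is published as 3.990 where the exact 3.99052
rounds to 3.991 — one unit in the last printed digit).  A test block holds
6 repetitions of each non-reference rung plus 18 of the reference
(54 trials; the reference's extra presentations replace its ordinary slot),
and a session runs two blocks per motor condition (108 trials).  Schedules
are seeded permutations of the exact trial multiset, never resamples.
Training presents each rung once per 7-trial block until ≥ 85 % correct,
where "correct" is defined as responding "same" exactly on the reference
trial (the only consistent reading of correctness feedback in a
same/different task); a 50-block cap bounds hopeless observers.

## Fitting

Count-weighted least squares of the four-parameter profile against the
per-duration proportions, on the log₁₀ axis (forced by the base-10 Weber
map; a linear-axis option exists but is non-default).  Weights are trial
counts (the reference has 3× the trials); unweighted is an option.  Box
bounds: peak within the ladder span ± one step, σ ∈ [0.01, 1], amplitude
and baseline in the unit interval.  A fixed grid of starts (every ladder
rung × four widths × two amplitude/baseline guesses) is scored on the loss;
the best six are refined with a bounded trust-region solver (tolerances
1e-12) and the lowest final loss wins — deterministic, no RNG.  Refinement
never increases the loss of its start, so the result is at least as good as
the best grid start; on 50 random binomial curves the fit also beat an
exhaustive 4-D grid oracle 50/50.  R² is computed unweighted about the mean
proportion, and fits with R² ≤ 0.7 are flagged and excluded from downstream
statistics (~1 % of fits at the calibrated noise levels).  Degenerate
inputs raise typed errors: fewer than 4 distinct durations, zero-variance
proportions (undefined R²), missing ladder levels (listed by name).

## Statistics

- **Power**: two-tailed paired *t*; power is the noncentral-*t* mass beyond
  the critical value at df = n−1, noncentrality d·√n.  `required_n` scans n
  upward from 2, so minimality is exact.  (At extreme noncentrality scipy's
  far-tail underflows to NaN; the negligible tail is replaced by its limit.)
- **JZS one-sample Bayes factor**: Cauchy prior (scale √2⁄2, the JASP
  default) on the standardized effect; BF₁₀ is the Cauchy-mixed
  noncentral-*t* density of the observed t over its central density,
  by adaptive quadrature at 1e-8 relative tolerance.  Cross-checked against
  an independent implementation (pingouin) to ~1e-4 (its quadrature's
  accuracy) and against the Rouder g-integral form to ~1e-12.
- **Correlation Bayes factor**: exact sampling density of Pearson r
  (hypergeometric form) integrated over a stretched-beta prior of width 1
  (uniform on (−1,1)), two-tailed.  |r| is clipped a hair below 1 so perfect
  correlations return a finite, huge BF rather than 0/0.
- **Evidence labels**: |LBF| ≥ 0.47 substantial, > 1 strong, > 2 decisive,
  symmetric for the null (negative LBF).
- **Mixed ANOVA**: random-intercept-per-participant linear mixed model
  (statsmodels MixedLM, REML), sum-coded modality × range × motor with all
  interactions; handles the unbalanced roster (only some participants did
  both modalities).  The dv is standardized internally (Wald statistics are
  affine-invariant) to stabilize optimization when the duration-range effect
  dominates the raw scale.  Each 1-df term's Wald z² is reported as F with a
  naive nobs − p denominator df; the contract is the direction and
  significance pattern of terms, not any particular small-sample df
  correction.
- **Normality**: scipy Shapiro–Wilk, used as a logged gate, never a hard
  stop.

## Reproducibility plumbing

All randomness flows from one master seed.  Stage seeds derive as
`SeedSequence([master, crc32(stage/label/path)]) mod 2³¹`, so any stage can
be re-run in isolation and a fixed master seed reproduces every CSV
byte-for-byte (manifest hashes are asserted equal in tests).  CSVs are
comma-separated, UTF-8, full-precision floats; rounding happens only in the
human-readable summary.

## Problem sizes in the test suite

Unit tests run single blocks or small cohorts.  The cohort-level checks use
the study's own scale — 29 visual + 23 auditory participants, two 54-trial
blocks per motor condition — with 20 replicate cohorts for the inference
battery and 8 null cohorts (running gain pinned at 1) for calibration; the
single-observer recovery checks use 10× the standard trial counts.

## Known limitations

- Independent draws across conditions understate within-subject correlation;
  the random intercept in the mixed model consequently absorbs little
  variance.  Cohort-level significance patterns should be read with that in
  mind.
- The calibrated per-condition means themselves embed small cross-condition
  structure (the run/rest ratio differs between duration ranges, and the
  modality ordering flips between ranges), so "interaction-free" is only
  approximately true of the simulated population, and interaction terms in
  the mixed ANOVA carry small true signals rather than pure noise.
- The generative model equals the fitting model by construction; parameter
  recovery here demonstrates estimator correctness, not robustness to model
  mismatch (lapse asymmetries, non-Gaussian profiles, sequential effects).
- Heart-rate traces are summary-faithful (ramp time, plateau, modulation
  scale), not physiologically detailed; effects and heart rate are generated
  independently, so the null HR-effect correlations are true nulls.
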