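# Methods

## Model

All computations live inside classical test theory: an observed score is
X = T + E with uncorrelated true score T and error E, so
σ²_X = σ²_T + σ²_E and reliability ρ_XX′ = σ²_T/σ²_X. The package treats
these as population parameters in `VarianceComponents` (ρ constrained to
[0, 1]) and as unconstrained sample estimates everywhere an estimator can
stray outside the unit interval (`SplitHalfResult.sb_estimate`). Variances
are stored as variances throughout; SDs are converted at the boundary,
because the worked example quotes group SDs (0.55, 0.22) but group
variances (0.31, 0.05) that disagree at the third decimal with the squared
SDs. The quoted variances are taken as canonical inputs for the printed
arithmetic; the quoted SDs are the moment-matching targets. Display
rounding is half-away-from-zero to 3 decimals (0.0215 → 0.022); raw values
are never rounded.

## Exact power

Power of the two-group mean comparison is
π(δ) = 1 − F_{df,ncp}(t_crit) with F the noncentral-t CDF. Two df
conventions are implemented because the literal formula — df = N − 1,
ncp = √N·δ/σ — describes a one-sample/paired layout rather than the usual
equal-n two-sample test:

- `formula="paper"` (default): df = N − 1, ncp = √N·δ/σ.
- `formula="standard_two_sample"`: df = 2(N − 1), ncp = √(N/2)·δ/σ.

Both produce the same monotone reliability–power relationships on the
reference grids; the choice shifts absolute power levels only.

Tails: the single critical value reads as one-sided, so `one_sided` is the
default; `two_sided` uses the upper-α/2 critical value **and includes the
lower rejection region** P(T < −t_crit). The lower-tail term is negligible
for positive noncentrality but including it makes the exact value equal the
rejection probability of an actual two-sided t-test, which is what the
Monte Carlo oracle simulates. scipy's noncentral-t CDF can underflow to NaN
deep in that lower tail at large ncp; the term is then dropped (its true
magnitude is below Φ(−ncp)). δ = 0 is rejected by `PowerSpec` (δ > 0 by
contract); the size-equals-level limit is tested through decreasing-δ
sequences, and the Monte Carlo module accepts a δ = 0 override explicitly
for type-I-error checks.

Scenario calibration: `fixed_true` sets σ² = 1 + (1−ρ)/ρ = 1/ρ (domain
ρ ∈ (0, 1]); `fixed_error` sets σ² = 1/(1−ρ) (domain ρ ∈ [0, 1)). Reference
grids: ρ ∈ {0.1, …, 1.0} or {0.0, …, 0.9}, N ∈ {10, …, 50}, α = 0.05,
δ = 0.5.

## Monte Carlo replication simulator

`mc_power` simulates the test the formula describes: for `paper`, N scores
per replication drawn as true score (variance σ²_T) plus error (variance
σ²_E) around mean δ, one-sample t against zero; for `standard_two_sample`,
two independent groups of N differing by δ, pooled-variance t. Significance
is p < α at the matching tails. The oracle must simulate what the formula
computes — calibrating the simulator against the other variant would
conflate the df conventions. Default 10,000 replications
(binomial SE ≤ 0.005); results carry seed and binomial SE for audit, and
identical (config, seed) pairs are bitwise reproducible
(`numpy.random.Generator`/PCG64 throughout).

## Synthetic experiment generator

The generator emulates the hypothetical two-condition instruction study:
n = 30 per condition, condition parameters (μ, σ²_X, ρ) =
(−0.25, 0.31, 0.92) for attitude-irrelevant and (0.68, 0.05, 0.57) for
attitude-relevant instructions. Per participant, T ~ N(μ, ρσ²_X); per
trial, score = T + ε with ε ~ N(0, K·σ²_E) i.i.d., K the total trial count.
Then the K-trial mean has error variance σ²_E, the full score has variance
σ²_X and reliability ρ in expectation, and a half-mean has error variance
2σ²_E — exactly the structure split-half estimation assumes. K defaults to
40 (20 practice + 20 test); trial counts and the trial-level error model
are declared choices, not quoted ones — 40 trials is a typical IAT length,
and i.i.d. normal trial noise is the simplest model consistent with the
CTT full-score structure.

What the generator does *not* emulate: reaction-time latencies and their
skew, error-trial penalties, D-score scaling, practice effects, or any
systematic (method) error variance. Passing tests therefore show that the
estimators behave correctly under the CTT data-generating process, not that
real IAT data satisfy that process.

`moment_match` is an opt-in affine rescaling (per condition, common map
across that condition's trials) that makes full-score sample mean and SD
hit targets exactly — used to reproduce the printed summary arithmetic
(t(38.05) = 8.60 from means −0.25/0.68 and SDs 0.55/0.22). It slightly
distorts the reliability calibration, so recovery tests use the raw
population mode.

## Split-half bootstrap

Each of 1000 iterations partitions the trial indices into random equal
halves — the same partition for all participants, so the halves are
comparable forms — and correlates the participants' half-means (Pearson).
The estimate is the Spearman–Brown correction 2r/(1+r) of the *mean* split
correlation. The phrase "Spearman–Brown corrected mean split-half
correlation" is grammatically ambiguous; correct-then-average is available
as `correction="correct_then_mean"` and differs only at second order.
Splits ignore the practice/test block labels, since the full score pools
both blocks. Splits with zero variance in a half are excluded with a
warning counter; above 10% exclusions the result is flagged unreliable.
No Fisher-z averaging is applied.

At study scale (n = 30) the estimator is slightly biased low: the split
correlation's small-sample bias and the concavity of the Spearman–Brown map
(Jensen) both pull the mean estimate down, by roughly 0.005 at ρ = 0.92 and
0.02 at ρ = 0.57. The recovery analyses (500 replicate datasets in
`scripts/acceptance.py`; 120 in the faster end-to-end test, enough for a
standard error of the mean near 0.01) sit within ±0.02 and ±0.04 of the
generating values, tolerances that absorb exactly this bias plus Monte
Carlo error.

## Welch comparison

`welch_from_summaries` evaluates t = (m₂−m₁)/√(s₁²/n₁+s₂²/n₂) with
Welch–Satterthwaite df; sample SDs use the n−1 denominator everywhere (the
convention is not quoted, so the standard one is used). Two-sided by
default. Recomputing from the printed rounded summaries gives t = 8.599,
df = 38.048; the published t(38.11) = 8.54 evidently comes from the
unrounded underlying data and is not reproducible from the summaries, so
the recomputed pair is validated against a 50-digit decimal evaluation
instead of the published digits.

## Problem sizes and numerical choices

Power surfaces are exact and instantaneous. Monte Carlo checks use 10,000
replications per grid cell (100 cells across both scenarios) and 20,000 for
null-rate checks. Reliability recovery uses 500 replicate datasets × 1000
splits per condition in the acceptance script and 120 replicates in the
test suite; the split engine is vectorized (all splits as two matrix
products), so both run in seconds. Seeds: every stochastic entry point
takes an explicit seed; internal stage seeds are spawned from it via
`numpy.random.SeedSequence` and masked to 31 bits.

## Known limitations

- CTT only: no congeneric/tau-equivalent model fitting, no coefficient
  alpha from item covariances, no latent-variable separation of method
  variance.
- Equal group sizes and the two fixed-variance calibrations only; no
  Welch-power or ANOVA power.
- The synthetic generator's realism limits noted above; conclusions about
  real IAT data require the CTT assumptions to hold approximately.
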