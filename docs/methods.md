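# Methods

This note documents the statistical procedures implemented in `psyvalid`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data generator does and does not emulate.

## Correlation machinery

All correlations are Pearson coefficients on pairwise-complete
observations (listwise deletion is available as an option).  Cells with
fewer than four complete pairs are undefined and excluded from any
downstream statistic, with the exclusion logged and the degrees of
freedom reduced.  Pair counts are carried per cell.

**Fisher z.**  z = atanh(r), inverse tanh.  Magnitudes at or above
1 − 1e−12 are clipped before atanh so unit correlations map to a large
finite z; clipping is logged.  The round trip is exact to 1e−9 for
|r| ≤ .999999.

**z-based averaging.**  Average absolute correlations are computed as
tanh(mean(atanh|rᵢ|)).  Because atanh is convex on [0, 1), this average
weakly dominates the arithmetic mean of |r| — a property test checks
this.

**Matrix comparison.**  Two statistics: the mean absolute deviation of
corresponding correlations, and the equality test
Q = Σ (z₁ₖ − z₂ₖ)² / (1/(n₁−3) + 1/(n₂−3)), referred to χ² with df equal
to the number of compared cells.  For symmetric matrices the default
cell set is the unique off-diagonal triangle; the diagonal is excluded
because atanh(1) is infinite and a unit self-correlation carries no
information.  A `cell_set="kxk"` compatibility mode counts every
ordered cell (df = k²; the diagonal contributes zero), because published
applications of this test sometimes report df that way; the χ²
calibration of that mode is not asserted.  The test assumes two
independent samples **and** independent cells.  The cells of one
correlation matrix are only asymptotically independent when the
population correlations are zero, so the type-I-error simulation in the
test suite draws from an independent-variable population; with strongly
correlated variables the statistic is over-dispersed and the test is
approximate.  When the two matrices come from the same subjects, the
result is flagged `dependence ignored` rather than corrected, matching
the common applied practice this package replicates.

**Disattenuation.**  r̂ = r / √(rel₁·rel₂).  Reliabilities are inputs
(e.g. coefficient ω of the instruments); the package does not estimate
internal consistency.  Corrected values beyond |1| are returned as
computed and logged, not clamped.

**Confidence intervals.**  z ± z_crit/√(n−3), back-transformed.

**Rounding.**  Half-away-from-zero to two decimals, applied only in the
report-writing layer; all stored and returned values are full precision.

## Double-entry profile similarity

The double-entry ICC of two profiles a, b of length k is the Pearson
correlation of the 2k-vector (a, b) with (b, a), equivalently

ICC_DE = 2 Σ(aᵢ−m)(bᵢ−m) / (Σ(aᵢ−m)² + Σ(bᵢ−m)²),  m the grand mean.

It penalizes differences in elevation and scatter as well as shape.
Profiles of correlations are Fisher-z transformed by default before
comparison (raw-r mode available).  Profiles must have at least three
elements and nonzero pooled variance.  Pairs with missing elements fall
back to the shared complete subset, whose size is reported.

One often-stated bound — |ICC_DE| ≤ |Pearson(a, b)| — is *not* true in
general: two nearly flat profiles at different elevations have Pearson
near zero but ICC_DE near −1.  The provable version, asserted by the
property tests, is one-sided: whenever ICC_DE ≥ 0, ICC_DE ≤ Pearson,
with equality when the two profiles share mean and variance.

Matrix-level profile similarity treats the unique off-diagonal cells of
two same-labeled correlation matrices as one profile each.  Note that the
bundled printed reference matrices for self- vs informant-rated
convergent validity yield a matrix-level ICC_DE of ≈.77, while the
original report of that comparison gives .97 alongside a non-significant
equality χ² — both irreconcilable with the printed values and evidently
computed on unrounded subsample matrices available only in the raw data.
The package computes from its actual inputs; it does not special-case
this discrepancy.

## Informant agreement

Informant ratings are averaged per target and measure (arithmetic mean,
count carried).  Consensus uses the one-way random-effects decomposition:
ICC(1) = (MSB − MSW)/(MSB + (k₀−1)MSW) and ICC(1,k) = (MSB − MSW)/MSB,
with k₀ = (N − Σkᵢ²/N)/(n−1) for unbalanced designs.  On balanced designs
ICC(1,k) equals the Spearman–Brown step-up of ICC(1) at k, verified to
1e−10; an independent cross-check against `pingouin` runs in the test
suite.  Negative ICC(1) down to −1/(k₀−1) is reported as computed.

The standardized mean difference d between self- and informant-ratings
divides by the pooled SD of the two score distributions (the
conventional reading of a "standardized mean difference", comparable to
a between-group d); the difference-score variant d_z is available behind
a flag.  Positive d means the self-rating is higher.  Zero-variance
difference scores make t undefined and are flagged degenerate.  Targets
without informants are excluded listwise.

## Constrained-correlation likelihood-ratio test

Whether two measures m₁, m₂ correlate equally with a correlate y is
tested by nesting two multivariate-normal models: a saturated model (all
correlations free; its ML fit is exactly the sample covariance, so its
discrepancy is zero) and a constrained model forcing
corr(m₁, y) = corr(m₂, y).  The statistic is N·F̂ with
F = log|Σ| + tr(SΣ⁻¹) − log|S| − p minimized over Σ, referred to χ²(1).

Numerical choices: the constrained family is parameterized by one log-SD
per variable plus one Fisher-z per unique correlation, the two
constrained cells sharing a single z parameter — smooth, unconstrained,
and the equality holds by construction.  Positive definiteness is
enforced by the objective (+∞ outside the PD cone; the optimizer starts
at the PD sample estimate and backtracks).  BFGS with a tight gradient
tolerance, polished by Nelder–Mead on the rare non-convergence.  N (the
complete-case count) scales the discrepancy; N−1 is switchable.  A
negative χ² beyond 1e−6 raises (the constrained model can never beat the
saturated one; such a value means the optimizer failed).  The statistic
is invariant to affine rescaling of any variable, which the tests check.

Each test uses the listwise-complete subsample of its model variables
(the likelihood needs a joint sample).  The default model scope is the
minimal three-variable set; a batch scope entering all measures of the
active batch is available — the saturated fits agree cell-wise either
way, the constrained optima can differ slightly.  Batch partitions keep
structurally dependent pairs (a total score and its own facets) from
being tested against each other.  Significance is declared at p < .001
with no further multiplicity correction, replicating the applied
convention for such scans.  The test was cross-checked against a
brute-force maximization of the constrained likelihood over
(r_shared, r₁₂, SDs) and calibrated under the null by simulation
(rejection rate within the binomial band at α = .05, n = 300).

## Heise three-occasion reliability

Under the quasi-simplex — observed X_t = √ρ·T_t + √(1−ρ)·e_t with
stationary T_{t+1} = s·T_t + √(1−s²)·ζ — the observed autocorrelations
are r₁₂ = r₂₃ = ρs and r₁₃ = ρs², so ρ = (r₁₂·r₂₃)/r₁₃ exactly.  The
estimator assumes evenly spaced occasions, a lag-1 true-score process,
and white error.  No clamping: estimates outside [0, 1] are flagged, as
is a denominator |r₁₃| < .1 (unstable).  Pairwise deletion across lags is
the default ("full" sample); a "panel" mode restricts to subjects
observed at all three waves.

Interval bounds follow the literal propagation convention: the formula
applied to the three lower (resp. upper) per-lag confidence limits.
Because the lower-bound r₁₃ enters the denominator, this interval is not
a calibrated confidence interval; its empirical coverage is whatever it
is (the tests report recovery of ρ, never coverage).  A clearly labeled
delta-method interval on the log scale is provided as the alternative.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume:

* **Measurement model.**  A standard-normal latent trait; measure m's
  true score is λ_m·L + √(1−λ_m²)·U_m and its observed score
  √rel_m·T + √(1−rel_m)·E, so corr(X_m, X_m′) = λλ′√(rel·rel′).
* **Correlates.**  C_j = c_j·L + √(1−c_j²)·noise, giving
  corr(C_j, X_m) = c_j λ_m √rel_m.
* **Informants.**  A target-level perception P = v·L + √(1−v²)·W shared
  by all informants of a target (v = informant validity), of which each
  informant holds √a·P + √(1−a)·Q_i (a = consensus).  Ratings apply the
  same measurement model to the informant's perception.  This two-level
  design makes ICC(1) (= rel·λ²·a) and single-informant agreement
  (= rel·λ²·√a·v) independently tunable.  Informant counts are drawn
  from a distribution over 1–6.
* **Three-wave simplex** as in the Heise section, with per-wave retention
  applied as missing-completely-at-random dropout.

Defaults describe a realistic validation study of this kind: n = 700
targets, loadings .80–.95, reliabilities .71–.94 (the range such
instruments print), informant validity .65, consensus .55, uniform 1–6
informants, and for the panel n = 411 with retention (1, .67, .67),
reliability .75, stability .90.  The implied full correlation matrix is
checked for positive semi-definiteness before sampling; eigenvalues in
(−1e−6, 0) are repaired by clipping and rescaling, anything more
indefinite raises (silently repairing a badly mis-specified structure
would hide user error).  Scores are continuous; an optional
equal-probability discretization onto a k-point scale mimics Likert
response formats.  All randomness flows from the spec's single seed.

What the generator does **not** emulate: item-level structure (so
internal consistency cannot be estimated from generated data —
reliabilities are inputs), informant-selection effects (real informants
are not missing at random; observed data show lonelier targets recruit
fewer informants, which the generator's MCAR informant counts do not
reproduce — a diagnostic correlation is exposed for real data), rater
mean biases, non-normal or floor/ceiling score distributions, and
self-informant shared method variance.  Passing tests therefore show the
estimators recover the parameters of this idealized structure, not that
real rating data satisfy it.

## Pipeline

`run_validity_study` and `run_heise_study` orchestrate the stages over
either a generator spec or delimited input tables (long-format ratings;
per-target correlates; measure metadata with reliabilities), honoring
analysis toggles, a single seed, and fixed alpha thresholds (.01 display
flag, .001 for pairwise tests).  Every display table is derived from the
machine-readable `summary.json` by rounding alone; reruns with the same
seed are byte-identical.  The command line (`psyvalid simulate |
validity | heise`) is a thin wrapper over these functions.

## Problem sizes in the test suite

Monte-Carlo checks use sizes chosen to bound sampling error well below
the asserted tolerances: 50 000 observations for ±.01–.02 checks of
implied correlations; 200 seeds × n = 5000 per (ρ, s) grid point for
Heise recovery within ±.03; 500 replicates at n = 300 for the LRT null
calibration; 200 replicates at n = 300 for the matrix-equality
calibration.  The whole suite runs in well under a minute on one CPU.

## Known limitations

* The matrix-equality χ² is approximate whenever matrix cells are
  dependent (overlapping variables, correlated populations) and when the
  two matrices share subjects; both situations are flagged, not fixed.
* The propagated Heise interval is a reporting convention, not a
  confidence procedure.
* Cross-study comparisons require explicit label maps; no fuzzy matching
  of measure or correlate names.
* No p-value adjustment beyond fixed thresholds; no robust or rank-based
  correlation options.
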