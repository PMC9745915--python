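# Methods

## Model

Each group *i* = 1..k is an i.i.d. sample from a delta-lognormal
distribution: an observation equals 0 with probability δ′ᵢ and is otherwise
lognormal(μᵢ, σ²ᵢ). Zeros are exact — the model has a point mass at 0, so
no epsilon threshold is applied to small positive values. The sufficient
statistics per group are the counts (n, n₀, n₁) and the mean ȳ₁ and
unbiased variance s²₁ of the natural logs of the positive observations.
The zero probability is estimated by the binomial MLE δ̂′ = n₀/n.

For a percentile level p ≤ δ′ the p-th quantile is 0 and interval
estimation is vacuous; such requests raise `PercentileAtZeroMass`. For
p > δ′ the quantile is exp(λ_p) with λ_p = μ + Φ⁻¹(η)σ and
η = (p − δ′)/(1 − δ′): the level is renormalised to the positive component.
All computation stays on the log scale; exponentiation happens only when an
interval or point estimate is reported, which avoids overflow for large σ².

## Common percentile and its weights

The common percentile across groups is the inverse-variance weighted
average of the per-group log-scale estimates λ̂_p,i = ȳ₁ᵢ + Φ⁻¹(η̂ᵢ)·s₁ᵢ.
The variance attached to λ̂_p,i combines two component formulas,
`var_ybar1` and `var_s2_1`, that carry exp(μ) factors (they are
back-transformed-scale expressions); they are implemented term by term as
printed in the formulas this package reimplements. Two circulating forms of
the combination differ in the placement of the squared normal quantile
z_p² = Φ⁻¹(p)²:

- `variance_form="eq41"` (default): λ²·Var(Ȳ) + z_p²·Var(S²)
- `variance_form="eq8"`:            λ²·(Var(Ȳ) + z_p²·Var(S²))

The default is the form used consistently by the fiducial and Bayesian
constructions; the other is retained as a switch. The weighted average is a
convex combination, so the pooled log percentile always lies within the
range of the per-group estimates, and it is invariant to a common rescaling
of all variances.

## FGCI

For g = 1..m, per group: draw χ² ~ chi-square(n₁−1) for the σ² pivot
R_σ² = (n₁−1)s²₁/χ²; draw (Z, U) for the Student-type pivots of μ and λ;
draw V ~ Uniform(0,1) for the zero-probability pivot
R_δ′ = H⁻¹(V·H(p; n₀+½, n₁+½)), a Beta(n₀+½, n₁+½) variate truncated to
[0, p]. The λ pivot is

    R_λ = R_μ + √R_σ²/√n₁ · (Z + Φ⁻¹(R_η)√n₁) / d,
    R_μ = ȳ₁ − Z/d · √((n₁−1)s²₁/n₁),

with the same (Z, U) appearing in both pivots of a group (the draws are
fresh and independent across groups and iterations). Per-group draws are
combined with per-draw inverse-variance weights (the variance formulas
evaluated at (R_μ, R_σ²)), and the interval is the exp of the empirical
α/2 and 1−α/2 quantiles (linear interpolation between order statistics,
the type-7 convention; differences between quantile conventions are
O(1/m)).

**The studentising divisor d.** The one-sample form of this construction
defines the studentising variate as U₍₁₎ = √(χ²ₙ₁₋₁/(n₁−1)), i.e. a
*normalised* chi-square under the square root. The k-group formulas write
the divisor as √U with U described as chi-square distributed, which admits
two readings:

- `pivot_scaling="normalized"` (default): U ~ χ²/(n₁−1), so d = √(χ²/df) —
  the divisor equals the one-sample U₍₁₎ exactly;
- `pivot_scaling="chi2"`: U ~ χ² and d = √χ².

The raw reading shrinks the percentile-shift term Φ⁻¹(R_η)·σ by roughly
√n₁, collapsing the pivot's dispersion: in simulation its intervals cover
the true common percentile only a few percent of the time, so it cannot be
a usable construction. The normalised reading makes the one-group pivot
conservative (its μ component is overdispersed relative to the sampling
distribution of ȳ₁), but the k-group precision weighting concentrates the
combined draws, and the resulting intervals attain small-sample coverage
slightly above the nominal level — the documented operating behaviour of
the method. The normalised reading is therefore the default; the raw one is
kept for comparison.

## Adjusted MOVER

The only closed-form method. Single-group limits come from the noncentral-t
construction for a lognormal percentile:

    l, u = ȳ₁ ∓ t*·s₁/√n₁,   t* = quantile of t(n₁−1, ncp = Φ⁻¹(η̂)√n₁),

with the (1−α) quantile for both limits by default
(`alpha_mode="one-sided"`; `"two-sided"` uses 1−α/2). Variance estimates
are recovered from the limits, V̂ar_l = (λ̂−l)²/z²_{α/2} and
V̂ar_u = (u−λ̂)²/z²_{α/2}; the pooled estimate λ̂_p uses the average of the
two as its weight; and the interval re-expands around λ̂_p:

- `weight_style="squared"` (default): wings
  √(Σ(λ̂ᵢ−lᵢ)²/V̂ar²_{l,i} / Σ1/V̂ar²_{l,i}) (and likewise above) — the
  printed squared-variance form;
- `weight_style="first-order"`: the standard MOVER expansion
  √(Σ wᵢ²(λ̂ᵢ−lᵢ)²) with normalised weights wᵢ.

Note z²_{α/2} cancels from both λ̂_p and the wings, so the recovered-variance
convention does not affect the interval. The squared form is noticeably
conservative in small samples (coverage ≈ 0.96 at nominal 0.95 for k = 3,
n = 10), the first-order form slightly anticonservative (≈ 0.89); neither
choice changes the k = 1 case, where both collapse exactly to the
single-group noncentral-t interval.

## Bayesian HPD intervals

Conjugate posteriors under the reference prior for the positive part:
σ² | y ~ InverseGamma((n₁−1)/2, (n₁−1)s²₁/2) and
μ | σ², y ~ Normal(ȳ₁, σ²/n₁). Priors are fixed; there is no MCMC — all
draws are exact.

- **BS1** draws the zero probability from the same truncated-beta
  construction as the FGCI and forms the percentile draw with the
  Student-type pivot structure (same studentising convention and
  `pivot_scaling` switch). At large n the posterior of (μ, σ²) and the
  fiducial pivots agree, and under a common divisor convention BS1 and
  FGCI intervals coincide (verified at n = 500 in the test suite).
- **BS2** uses the plug-in η̂ (from δ̂′ = n₀/n) inside a noncentral-t
  factor t* at the 1−α level; given a group, t* is a constant, so
  randomness enters only through (μ, σ²). Because t* is an upper-tolerance
  factor, the BS2 draw sits above the true percentile on average; its
  intervals are long in small samples and increasingly miss below as n
  grows. This bias is inherent to the construction, not a tuning choice.

Both variants combine groups with per-draw inverse-variance weights
(variance formulas at the drawn (μ, σ²)) and report the **shortest
empirical HPD window**: sort the m draws, slide a window of
⌈(1−α)m⌉ consecutive order statistics, and take the first window of
minimal width (first-window tie-break). The window is a contiguous pair of
order statistics and is never wider than the equal-tailed interval on the
same draws.

## Simulation harness

`run_study` implements the coverage/length experiment: per replication,
generate k delta-lognormal samples, summarise, build each selected
interval, and record containment of the true common percentile and the
interval length. The true value for heterogeneous configurations is
defined as the inverse-variance weighted combination of the per-group true
λ_p,i with variances evaluated at the true parameters (`true_theta_mode`
equivalent: an explicit `true_theta_value` can be supplied instead); for
homogeneous groups the weights are immaterial.

Replications where any group has fewer than two positives, or an estimated
zero probability at or above p, are regenerated with a bounded retry budget
(default 1000 attempts; exhaustion raises rather than looping). Each
replication draws from child streams spawned off the master seed, one per
(replication, method), so per-method results are identical regardless of
which other methods run.

Default problem sizes are M = 1000 outer replications with m = 500 inner
draws — a desk-scale preset giving a binomial standard error of about 0.007
on a coverage of 0.95; full-scale studies of this design use M = 5000 and
m = 1000. Coverage estimates drift slightly upward with m because the
combined draws are heavy-tailed and empirical quantiles/HPD windows extend
further at larger m (≈ +0.01 between m = 300 and m = 500 at k = 3,
n = 10).

The generator (`sample_delta_lognormal`) emulates i.i.d. delta-lognormal
sampling only: no spatial or temporal correlation between stations or
days, no detection limits or censoring, and no covariates. Passing tests
therefore validate the estimators under the model, not the adequacy of the
model for any particular rainfall network.

## Model selection for the positive part

`fit_candidates` fits normal, lognormal, gamma and exponential models to
the positive observations by maximum likelihood and compares AIC =
2·(number of parameters) − 2·(maximised log-likelihood). Normal and
lognormal use the closed-form MLE with the ML variance (divisor n), which
is what the maximised likelihood requires; the exponential has the closed
form AIC = 2 + 2n(1 + ln x̄) with one parameter; the gamma is fitted
numerically (moment start, `scipy.stats.gamma.fit` with location pinned at
0). Ties in the minimum are broken toward fewer parameters, then input
order.

## Numerical choices

- Empirical quantiles: numpy's default linear interpolation (type 7).
- The truncated-beta inverse-CDF clamps its output at p, which is exact
  mathematically and guards against the Beta CDF saturating at 1.0 in
  double precision.
- The variance formulas may overflow to infinity for extreme σ² draws;
  infinite variance is treated as zero weight, the correct limit.
- HPD windows are at least 2 draws wide; `m ≥ 100` is enforced for the
  stochastic intervals.
- Noncentral-t quantiles come from `scipy.stats.nct.ppf`; an independent
  chi-square-mixture integral representation of the CDF cross-checks them
  in the test suite.

## The bundled rainfall dataset

Five regional series of daily rainfall (mm) with many exact zeros. Four
series are internally consistent with their published summary statistics
to recomputation precision. The printed Southern series is not (it shows 6
zeros where the published statistics require 13); the default fixture
therefore ships a reconstruction in which seven small positives are set to
zero, reproducing the published counts exactly and the published log-scale
mean (2.07) and variance (3.66) at their printed precision. The series as
printed remains available via `rainfall_fixture(reconciled=False)`.
Southern-dependent results (its AIC values in particular) are reproducible
only to the precision that a 2-decimal reconstruction allows (≈ 0.15 in
AIC).

## Known limitations

- The exotic printed variance formulas used as weights are implemented
  verbatim; they are not delta-method variances of the log-scale estimator,
  and no alternative (bootstrap, delta-method) weighting is offered.
- The squared-weight MOVER combination and the BS2 construction have poor
  operating characteristics in parts of the parameter space (overcoverage
  with growing length, and downward-biased coverage at large n,
  respectively); both are provided as specified, with switches where a
  standard alternative exists.
- Intervals are marginal: no simultaneous inference across several
  percentile levels or group subsets.
- k = 1 fiducial intervals under the default pivot scaling are
  conservative; the precision-weighted combination is what yields
  near-nominal behaviour for k ≥ 2 designs of moderate size.
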