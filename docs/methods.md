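# Methods

## The multinomial index

For a sample of N individuals with offspring counts r_i (total R = Σ r_i)
and exposure times t_i (total T = Σ t_i), define the offspring shares
r̂_i = r_i/R and exposure shares t̂_i = t_i/T. The raw index is the
normalized average squared deviation of observed counts from the counts
expected under perfectly equal reproductive rates, r̄_i = (R/T) t_i:

    M̌(r, t) = (N/R²) Σ_i (r_i − r̄_i)²  =  N Σ_i (r̂_i − t̂_i)²

M̌ generalizes the opportunity for selection I = var(r)/mean(r)² to unequal
exposure; under equal exposure M̌ = I exactly (population variance — the
1/N prefactor in the deviation form forces that convention, and the
form-equivalence tests would fail under the sample-variance convention).

M̌ is positive even when all individuals share one reproductive rate,
because a finite random allocation of R offspring over N individuals is
never perfectly proportional. The bias is removed by subtracting the
expectation of M̌ under the equal-rates null X ~ Multinomial(R, t̂):

    M(r, t) = M̌(r, t) − E[M̌(X, t)],   E[M̌(X, t)] = (N/R)(1 − Σ t̂_i²)

The closed form follows from the multinomial cell variance
R t̂_i (1 − t̂_i); it is validated in the suite against exhaustive
enumeration over all compositions of R into N cells (N ≤ 4, R ≤ 8,
tolerance 1e−12) and against Monte-Carlo draws. M = 0 means the data are
consistent with equal rates; M > 0 means positive skew; M < 0 means
reproduction is shared more equally than chance ("hyper-equal").

### Equivalent computational forms

`mcheck_forms` evaluates M̌ by five routes — count deviations, share
deviations, a full variance decomposition of the residual r − R t̂
(var(r) + var(R t̂) − 2 cov), the residual variance directly, and the
empirical conditional variance about the equal-rate line — and the suite
asserts agreement to 1e−10 on random samples. Two commonly quoted
shortcuts, var(r) − var(R t̂) and var(r)(1 − corr(r, R t̂)²), omit the
in-sample covariance between residual and exposure; they are identities
in expectation under the equal-rate model (law of total variance), not
per sample, and are therefore not used as computational routes.

### Related indices and exact conversions

Under the stated conditions the following are implemented and tested to
machine precision (N, R are the sample size and offspring total behind a
published value):

| relation | condition |
|---|---|
| M̌ = B·N + (N−1)/R (and inverse) | any exposure pattern, sample-N convention |
| M̌ = (N/R)((R−1)Q + 1) (and inverse) | equal exposure |
| M = ((R−1)/R)(Iσ − 1) (and inverse) | equal exposure |
| M = I − (N−1)/R = Δ_I | equal exposure |
| Gini(r) = ΣΣ|r_i−r_j| / (2RN) | equal exposure |

Morisita's index is computed in its classical form
Iσ = N Σ r_i(r_i − 1) / (R(R−1)), the version whose expectation is 1
under random allocation; only this form makes the Iσ↔M relation exact
(the variance identity N Σr² − NR = N² var(r) + R² − NR confirms it).
Nonacs' B uses the sample N in its sampling term by default; the
original N̂ = 1/max(t̂) convention is available via `nonacs_n=True`. Q,
Iσ, Δ_I and Gini are refused with an explanatory error under unequal
exposure rather than silently ignoring exposure, since their relations
to M̌ hold only at t̂_i = 1/N. R = 0 raises an error everywhere — skew is
undefined without reproduction, and silent NaNs would corrupt grid
studies. A single individual holding all reproduction is valid input.

## Age elasticity

The linear-exposure model assumes every unit of time at risk contributes
equally to expected output. With diminishing returns to age, expected
output over an observation window (a, b) is modelled as
E[r | a, b] = α (b^β − a^β) with elasticity β ∈ (0, 1); β → 1 recovers
linear exposure. The effective exposures b_i^β − a_i^β replace t_i in M̌
and in the null expectation.

(α, β) are estimated by Poisson maximum likelihood with mean
α (b^β − a^β): α is profiled out in closed form (α̂ = R / Σ (b^β − a^β)),
leaving a one-dimensional profile likelihood in β, kept inside the open
interval by a logistic transform of the optimization variable (bounded
scalar minimization on the logit scale, |logit β| ≤ 25). Overdispersion
is deliberately ignored at this stage: only the mean function enters the
exposure shares. Data generated with near-linear returns drive the
estimate against the upper constraint; the fit remains strictly interior
and reports convergence, with β̂ ≈ 1 signalling that linear exposure
suffices. Parameter recovery: median |β̂ − β| < 0.05 at N = 500 across
β ∈ {0.3, 0.5, 0.7} (asserted in the suite).

Caveats. Effective exposure b^β − a^β is not invariant to the age unit
when β < 1, so `AgedSample` records the unit and all individuals must
share it. β = 0 and β = 1 are excluded by the open-interval constraint;
for linear exposure use the core estimator with t = b − a. For
arbitrarily nonlinear age effects, `compute_m_age(exposure_fn=...)`
accepts any user-supplied map from (a, b) to positive expected-exposure
weights.

## Bayesian estimation

The latent quantity is the vector p of reproduction shares. With a
multinomial likelihood for the counts and a Dirichlet prior centred on
the exposure shares, p ~ Dirichlet(c·t̂), the posterior is conjugate:
p | r ~ Dirichlet(c·t̂ + r). Each draw yields M̌_draw = N Σ (p_i − t̂_i)²
and M_draw = M̌_draw − (N/R)(1 − Σ t̂²). Defaults: total prior
concentration c = 1 (weakly informative, prior mean exactly on the
equal-rates null), 90% central credible intervals, 4000 draws. Draws are
bitwise-reproducible given a seed. Halving or doubling c moves the
posterior mean of M by well under 10% on the simulated grids (asserted).

Known finite-sample property: the posterior mean of the convex
functional M̌ exceeds the point value by approximately
N (1 − Σ p̄²) / (R + c) — the posterior-spread term, numerically close to
the multinomial null expectation. It vanishes as reproduction
accumulates (≈ 1/rate at fixed N; e.g. ≈ 0.05 at rate 20, ≈ 0.01 at
rate 100) and cancels in contrasts between samples of comparable size
and rate, which is why `contrast_m` is the recommended basis for
population comparisons. Contrast coverage on identical populations is
conservative (measured ≈ 0.96 at nominal 0.90, N = 25). The joint
posterior over (β, p) is out of scope; a fixed β may be supplied via the
age module's effective exposures.

## Simulation engine

`simulate_sample` draws r_i ~ Poisson(t_i · μ · exp(η_i − s²/2)) with
η_i ~ Normal(0, s²): a lognormal–Poisson (negative-binomial-like)
mixture in which s is the exponent of a multiplicative rate-scaling
random effect. The −s²/2 correction keeps the marginal mean at μ t_i for
every s, so the skew knob changes inequality without moving mean RS
(asserted to < 2% at 10⁵ draws). Study levels: skew s ∈ {0.01, 0.31,
0.61} (low/mid/high), mean rate μ ∈ {1, 7, 20}, exposure either equal
(t = 1) or Uniform(0.2, 1.8) (mean 1, strictly positive; bounds
configurable), 30 log-spaced sample sizes on [2, 1000], 500 replicates
per cell — 270,000 datasets at full scale (`full_scale_config`). All
levels are configurable; the tests run reduced grids (typically 5–8
sample sizes × 60–100 replicates) chosen so that every asserted effect
is several Monte-Carlo standard errors wide.

Per-replicate seeds derive from the master seed by stable spawning
(`SeedSequence` keyed on master seed, cell index, replicate), so any
dataset can be regenerated in isolation and reruns are byte-identical.
Indices undefined on a replicate (R = 0; R ≤ 1 for Q and Iσ) are dropped
and counted per index, never recorded as zero.

What the generator does not emulate: real age structure (exposure is a
scalar draw, not a life history), between-group covariance, temporal
autocorrelation in rates, or non-multiplicative forms of rate
heterogeneity. Passing grid tests therefore demonstrate the structural
(in)sensitivity of indices to sample size, mean rate and exposure
spread — not distributional realism for any particular taxon.

Measured laws (asserted in the suite at reduced scale): under equal
exposure B = M/N exactly, so mean B falls as 1/n at fixed skew — the
log–log slope is estimated at the mid-skew level, where mean M ≈ 0.10
stands far above Monte-Carlo noise (at s = 0.01 the expected M is
e^{s²} − 1 ≈ 1e−4, beneath the noise floor of any affordable replicate
count, and cell means can be negative, making log slopes undefined).
Mean M is flat in n (|log–log trend| < 0.2) and orders the skew levels
at every sample size; the known exception — M dips for small samples
from highly skewed populations — is asserted to be present, not absent.

## Reproducing the null-centring result

`scripts/acceptance.py` draws 1,000 datasets X ~ Multinomial(60, equal
shares) for N = 20 and reports the mean of M across them, which should
be zero up to Monte-Carlo error (≈ ±0.005); the suite additionally
checks (N, R) ∈ {(10, 5), (50, 500)}, including the R < N regime.

## Numerical choices

- Equal-exposure detection: relative spread of t̂ below 1e−9.
- Exact null-expectation enumeration refused above C(R+N−1, N−1) = 2×10⁶
  compositions, with a pointer to the analytic/Monte-Carlo methods.
- Population variance (divide by N) throughout the index algebra.
- Validation raises on R = 0, N < 2, non-integer or negative counts,
  non-positive exposures, and malformed simplex vectors; errors name the
  offending row when reading tables.
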