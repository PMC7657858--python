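# multiskew

Robust estimation of reproductive skew with the multinomial index **M**.

## The problem

Reproductive skew — how unevenly reproduction is shared within a group —
is central to behavioural ecology and evolutionary demography, but the
indices traditionally used to measure it (the opportunity for selection
*I*, Nonacs' *B*, Morisita's *I<sub>σ</sub>*, Ruzzante's *Q*, the Gini
coefficient, the maximum mating proportion) confound real skew with
sample size, mean fecundity and observation time. Two populations with
identical reproductive inequality can report very different *B* values
simply because one group is larger; comparative analyses built on such
indices inherit the bias.

The multinomial index fixes this by asking how far the observed
offspring counts deviate from what a *random* allocation of the same
total reproduction over the same individuals (with their actual
exposure times) would produce, and subtracting that chance component
exactly:

```
M̌(r, t) = N Σᵢ (r̂ᵢ − t̂ᵢ)²            raw inequality of offspring shares
                                       r̂ relative to exposure shares t̂
M = M̌ − E[M̌(X, t)],  X ~ Multinomial(R, t̂)
```

with the null expectation available in closed form,
`E[M̌] = (N/R)(1 − Σ t̂ᵢ²)`. M = 0 means reproduction is consistent with
equal rates; M > 0 means more skew than chance; M < 0 means
reproduction is shared *more* evenly than a random allocation.
Because the chance term is removed analytically, M is directly
comparable across group sizes, fecundities and study designs.

The package provides:

- **Point estimation** of M, M̌ and eight classical indices, with exact
  conversion formulas that place published *B*, *Q*, *I<sub>σ</sub>*,
  *Δ<sub>I</sub>* and *I* values onto the M scale
  (`multiskew.indices`, `multiskew.conversions`).
- **Age adjustment** for diminishing reproductive returns to age:
  expected output over a window (a, b) is modelled as α(b^β − a^β) with
  elasticity β fitted by Poisson maximum likelihood
  (`multiskew.age`).
- **Bayesian estimation**: a conjugate Dirichlet–multinomial posterior
  for the reproduction shares, yielding credible intervals for M and
  principled contrasts between populations (`multiskew.bayes`).
- **A simulation engine** reproducing the lognormal–Poisson robustness
  study design: skew, mean rate, exposure heterogeneity and sample size
  vary on a factorial grid, all indices are computed per dataset, and
  per-replicate seeding makes every dataset individually reproducible
  (`multiskew.simulate`).
- **I/O and a thin CLI** (`multiskew estimate|convert|simulate`) for
  table-based workflows (`multiskew.io`, `multiskew.cli`).

See [docs/methods.md](docs/methods.md) for the full model, estimation
details, defaults and limitations.

## Worked example

Four males observed for one season each; one sired all four offspring
(`examples/point_estimates.py`):

```python
from multiskew import ReproductiveSample, compute_m, compute_mcheck

sample = ReproductiveSample(rs=[4, 0, 0, 0], exposure=[1, 1, 1, 1])
est = compute_m(sample)
print(compute_mcheck(sample), est.null_expectation, est.value)
```

Output:

```
N = 4, R = 4 (full monopoly)
M-check (raw index)       = 3.0000
null expectation E[M-check] = 0.7500
M (bias-corrected)        = 2.2500
```

A random multinomial scatter of 4 offspring over 4 equally exposed
males already produces M̌ = 0.75 on average; M = 2.25 is the inequality
*beyond* chance. The same script prints the classical indices for
comparison (I = 3.0, B = 0.5625, Q = 0.6667, I<sub>σ</sub> = 4.0,
Δ<sub>I</sub> = 2.25, Gini = 0.75, MMP = 1.0).

Bayesian comparison of two populations
(`examples/posterior_contrast.py`, N = 200 each, mean rate 20):

```
 high-skew: point M = +0.369, posterior mean = +0.421, 90% CI = (+0.378, +0.463)
  low-skew: point M = -0.001, posterior mean = +0.049, 90% CI = (+0.029, +0.070)

contrast (high - low): mean = +0.372, 90% CI = (+0.327, +0.418)
The interval excludes zero: skew difference supported.
```

Why M instead of B (`examples/robustness_grid.py`, 1,000 simulated
datasets): at constant generative skew, mean B falls with sample size
with a log–log slope of −0.94 (≈ −1, a structural 1/n bias), while mean
M stays flat and keeps the skew levels separated at every n.

Other examples: `examples/age_elasticity.py` (recovers elasticity
β̂ = 0.459 for true β = 0.5 at N = 400 and shows the age adjustment
removing spurious skew: M goes from +0.0499 under linear exposure to
−0.0133 with fitted effective exposure) and
`examples/convert_published.py` (a small table of published B /
Morisita / Δ<sub>I</sub> values converted onto the M scale).

## Command line

```bash
multiskew estimate data.csv --rs-col offspring --exposure-col seasons --posterior --seed 1
multiskew convert published.csv -o converted.csv
multiskew simulate --config grid.yaml --output sim.csv --summary --seed 42
```

`estimate` reads CSV/TSV with per-individual rows (optionally grouped),
`convert` maps columns `index_name,value,n,total_rs` to M̌ and M, and
`simulate` runs a grid study, writing a CSV plus a manifest recording
the seed and configuration.

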