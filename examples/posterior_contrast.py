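"""Bayesian comparison of reproductive skew between two populations.

Simulates a high-skew and a low-skew population, estimates the posterior
of M for each, and contrasts them. The credible interval of the
difference — not the gap between point estimates — is what justifies
claiming the populations differ.
"""

import numpy as np

from multiskew import ReproductiveSample, contrast_m, posterior_m

rng = np.random.default_rng(11)


def population(n, skew_s, rate=20.0):
    eta = rng.normal(0.0, skew_s, n)
    return ReproductiveSample(rng.poisson(rate * np.exp(eta - skew_s**2 / 2)))


high = population(200, skew_s=0.61)
low = population(200, skew_s=0.01)

post_high = posterior_m(high, n_draws=4000, seed=1)
post_low = posterior_m(low, n_draws=4000, seed=2)

for name, post in (("high-skew", post_high), ("low-skew", post_low)):
    lo, hi = post.ci_m
    print(f"{name:>10}: point M = {post.point_m:+.3f}, "
          f"posterior mean = {post.mean_m:+.3f}, "
          f"90% CI = ({lo:+.3f}, {hi:+.3f})")

mean_diff, (lo, hi) = contrast_m(post_high, post_low)
print(f"\ncontrast (high - low): mean = {mean_diff:+.3f}, "
      f"90% CI = ({lo:+.3f}, {hi:+.3f})")
verdict = "excludes" if lo > 0 or hi < 0 else "includes"
print(f"The interval {verdict} zero: "
      f"{'skew difference supported' if verdict == 'excludes' else 'no reliable difference'}.")
print("\nNote: each posterior mean sits slightly above its point estimate")
print("(a finite-sample offset of order N/R); the offset is shared by")
print("comparable samples and cancels in the contrast.")
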