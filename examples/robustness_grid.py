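"""Reduced index-robustness study: why B confounds skew with group size.

Simulates reproductive-success datasets across a grid of sample sizes at
fixed generative skew and mean rate, then compares how mean B and mean M
move with sample size. B falls as 1/n regardless of the underlying skew;
M stays flat and keeps skew levels apart.
"""

import numpy as np

from multiskew import GridConfig, run_grid

config = GridConfig(
    sample_sizes=[10, 30, 90, 270, 810],
    mean_rates=[7.0],
    skew_levels=[0.31, 0.61],
    exposure_modes=["equal"],
    replicates=100,
    seed=3,
)
print(f"running {config.n_datasets} simulated datasets ...")
means = run_grid(config).cell_means()

for index in ("B", "M"):
    print(f"\nmean {index} by sample size:")
    sub = means[means.index_name == index]
    for s in config.skew_levels:
        row = sub[sub.skew_s == s].sort_values("n")
        vals = " ".join(f"{v:+.4f}" for v in row["mean_value"])
        print(f"  skew {s:.2f}:  {vals}")

b = means[(means.index_name == "B") & (means.skew_s == 0.31)].sort_values("n")
slope = np.polyfit(np.log(b["n"]), np.log(b["mean_value"]), 1)[0]
print(f"\nlog-log slope of mean B vs n at skew 0.31: {slope:.2f} (≈ -1)")
print("B shrinks ~tenfold per tenfold increase in n at constant skew —")
print("a structural bias; M's columns stay level and ordered by skew.")
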