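"""Group coding of numerosity in classifier-layer activations.

Generates a planted synthetic activation dataset (7 numerosity groups), then
shows the two signatures of group coding: the upper decile of per-unit mean
activations rises with the number of items while the lower decile of the
per-unit standard deviations falls, with error bars from the 10-repetition
resampling protocol.
"""

import numpy as np

from numsense import decile_stats, gen_activation_dataset, resample_summary, trend_tests
from numsense.config import SynthActivationConfig
from numsense.group_stats import group_summary

cfg = SynthActivationConfig(n_units=200, n_pictures_per_group=600,
                            n_increasing=30, n_decreasing=8,
                            slope_mean=0.05, sigma_scale=0.9, seed=1)
acts = gen_activation_dataset(cfg)
print(f"dataset: {acts.n_pictures} pictures x {acts.n_units} units, "
      f"{cfg.n_increasing}+{cfg.n_decreasing} planted monotone units")

summaries = resample_summary(acts, n_pick=500, reps=10, seed=2)
mean90 = np.array([decile_stats(s, "mean90") for s in summaries])
std10 = np.array([decile_stats(s, "std10") for s in summaries])

print("\n  n   mean 90th pct        std 10th pct")
for k, g in enumerate(range(1, 8)):
    print(f"  {g}   {mean90[:, k].mean():.4f} +/- {mean90[:, k].std():.4f}   "
          f"{std10[:, k].mean():.4f} +/- {std10[:, k].std():.4f}")

tests = trend_tests(group_summary(acts))
print(f"\nANOVA across groups (units as observations):")
print(f"  means: F({tests['mean']['df_between']}, {tests['mean']['df_within']})"
      f" = {tests['mean']['F']:.1f}, p = {tests['mean']['p']:.2e}")
print(f"  stds:  F({tests['std']['df_between']}, {tests['std']['df_within']})"
      f" = {tests['std']['F']:.1f}, p = {tests['std']['p']:.2e}")
print("\nRising mean-decile and falling std-decile with item count are the "
      "group-coding signature: co-activation accumulates and stabilizes as "
      "scenes contain more objects.")
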