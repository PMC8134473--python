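"""The full diversity-time-series pipeline on the synthetic clade battery.

Fifteen synthetic fossil-style richness trajectories (exponential rises,
logistic plateaus, waxing-waning and extinct clades, mass-extinction
survivors, offset pairs) are pushed through the whole workflow: ARR
estimates at every timepoint, every ordered pair of timepoints scored
under the ARR / constant / zero models, AIC weights, and rate-decline
factors.
"""

import numpy as np

from arrkit import (
    analyze_pairs,
    arr_through_time,
    fixture_battery,
    rate_decline_factor,
    rescale_series,
    summarize_support,
)

eps = 0.5
pooled, folds = [], {}
for series in fixture_battery(seed=0):
    series = rescale_series(series)
    folds[series.clade] = rate_decline_factor(arr_through_time(series, eps))
    pooled.extend(analyze_pairs(series, eps, seed=0))

print(f"pooled ordered timepoint pairs across 15 clades: {len(pooled)}")
print(f"mean first-to-last ARR fold decline: {np.mean(list(folds.values())):.1f}x")
print("largest declines:", {k: round(v, 1) for k, v in sorted(folds.items(), key=lambda kv: -kv[1])[:3]})

support = summarize_support(pooled, hi=0.95)
print("\nstrong support summary (weight > 0.95 favors ARR, < 0.05 rejects it):")
print(support.to_string(index=False))
print("\nstrong rejection outweighs strong support even though several battery")
print("clades really did grow exponentially; on flat or waxing-waning")
print("trajectories the fitted exponential loses to current diversity outright.")
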