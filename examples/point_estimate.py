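"""The ARR point estimate and its inversion.

A clade with a Cambrian stem origin (535 Ma) is observed in the Early
Cretaceous (140 Ma) with 3,700 species.  The age-richness-rate estimator
turns that single (age, richness) pair into a net diversification rate,
conditional on an extinction fraction the analyst must simply assume --
and the same datum can be "inverted" to give an extinction-fraction MLE
for any assumed rate instead.
"""

from arrkit import arr_rate, elapsed_time, maximized_datum_probability, mle_extinction_fraction

n = 3700
t = elapsed_time(stem_age_ma=535, observation_age_ma=140)
print(f"elapsed time since stem origin: {t:.0f} my")

for eps in (0.5, 0.9):
    r = arr_rate(n, t, eps)
    print(f"ARR rate at eps = {eps}: r = {r:.4f} per lineage per my")

# the probability of the datum at the maximum is the same for every eps
print(f"maximized datum probability: {maximized_datum_probability(n):.3e} (independent of t and eps)")

# fix the rate instead and estimate eps: equally good, different biology
r_fixed = 0.01
print(f"eps MLE at an assumed r = {r_fixed}: {mle_extinction_fraction(n, t, r_fixed):.4f}")
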