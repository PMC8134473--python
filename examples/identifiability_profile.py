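"""Numerical demonstration that the ARR process is non-identifiable.

For a single age-richness datum the maximized log-likelihood is the same
at every extinction fraction -- and the balanced process with zero net
diversification attains exactly the same value.  Nothing in one datum can
distinguish these scenarios.
"""

import numpy as np

from arrkit import (
    arr_rate,
    likelihood_profile,
    log_maximized_datum_probability,
    mle_speciation_zero,
)
from arrkit.core import geometric_logpmf, geometric_params_balanced

n, t = 3700, 395.0
eps_grid = np.arange(0.0, 0.95, 0.1)

profile, argmax = likelihood_profile(n, t, eps_grid, return_argmax=True)
print("eps     max log L    argmax r    closed-form r")
for eps, logl, r_num in zip(eps_grid, profile, argmax):
    print(f"{eps:4.2f}  {logl:12.6f}  {r_num:10.6f}  {arr_rate(n, t, eps):13.6f}")

print(f"\nprofile spread: {profile.max() - profile.min():.2e} (flat to optimizer tolerance)")
print(f"closed form log[(1/n)((n-1)/n)^(n-1)]: {log_maximized_datum_probability(n):.6f}")

lam_hat = mle_speciation_zero(n, t)
_, lb, l1mb = geometric_params_balanced(lam_hat, t)
print(f"zero-rate model at lambda_hat = (n-1)/t: {geometric_logpmf(n, lb, l1mb):.6f} (same maximum)")
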