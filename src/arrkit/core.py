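"""Closed-form diversification estimators for stem-clade age-richness data.

The age-richness-rate (ARR) estimator converts a clade's stem age ``t`` and
its species richness ``n`` into a point estimate of the net diversification
rate ``r = lambda - mu`` under a constant-rate birth-death process that
starts from a single lineage and is conditioned on clade survival:

    r_hat = (1/t) * log(n * (1 - eps) + eps)

where ``eps = mu / lambda`` is the extinction fraction, which must be chosen
by the analyst.  Conditioned on survival to time ``t``, richness follows a
geometric distribution on {1, 2, ...} with success parameter ``1 - beta``,

    beta = (exp(r t) - 1) / (exp(r t) - eps),        r > 0
    beta = lambda t / (1 + lambda t),                r = 0,

and the probability of the single datum at the maximum-likelihood rate is

    P = (1/n) * ((n - 1)/n)^(n - 1),

independent of both ``t`` and ``eps``.  That independence is the
non-identifiability result this module verifies numerically: any extinction
fraction in [0, 1] -- including the balanced process with ``r = 0`` and
``lambda_hat = (n - 1)/t`` -- assigns the same maximized probability to the
same datum, so a single age-richness pair carries no information about
``eps`` or about whether net diversification is positive at all.

All probability mass is computed and stored in natural-log space;
``beta`` can sit within 1e-300 of 1 for fossil-scale richness, so the
linear-scale pmf underflows long before the log-scale one loses accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "AgeRichnessDatum",
    "BirthDeathParams",
    "elapsed_time",
    "arr_rate",
    "stem_survival_beta",
    "stem_conditional_pmf",
    "stem_conditional_logpmf",
    "geometric_params_from_rate",
    "geometric_params_balanced",
    "geometric_logpmf",
    "maximized_datum_probability",
    "log_maximized_datum_probability",
    "mle_extinction_fraction",
    "mle_speciation_zero",
    "likelihood_profile",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class AgeRichnessDatum:
    """One (richness, elapsed time) observation: the entire input to an ARR
    point estimate.

    Parameters
    ----------
    n : int
        Species richness at the observation time (>= 1).
    t : float
        Elapsed time since the stem origin, in million years (> 0).
    """

    n: int
    t: float

    def __post_init__(self) -> None:
        if self.n < 1 or self.n != int(self.n):
            raise ValueError(f"richness must be an integer >= 1, got {self.n!r}")
        if not self.t > 0:
            raise ValueError(f"elapsed time must be > 0 my, got {self.t!r}")

    def rate(self, eps: float) -> float:
        """ARR net diversification rate at extinction fraction ``eps``."""
        return arr_rate(self.n, self.t, eps)


@dataclass(frozen=True)
class BirthDeathParams:
    """Speciation and extinction rates of a constant-rate birth-death process.

    Rates are per lineage per million years.  The extinction fraction is
    restricted to [0, 1] (``mu <= lam``), the domain covered by the
    identifiability results.
    """

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"speciation rate must be > 0, got {self.lam!r}")
        if not 0 <= self.mu <= self.lam:
            raise ValueError(
                f"extinction rate must satisfy 0 <= mu <= lam, got mu={self.mu!r}, lam={self.lam!r}"
            )

    @property
    def r(self) -> float:
        """Net diversification rate lambda - mu (>= 0)."""
        return self.lam - self.mu

    @property
    def eps(self) -> float:
        """Extinction fraction mu / lambda, in [0, 1]."""
        return self.mu / self.lam


def elapsed_time(stem_age_ma: float, observation_age_ma: float, clade: str | None = None) -> float:
    """Elapsed time (my) from stem origin to an observation.

    Geological ages count backwards from the present (Ma), so the duration
    is ``stem_age_ma - observation_age_ma``.
    """
    if not observation_age_ma >= 0:
        raise ValueError(f"observation age must be >= 0 Ma, got {observation_age_ma!r}")
    if not stem_age_ma > observation_age_ma:
        who = f" for clade {clade!r}" if clade is not None else ""
        raise ValueError(
            f"observation age {observation_age_ma} Ma is at or before the stem origin "
            f"{stem_age_ma} Ma{who}"
        )
    return stem_age_ma - observation_age_ma


def _check_eps(eps: float, *, allow_one: bool = True) -> None:
    hi = 1.0 if allow_one else 1.0 - 1e-15
    if not 0.0 <= eps <= 1.0 or (not allow_one and eps >= 1.0):
        raise ValueError(f"extinction fraction must be in [0, 1{']' if allow_one else ')'}, got {eps!r}")


def arr_rate(n: int, t: float, eps: float) -> float:
    """Age-richness-rate point estimate of net diversification.

    Computes ``(1/t) * log(n (1 - eps) + eps)`` via ``log1p((n-1)(1-eps))``.
    Returns exactly 0 when ``n == 1`` for any ``eps``, and 0 at ``eps == 1``
    for any ``n`` (the argument of the log collapses to 1 at that boundary).
    Non-negative for all valid inputs.
    """
    if n < 1:
        raise ValueError(f"richness must be >= 1, got {n!r}")
    if not t > 0:
        raise ValueError(f"elapsed time must be > 0, got {t!r}")
    _check_eps(eps)
    return math.log1p((n - 1) * (1.0 - eps)) / t


def geometric_params_from_rate(r: float, eps: float, t: float) -> tuple[float, float, float]:
    """(beta, log beta, log(1 - beta)) for the survival-conditioned geometric
    richness distribution at elapsed time ``t`` under rates ``(r, eps)``.

    Uses the algebraically equivalent form
    ``beta = (1 - e^{-rt}) / ((1 - e^{-rt}) + (1 - eps) e^{-rt})`` evaluated
    with ``expm1``, which is accurate to machine precision across the whole
    range of ``rt`` (no series branch needed near r = 0).  ``r == 0`` with
    ``eps < 1`` is the degenerate no-speciation limit beta = 0; the balanced
    process (mu == lam > 0) must go through :func:`geometric_params_balanced`.
    """
    _check_eps(eps, allow_one=False)
    if not t > 0:
        raise ValueError(f"elapsed time must be > 0, got {t!r}")
    if r < 0:
        raise ValueError(f"net rate must be >= 0, got {r!r}")
    x = r * t
    if x == 0.0:
        return 0.0, _NEG_INF, 0.0
    a = -math.expm1(-x)  # 1 - e^{-x}, exact for tiny x
    b = (1.0 - eps) * math.exp(-x)
    denom = a + b  # = 1 - eps * e^{-x}
    log_denom = math.log(denom)
    log1m_beta = math.log1p(-eps) - x - log_denom
    beta = a / denom
    if beta > 0.5:
        # near 1: go through 1 - beta to keep log beta accurate
        log_beta = math.log1p(-math.exp(log1m_beta)) if log1m_beta > -745 else -math.exp(log1m_beta)
    else:
        log_beta = math.log(a) - log_denom
    return beta, log_beta, log1m_beta


def geometric_params_balanced(lam: float, t: float) -> tuple[float, float, float]:
    """(beta, log beta, log(1 - beta)) for the balanced (r = 0) process,
    where ``beta = lam * t / (1 + lam * t)``."""
    if lam < 0:
        raise ValueError(f"speciation rate must be >= 0, got {lam!r}")
    if not t > 0:
        raise ValueError(f"elapsed time must be > 0, got {t!r}")
    L = lam * t
    if L == 0.0:
        return 0.0, _NEG_INF, 0.0
    log1pL = math.log1p(L)
    return L / (1.0 + L), math.log(L) - log1pL, -log1pL


def geometric_logpmf(n: int, log_beta: float, log1m_beta: float) -> float:
    """log[(1 - beta) beta^{n-1}] on the survival-conditioned support n >= 1."""
    if n < 1:
        raise ValueError(f"survival-conditioned support starts at 1, got n={n!r}")
    if log_beta == _NEG_INF:  # beta == 0: point mass at n = 1
        return 0.0 if n == 1 else _NEG_INF
    return log1m_beta + (n - 1) * log_beta


def stem_survival_beta(params: BirthDeathParams, t: float) -> float:
    """Geometric parameter beta of the survival-conditioned richness
    distribution at elapsed time ``t``.

    Continuous across r -> 0: for ``r > 0`` uses the closed form
    ``(e^{rt} - 1)/(e^{rt} - eps)``; at ``r == 0`` exactly, the limit
    ``lam t / (1 + lam t)``.
    """
    if params.r == 0.0:
        return geometric_params_balanced(params.lam, t)[0]
    return geometric_params_from_rate(params.r, params.eps, t)[0]


def stem_conditional_logpmf(n: int, params: BirthDeathParams, t: float) -> float:
    """Log-probability of richness ``n`` at elapsed time ``t``, conditioned
    on clade survival (geometric with parameter ``1 - beta``)."""
    if params.r == 0.0:
        _, lb, l1mb = geometric_params_balanced(params.lam, t)
    else:
        _, lb, l1mb = geometric_params_from_rate(params.r, params.eps, t)
    return geometric_logpmf(n, lb, l1mb)


def stem_conditional_pmf(n: int, params: BirthDeathParams, t: float) -> float:
    """Linear-scale companion of :func:`stem_conditional_logpmf` (may
    underflow to 0 for fossil-scale ``n``; prefer the log form)."""
    return math.exp(stem_conditional_logpmf(n, params, t))


def log_maximized_datum_probability(n: int) -> float:
    """Natural log of (1/n)((n-1)/n)^{n-1}, with the 0^0 = 1 convention at
    n = 1 (the limit of the expression, and the survival-conditioned pmf of
    a point mass at 1)."""
    if n < 1:
        raise ValueError(f"richness must be >= 1, got {n!r}")
    if n == 1:
        return 0.0
    return -math.log(n) + (n - 1) * math.log1p(-1.0 / n)


def maximized_datum_probability(n: int) -> float:
    """Probability of an age-richness datum at the ARR maximum-likelihood
    rate: (1/n)((n-1)/n)^{n-1}.

    Independent of both the elapsed time and the extinction fraction, and
    strictly decreasing in ``n``; n = 1 gives 1 (0^0 = 1 convention).
    """
    return math.exp(log_maximized_datum_probability(n))


def mle_extinction_fraction(n: int, t: float, r: float) -> float:
    """Maximum-likelihood extinction fraction given a fixed net rate ``r``:
    ``eps_hat = (n - e^{rt}) / (n - 1)``.

    Requires ``n >= 2`` (the profile is undefined for a monotypic clade) and
    ``1 <= e^{rt} <= n`` so that the estimate lands in [0, 1].  ``r = 0``
    gives eps_hat = 1; ``e^{rt} = n`` gives eps_hat = 0.
    """
    if n < 2:
        raise ValueError(f"extinction-fraction MLE needs n >= 2, got n={n!r}")
    if not t > 0:
        raise ValueError(f"elapsed time must be > 0, got {t!r}")
    if r < 0:
        raise ValueError(f"net rate must be >= 0, got {r!r}")
    ert = math.exp(r * t)
    if ert > n * (1.0 + 1e-12):
        raise ValueError(
            f"no valid extinction fraction: exp(r t) = {ert:.6g} exceeds n = {n}; "
            "the assumed rate over-predicts the datum"
        )
    eps_hat = (n - ert) / (n - 1)
    return min(1.0, max(0.0, eps_hat))


def mle_speciation_zero(n: int, t: float) -> float:
    """MLE of the speciation rate under the balanced (r = 0) process:
    ``lambda_hat = (n - 1) / t``.  The balanced conditional pmf at this
    rate attains the same maximized datum probability as the r > 0 fit."""
    if n < 1:
        raise ValueError(f"richness must be >= 1, got {n!r}")
    if not t > 0:
        raise ValueError(f"elapsed time must be > 0, got {t!r}")
    return (n - 1) / t


def likelihood_profile(
    n: int,
    t: float,
    eps_grid: Sequence[float],
    *,
    return_argmax: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Maximized conditional log-likelihood of one datum at each extinction
    fraction in ``eps_grid``.

    For each ``eps`` the log of the survival-conditioned geometric pmf is
    maximized numerically over ``r`` in ``[0, log(10 n)/t]`` (the MLE lies
    below that bound by construction).  The returned profile is flat: every
    entry equals ``log_maximized_datum_probability(n)`` up to optimizer
    tolerance, which is the non-identifiability result.  With
    ``return_argmax=True`` also returns the maximizing rates, which match
    the closed-form ARR estimator.

    ``eps`` values must lie in [0, 1): the pmf parameterization degenerates
    at eps = 1 even though the flatness result extends there.
    """
    if n < 2:
        raise ValueError(f"likelihood profile needs n >= 2, got n={n!r}")
    if not t > 0:
        raise ValueError(f"elapsed time must be > 0, got {t!r}")
    r_max = math.log(10.0 * n) / t
    maxima = np.empty(len(eps_grid))
    argmax = np.empty(len(eps_grid))
    for i, eps in enumerate(eps_grid):
        _check_eps(eps, allow_one=False)

        def nll(r: float, eps: float = eps) -> float:
            _, lb, l1mb = geometric_params_from_rate(r, eps, t)
            return -geometric_logpmf(n, lb, l1mb)

        res = minimize_scalar(nll, bounds=(0.0, r_max), method="bounded", options={"xatol": 1e-12})
        if not res.success:
            raise RuntimeError(f"rate optimization failed at (n={n}, t={t}, eps={eps}): {res.message}")
        maxima[i] = -res.fun
        argmax[i] = res.x
    if return_argmax:
        return maxima, argmax
    return maxima
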