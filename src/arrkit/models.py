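"""Richness prediction models and AIC-weight comparison.

Given one timepoint ``(n1, t1)`` of a clade's diversity trajectory, three
parametric models predict the richness distribution at a second elapsed
time ``t2``, each a survival-conditioned geometric distribution anchored so
that its conditional mean at ``t2 == t1`` equals ``n1`` exactly:

* ARR: fit ``r1`` from ``(n1, t1)`` at an assumed extinction fraction and
  project richness from the clade origin, mean ``(e^{r1 t2} - eps)/(1 - eps)``
  (exponential in ``t2``);
* zero: balanced birth-death with ``lambda1 = (n1 - 1)/t1``, mean
  ``1 + lambda1 t2`` (linear in ``t2``);
* constant: geometric with mean ``n1`` regardless of time.

The ARR prediction is anchored at the clade origin -- beta is evaluated at
elapsed time ``t2`` from the stem, not compounded from ``n1`` over
``t2 - t1`` -- which is the unique reading under which the fitted curve
passes exactly through the focal observation and the pmf keeps the
single-lineage geometric form.

Because all three models have one parameter, the Akaike weight of model A
against model B reduces to ``P_A / (P_A + P_B)``.  A fourth, "random" model
(uniform richness on [1, N_max]) supports only absolute-error comparison,
not AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    arr_rate,
    geometric_logpmf,
    geometric_params_balanced,
    geometric_params_from_rate,
    mle_speciation_zero,
)

__all__ = [
    "GeometricPrediction",
    "ModelComparison",
    "PredictionError",
    "arr_prediction",
    "zero_prediction",
    "constant_prediction",
    "model_log_probability",
    "akaike_weight",
    "compare_models",
    "prediction_error",
    "random_model_error",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class GeometricPrediction:
    """Survival-conditioned geometric richness distribution predicted by one
    model at a target elapsed time.

    ``mean`` materializes ``1/(1 - beta)`` on the linear scale and returns
    ``inf`` on overflow; ``log_expected_richness`` is always finite and is
    the quantity to use for fossil-scale projections.
    """

    model_tag: str  # "ARR" | "ZERO" | "CONSTANT"
    beta: float
    log_beta: float
    log1m_beta: float
    n1: int
    t1: float | None
    t2: float | None
    eps: float | None = None
    rate: float | None = None  # fitted r1 (ARR) or lambda1 (ZERO)

    @property
    def log_expected_richness(self) -> float:
        return -self.log1m_beta

    @property
    def mean(self) -> float:
        try:
            return math.exp(self.log_expected_richness)
        except OverflowError:
            return math.inf


@dataclass(frozen=True)
class ModelComparison:
    """Log-probabilities of an observed richness under the three parametric
    models, with the ARR model's Akaike weights against each null."""

    log_prob_arr: float
    log_prob_constant: float
    log_prob_zero: float
    weight_arr_vs_constant: float
    weight_arr_vs_zero: float


@dataclass(frozen=True)
class PredictionError:
    """Signed and absolute error of a predicted conditional mean, with the
    log10-scale richness values used for plotting conventions."""

    signed: float
    absolute: float
    log10_predicted: float
    log10_observed: float


def arr_prediction(n1: int, t1: float, eps: float, t2: float) -> GeometricPrediction:
    """ARR model: rate fitted at the focal point, richness projected from
    the clade origin to elapsed time ``t2``.

    ``eps = 1`` is rejected (the fitted rate is 0 and the conditional-mean
    form is undefined there); use :func:`zero_prediction` for a balanced
    process.  ``n1 = 1`` with ``eps < 1`` degenerates gracefully to a point
    mass at richness 1.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError(
            f"ARR prediction needs extinction fraction in [0, 1), got {eps!r}; "
            "for a balanced (r = 0) process use zero_prediction"
        )
    r1 = arr_rate(n1, t1, eps)
    beta, lb, l1mb = geometric_params_from_rate(r1, eps, t2)
    return GeometricPrediction("ARR", beta, lb, l1mb, n1=n1, t1=t1, t2=t2, eps=eps, rate=r1)


def zero_prediction(n1: int, t1: float, t2: float) -> GeometricPrediction:
    """Zero-net-diversification model: ``lambda1 = (n1 - 1)/t1``; the
    survival-conditioned mean ``1 + lambda1 t2`` grows linearly in ``t2``."""
    lam1 = mle_speciation_zero(n1, t1)
    beta, lb, l1mb = geometric_params_balanced(lam1, t2)
    return GeometricPrediction("ZERO", beta, lb, l1mb, n1=n1, t1=t1, t2=t2, rate=lam1)


def constant_prediction(n1: int) -> GeometricPrediction:
    """Constant model: geometric richness with mean ``n1``, independent of
    both timepoints (beta = (n1 - 1)/n1)."""
    if n1 < 1:
        raise ValueError(f"richness must be >= 1, got {n1!r}")
    if n1 == 1:
        return GeometricPrediction("CONSTANT", 0.0, _NEG_INF, 0.0, n1=n1, t1=None, t2=None)
    beta = (n1 - 1) / n1
    log_beta = math.log(n1 - 1) - math.log(n1)
    log1m_beta = -math.log(n1)
    return GeometricPrediction("CONSTANT", beta, log_beta, log1m_beta, n1=n1, t1=None, t2=None)


def model_log_probability(pred: GeometricPrediction, n2: int) -> float:
    """Log-probability of observed richness ``n2`` under a prediction;
    ``-inf`` (not an exception) when a degenerate point-mass prediction
    misses the observation."""
    return geometric_logpmf(n2, pred.log_beta, pred.log1m_beta)


def akaike_weight(log_p_a: float, log_p_b: float) -> float:
    """Akaike weight of model A against model B for equal parameter counts:
    ``P_A / (P_A + P_B)`` computed as a stable sigmoid of the log-probability
    difference.  Equal inputs give 0.5."""
    if log_p_a == _NEG_INF and log_p_b == _NEG_INF:
        raise ValueError("both models assign zero probability; weight undefined")
    if log_p_a == _NEG_INF:
        return 0.0
    if log_p_b == _NEG_INF:
        return 1.0
    d = log_p_b - log_p_a
    if d >= 0:
        e = math.exp(-d)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(d))


def compare_models(n1: int, t1: float, eps: float, t2: float, n2: int) -> ModelComparison:
    """Score one ordered timepoint pair under the ARR, constant, and zero
    models and compute the ARR model's weight against each null."""
    lp_arr = model_log_probability(arr_prediction(n1, t1, eps, t2), n2)
    lp_const = model_log_probability(constant_prediction(n1), n2)
    lp_zero = model_log_probability(zero_prediction(n1, t1, t2), n2)
    return ModelComparison(
        log_prob_arr=lp_arr,
        log_prob_constant=lp_const,
        log_prob_zero=lp_zero,
        weight_arr_vs_constant=akaike_weight(lp_arr, lp_const),
        weight_arr_vs_zero=akaike_weight(lp_arr, lp_zero),
    )


def prediction_error(pred: GeometricPrediction, n2: int) -> PredictionError:
    """Signed (mean - observed) and absolute error in species, plus both
    richness values on the log10 scale.  Means beyond float range surface
    as ``inf`` errors; ``log10_predicted`` stays finite."""
    if n2 < 1:
        raise ValueError(f"observed richness must be >= 1, got {n2!r}")
    mean = pred.mean
    signed = mean - n2
    return PredictionError(
        signed=signed,
        absolute=abs(signed),
        log10_predicted=pred.log_expected_richness / math.log(10.0),
        log10_observed=math.log10(n2),
    )


def random_model_error(
    n2: int,
    n_max: int,
    draws: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Absolute errors of the random model: uniform integer richness on
    [1, n_max] against the observed ``n2``.

    Supports only absolute-error comparison (a uniform pmf has no fitted
    parameter structure to weight against the geometric models).
    """
    if n_max < 1:
        raise ValueError(f"richness ceiling must be >= 1, got {n_max!r}")
    if draws < 1:
        raise ValueError(f"draws must be >= 1, got {draws!r}")
    if n2 < 1:
        raise ValueError(f"observed richness must be >= 1, got {n2!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.abs(rng.integers(1, n_max + 1, size=draws) - n2)
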