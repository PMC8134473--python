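"""Fossil diversity time-series analysis pipeline.

Takes a clade's richness-through-time series (typically ~10-my bins of
sampling-standardized richness proportional to true richness), rescales it
to absolute species counts, computes ARR estimates at every timepoint,
scores every ordered pair of timepoints under the ARR / constant / zero /
random prediction models, bins results by temporal lag, and summarizes how
often the ARR model is strongly favored or rejected.

Conventions:

* timepoints are stored oldest first (ages strictly decreasing in Ma);
  elapsed times are measured forward from the stem origin;
* lag = t2 - t1 in elapsed my; positive lag predicts forward in time
  (toward the present);
* rescaled richness is rounded to the nearest integer and floored at 1
  (geometric support starts at 1 under survival conditioning);
* lag bins are half-open [lo, hi) aligned to multiples of the bin width on
  both sides of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import arr_rate
from .models import (
    ModelComparison,
    arr_prediction,
    compare_models,
    constant_prediction,
    prediction_error,
    random_model_error,
    zero_prediction,
)

__all__ = [
    "DiversitySeries",
    "LagPairResult",
    "rescale_series",
    "arr_through_time",
    "enumerate_lag_pairs",
    "analyze_pairs",
    "pairs_to_frame",
    "bin_by_lag",
    "summarize_support",
    "rate_decline_factor",
]

RESCALE_MODES = ("none", "present_day_ratio", "peak_calibration")


@dataclass
class DiversitySeries:
    """A clade's richness trajectory with its stem age and rescaling rule.

    ``ages_ma`` must be strictly decreasing (oldest timepoint first) and
    every age must be younger than the stem age.  ``raw_richness`` holds the
    as-deposited values (SQS-like proportional estimates or lineage counts);
    ``scaled_richness`` is populated by :func:`rescale_series` and holds
    integer species counts >= 1.
    """

    clade: str
    stem_age_ma: float
    ages_ma: np.ndarray
    raw_richness: np.ndarray
    rescale_mode: str = "none"
    calibration_richness: float | None = None
    scaled_richness: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.ages_ma = np.asarray(self.ages_ma, dtype=float)
        self.raw_richness = np.asarray(self.raw_richness, dtype=float)
        if self.ages_ma.ndim != 1 or self.ages_ma.shape != self.raw_richness.shape:
            raise ValueError(f"{self.clade}: ages and richness must be 1-d arrays of equal length")
        if len(self.ages_ma) and not np.all(np.diff(self.ages_ma) < 0):
            raise ValueError(f"{self.clade}: ages must be strictly decreasing (oldest first)")
        if len(self.ages_ma) and not np.all(self.ages_ma < self.stem_age_ma):
            bad = self.ages_ma[self.ages_ma >= self.stem_age_ma]
            raise ValueError(
                f"{self.clade}: timepoint age(s) {bad.tolist()} Ma at or before the stem origin "
                f"{self.stem_age_ma} Ma"
            )
        if np.any(self.raw_richness < 0):
            raise ValueError(f"{self.clade}: richness values must be >= 0")
        if self.rescale_mode not in RESCALE_MODES:
            raise ValueError(f"{self.clade}: unknown rescale mode {self.rescale_mode!r}")
        if self.scaled_richness is not None:
            self.scaled_richness = np.asarray(self.scaled_richness, dtype=int)
            if np.any(self.scaled_richness < 1):
                raise ValueError(f"{self.clade}: scaled richness must be >= 1 everywhere")

    def __len__(self) -> int:
        return len(self.ages_ma)

    @property
    def elapsed_my(self) -> np.ndarray:
        """Elapsed time from the stem origin at each timepoint (my)."""
        return self.stem_age_ma - self.ages_ma

    def truncate_extinct(self) -> "DiversitySeries":
        """Drop the trailing zero-richness tail of an extinct clade (the
        survival-conditioned models have no support at richness 0)."""
        positive = np.nonzero(self.raw_richness > 0)[0]
        if len(positive) == 0:
            raise ValueError(f"{self.clade}: no positive-richness timepoints")
        last = positive[-1] + 1
        return replace(
            self,
            ages_ma=self.ages_ma[:last],
            raw_richness=self.raw_richness[:last],
            scaled_richness=None if self.scaled_richness is None else self.scaled_richness[:last],
        )


def rescale_series(series: DiversitySeries) -> DiversitySeries:
    """Convert proportional richness to absolute species counts.

    * ``present_day_ratio``: multiply by calibration richness / raw value of
      the most recent timepoint (the convention for extant marine clades
      calibrated to present-day richness, e.g. 37,000 marine gastropods);
    * ``peak_calibration``: multiply by calibration richness / series
      maximum (the trilobite convention: peak diversity pinned at 1000);
    * ``none``: copy raw values (already absolute lineage counts).

    Scaled values are rounded to the nearest integer and floored at 1.
    """
    if len(series) == 0:
        raise ValueError(f"{series.clade}: empty series")
    raw = series.raw_richness
    if series.rescale_mode == "none":
        factor = 1.0
    elif series.rescale_mode == "present_day_ratio":
        if series.calibration_richness is None:
            raise ValueError(f"{series.clade}: present_day_ratio rescaling needs calibration_richness")
        newest = raw[-1]
        if newest <= 0:
            raise ValueError(
                f"{series.clade}: cannot rescale by present-day ratio; most recent raw richness is {newest}"
            )
        factor = series.calibration_richness / newest
    else:  # peak_calibration
        if series.calibration_richness is None:
            raise ValueError(f"{series.clade}: peak_calibration rescaling needs calibration_richness")
        peak = raw.max()
        if peak <= 0:
            raise ValueError(f"{series.clade}: cannot rescale by peak; series maximum is {peak}")
        factor = series.calibration_richness / peak
    scaled = np.maximum(1, np.rint(raw * factor).astype(int))
    return replace(series, scaled_richness=scaled)


def _require_scaled(series: DiversitySeries) -> np.ndarray:
    if series.scaled_richness is None:
        raise ValueError(f"{series.clade}: series must be rescaled first (rescale_series)")
    return series.scaled_richness


def arr_through_time(series: DiversitySeries, eps: float) -> pd.DataFrame:
    """ARR estimate at every timepoint of a rescaled series.

    Returns a frame with columns ``age_ma, elapsed_my, n, r``, order
    preserved (oldest first).
    """
    n = _require_scaled(series)
    elapsed = series.elapsed_my
    rates = [arr_rate(int(ni), ti, eps) for ni, ti in zip(n, elapsed)]
    return pd.DataFrame(
        {"age_ma": series.ages_ma, "elapsed_my": elapsed, "n": n, "r": rates}
    )


def enumerate_lag_pairs(series: DiversitySeries, positive_only: bool = False) -> list[tuple[int, int]]:
    """All ordered index pairs (i, j), i != j, of a series' timepoints.

    A k-point series yields k(k-1) ordered pairs; the positive-lag subset
    (j later than i, i.e. i < j with oldest-first ordering) has k(k-1)/2.
    """
    k = len(series)
    if k < 2:
        raise ValueError(f"{series.clade}: need at least 2 timepoints, got {k}")
    if positive_only:
        return [(i, j) for i in range(k) for j in range(i + 1, k)]
    return [(i, j) for i in range(k) for j in range(k) if i != j]


@dataclass(frozen=True)
class LagPairResult:
    """One ordered (t1 -> t2) comparison from a diversity series."""

    clade: str
    t1: float
    t2: float
    lag: float
    n1: int
    n2: int
    r1: float
    eps: float
    comparison: ModelComparison
    abs_error_arr: float
    abs_error_constant: float
    abs_error_zero: float
    random_mean_abs_error: float
    degenerate: bool = False


def analyze_pairs(
    series: DiversitySeries,
    eps: float,
    *,
    seed: int | np.random.Generator | None = 0,
    random_draws: int = 200,
    positive_only: bool = False,
) -> list[LagPairResult]:
    """Score every ordered timepoint pair of a rescaled series.

    For each pair: ARR / zero / constant predictions of ``n2`` from
    ``(n1, t1)``, their log-probabilities and absolute errors, the ARR
    model's AIC weight against each null, and the random model's mean
    absolute error (uniform on [1, N_max] with N_max the clade's maximum
    observed richness).  Deterministic given series, eps, and seed -- the
    random model is the only stochastic piece.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"extinction fraction must be in [0, 1) for pair analysis, got {eps!r}")
    n = _require_scaled(series)
    elapsed = series.elapsed_my
    n_max = int(n.max())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results: list[LagPairResult] = []
    for i, j in enumerate_lag_pairs(series, positive_only=positive_only):
        t1, t2 = float(elapsed[i]), float(elapsed[j])
        n1, n2 = int(n[i]), int(n[j])
        rand_err = float(random_model_error(n2, n_max, random_draws, rng).mean())
        try:
            comp = compare_models(n1, t1, eps, t2, n2)
            err_arr = prediction_error(arr_prediction(n1, t1, eps, t2), n2).absolute
            err_const = prediction_error(constant_prediction(n1), n2).absolute
            err_zero = prediction_error(zero_prediction(n1, t1, t2), n2).absolute
            degenerate = False
        except (ValueError, OverflowError):
            # surfaced per-pair rather than aborting the batch
            comp = ModelComparison(math.nan, math.nan, math.nan, math.nan, math.nan)
            err_arr = err_const = err_zero = math.nan
            degenerate = True
        results.append(
            LagPairResult(
                clade=series.clade,
                t1=t1,
                t2=t2,
                lag=t2 - t1,
                n1=n1,
                n2=n2,
                r1=arr_rate(n1, t1, eps),
                eps=eps,
                comparison=comp,
                abs_error_arr=err_arr,
                abs_error_constant=err_const,
                abs_error_zero=err_zero,
                random_mean_abs_error=rand_err,
                degenerate=degenerate,
            )
        )
    return results


def pairs_to_frame(results: Iterable[LagPairResult]) -> pd.DataFrame:
    """Flatten LagPairResult records into a tidy frame (natural-log
    probabilities)."""
    rows = []
    for p in results:
        rows.append(
            {
                "clade": p.clade,
                "t1": p.t1,
                "t2": p.t2,
                "lag": p.lag,
                "n1": p.n1,
                "n2": p.n2,
                "r1": p.r1,
                "eps": p.eps,
                "log_prob_arr": p.comparison.log_prob_arr,
                "log_prob_constant": p.comparison.log_prob_constant,
                "log_prob_zero": p.comparison.log_prob_zero,
                "weight_arr_vs_constant": p.comparison.weight_arr_vs_constant,
                "weight_arr_vs_zero": p.comparison.weight_arr_vs_zero,
                "abs_error_arr": p.abs_error_arr,
                "abs_error_constant": p.abs_error_constant,
                "abs_error_zero": p.abs_error_zero,
                "random_mean_abs_error": p.random_mean_abs_error,
                "degenerate": p.degenerate,
            }
        )
    return pd.DataFrame(rows)


def bin_by_lag(results: Sequence[LagPairResult], bin_width: float = 15.0) -> pd.DataFrame:
    """Per-lag-bin medians of absolute errors and ARR weights.

    Bins are half-open ``[k*w, (k+1)*w)`` aligned to multiples of the width
    on both sides of zero (a lag exactly on an edge falls in the upper bin).
    Empty input yields an empty frame.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be > 0, got {bin_width!r}")
    cols = [
        "bin_lo",
        "bin_hi",
        "n_pairs",
        "median_abs_error_arr",
        "median_abs_error_constant",
        "median_abs_error_zero",
        "median_random_mean_abs_error",
        "median_weight_arr_vs_constant",
        "median_weight_arr_vs_zero",
    ]
    if len(results) == 0:
        return pd.DataFrame(columns=cols)
    df = pairs_to_frame(results)
    idx = np.floor(df["lag"] / bin_width).astype(int)
    rows = []
    for k in sorted(idx.unique()):
        sub = df[idx == k]
        rows.append(
            {
                "bin_lo": k * bin_width,
                "bin_hi": (k + 1) * bin_width,
                "n_pairs": len(sub),
                "median_abs_error_arr": sub["abs_error_arr"].median(),
                "median_abs_error_constant": sub["abs_error_constant"].median(),
                "median_abs_error_zero": sub["abs_error_zero"].median(),
                "median_random_mean_abs_error": sub["random_mean_abs_error"].median(),
                "median_weight_arr_vs_constant": sub["weight_arr_vs_constant"].median(),
                "median_weight_arr_vs_zero": sub["weight_arr_vs_zero"].median(),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def summarize_support(
    results: Sequence[LagPairResult],
    hi: float = 0.95,
    lo: float | None = None,
) -> pd.DataFrame:
    """Fractions of pairs strongly favoring / strongly rejecting the ARR
    model against each null.

    "Strongly favored" means ARR weight > ``hi`` (default 0.95); "strongly
    rejected" means weight < ``lo`` (default 1 - hi).  Pairs are pooled as
    given -- pass a concatenated list to pool across clades.
    """
    if not 0.5 < hi < 1.0:
        raise ValueError(f"hi threshold must be in (0.5, 1), got {hi!r}")
    if lo is None:
        lo = 1.0 - hi
    rows = []
    for pairing, attr in (
        ("arr_vs_constant", "weight_arr_vs_constant"),
        ("arr_vs_zero", "weight_arr_vs_zero"),
    ):
        weights = np.array([getattr(p.comparison, attr) for p in results], dtype=float)
        ok = ~np.isnan(weights)
        total = int(ok.sum())
        rows.append(
            {
                "pairing": pairing,
                "n_pairs": total,
                "frac_favored": float((weights[ok] > hi).sum() / total) if total else math.nan,
                "frac_rejected": float((weights[ok] < lo).sum() / total) if total else math.nan,
                "hi": hi,
                "lo": lo,
            }
        )
    return pd.DataFrame(rows)


def rate_decline_factor(rates: pd.DataFrame | Sequence[tuple[float, float]]) -> float:
    """Fold change of the ARR estimate between the first (oldest, smallest
    elapsed time) and last (most recent) timepoints: ``r_first / r_last``.

    A zero most-recent rate yields ``inf`` (flagged by the caller as an
    infinite fold rather than an error).
    """
    if isinstance(rates, pd.DataFrame):
        pairs = list(zip(rates["elapsed_my"], rates["r"]))
    else:
        pairs = list(rates)
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 timepoints, got {len(pairs)}")
    pairs = sorted(pairs, key=lambda p: p[0])
    r_first, r_last = pairs[0][1], pairs[-1][1]
    if r_first <= 0:
        raise ValueError(f"first rate must be positive, got {r_first!r}")
    if r_last == 0:
        return math.inf
    return r_first / r_last
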