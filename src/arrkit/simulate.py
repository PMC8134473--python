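"""Synthetic diversity data: birth-death simulators, null models, and
canonical trajectory fixtures.

Everything here emits :class:`~arrkit.pipeline.DiversitySeries` in the same
dialect the analysis pipeline consumes, so the full workflow runs without
any external fossil data.  Three families of generators:

* exact (event-driven) linear birth-death trajectories, optionally
  rejection-sampled to hit a target present-day richness -- the substrate
  for push-of-the-past experiments and the brute-force oracle behind the
  survival-conditioned geometric pmf;
* uniform-random richness series: the "no underlying biological process"
  null whose ARR-through-time profile declines like 1/t;
* deterministic trajectory templates (exponential rise, logistic plateau,
  symmetric rise-and-fall, extinction, abrupt mass-extinction drop, and
  time-offset clade pairs) emulating the qualitative shapes of Phanerozoic
  fossil diversity curves: ~10-my sampling bins spanning tens to hundreds
  of millions of years, with optional multiplicative log-normal noise.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import BirthDeathParams, geometric_params_balanced, geometric_params_from_rate
from .pipeline import DiversitySeries

__all__ = [
    "SimulationConfig",
    "simulate_bd_trajectory",
    "simulate_conditioned_bd",
    "random_uniform_series",
    "fixture_series",
    "fixture_battery",
    "oracle_conditional_distribution",
    "tv_distance_to_geometric",
]


@dataclass
class SimulationConfig:
    """Parameters of one birth-death trajectory simulation.

    Rates are per lineage per my; sample times are geological ages (Ma),
    all younger than the stem age.  ``n_present_target`` and
    ``max_attempts`` only matter for conditioned (rejection-sampled) runs.
    """

    lam: float
    mu: float
    stem_age_ma: float
    sample_times_ma: list[float] = field(default_factory=list)
    n_present_target: int | None = None
    max_attempts: int = 1000
    seed: int | None = None
    clade: str = "sim"

    def __post_init__(self) -> None:
        BirthDeathParams(self.lam, self.mu)  # validate rate domain
        self.sample_times_ma = sorted((float(a) for a in self.sample_times_ma), reverse=True)
        if any(a >= self.stem_age_ma for a in self.sample_times_ma):
            raise ValueError("all sample times must be younger than the stem age")
        if any(a < 0 for a in self.sample_times_ma):
            raise ValueError("sample times must be >= 0 Ma")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _simulate_counts(
    lam: float, mu: float, offsets: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exact Gillespie simulation of the lineage count of a linear
    birth-death process started from 1 lineage at time 0, recorded at the
    given ascending time offsets.  Extinct-by-then offsets record 0."""
    out = np.zeros(len(offsets), dtype=int)
    n = 1
    t = 0.0
    total = lam + mu
    p_birth = lam / total
    k = len(offsets)
    i = 0
    expo = rng.exponential
    unif = rng.random
    while i < k:
        if n == 0:
            break  # remaining samples stay 0
        t_next = t + expo(1.0 / (total * n))
        while i < k and offsets[i] < t_next:
            out[i] = n
            i += 1
        t = t_next
        n += 1 if unif() < p_birth else -1
    return out


def simulate_bd_trajectory(
    config: SimulationConfig, rng: int | np.random.Generator | None = None
) -> DiversitySeries:
    """One exact birth-death trajectory sampled at the configured ages.

    Returns a raw (unrescaled, mode ``none``) series; timepoints where the
    clade was already extinct record richness 0 -- call
    :meth:`DiversitySeries.truncate_extinct` before pipeline analysis.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    ages = np.asarray(config.sample_times_ma, dtype=float)  # descending
    offsets = config.stem_age_ma - ages  # ascending elapsed times
    counts = _simulate_counts(config.lam, config.mu, offsets, rng)
    return DiversitySeries(
        clade=config.clade,
        stem_age_ma=config.stem_age_ma,
        ages_ma=ages,
        raw_richness=counts.astype(float),
        rescale_mode="none",
    )


def simulate_conditioned_bd(
    config: SimulationConfig,
    tolerance: float = 0.1,
    rng: int | np.random.Generator | None = None,
) -> tuple[DiversitySeries, int]:
    """Rejection-sample trajectories until the most recent sampled richness
    lands within a relative ``tolerance`` of ``n_present_target``.

    Mirrors conditioning a clade's history on its present-day diversity
    (the push-of-the-past construction): acceptance requires survival plus
    ``|n_T - target| / target <= tolerance``.  ``tolerance=inf`` accepts
    the first surviving run.  Returns (accepted series, attempts used).
    """
    if config.n_present_target is None or config.n_present_target < 1:
        raise ValueError("conditioned simulation needs n_present_target >= 1")
    if not config.sample_times_ma:
        raise ValueError("conditioned simulation needs at least one sample time")
    rng = _as_rng(config.seed if rng is None else rng)
    target = config.n_present_target
    accepted = 0
    for attempt in range(1, config.max_attempts + 1):
        series = simulate_bd_trajectory(config, rng)
        n_final = series.raw_richness[-1]  # most recent sample
        if n_final >= 1 and abs(n_final - target) / target <= tolerance:
            return series, attempt
        if n_final >= 1:
            accepted += 1
    raise RuntimeError(
        f"{config.clade}: no trajectory hit the target window in {config.max_attempts} attempts "
        f"(survival rate {accepted / config.max_attempts:.3f}); widen the tolerance or adjust rates"
    )


def random_uniform_series(
    n_max: int,
    sample_times_ma: list[float],
    stem_age_ma: float,
    seed: int | np.random.Generator | None = None,
    clade: str = "uniform_null",
) -> DiversitySeries:
    """I.i.d. uniform integer richness on [1, n_max] at each sample time:
    the no-biology null whose ARR profile nevertheless declines ~1/t."""
    if n_max < 1:
        raise ValueError(f"richness ceiling must be >= 1, got {n_max!r}")
    rng = _as_rng(seed)
    ages = np.asarray(sorted(sample_times_ma, reverse=True), dtype=float)
    richness = rng.integers(1, n_max + 1, size=len(ages)).astype(float)
    return DiversitySeries(
        clade=clade,
        stem_age_ma=stem_age_ma,
        ages_ma=ages,
        raw_richness=richness,
        rescale_mode="none",
    )


# ---------------------------------------------------------------------------
# deterministic fixture trajectories


def _default_ages(stem_age_ma: float, bin_my: float = 10.0, first_offset_my: float = 10.0) -> np.ndarray:
    """~10-my sampling bins from shortly after the origin to the present."""
    ages = np.arange(stem_age_ma - first_offset_my, -bin_my / 2, -bin_my)
    return np.clip(ages, 0.0, None)


def _template(shape: str, elapsed: np.ndarray, p: dict) -> np.ndarray:
    if shape == "exponential":
        return p.get("n0", 2.0) * np.exp(p["r"] * elapsed)
    if shape == "logistic":
        n0, K, r = p.get("n0", 2.0), p["K"], p["r"]
        return K / (1.0 + (K / n0 - 1.0) * np.exp(-r * elapsed))
    if shape in ("rise_fall", "extinct"):
        # symmetric waxing and waning around a peak
        return p["peak"] * np.exp(-(((elapsed - p["center"]) / p["sigma"]) ** 2))
    if shape == "mass_extinction":
        n = p.get("n0", 2.0) * np.exp(p["r"] * elapsed)
        drop_elapsed = p["stem_age_ma"] - p["drop_age_ma"]
        n = np.where(elapsed >= drop_elapsed, n * p.get("survival_fraction", 0.25), n)
        return n
    raise ValueError(f"unknown fixture shape {shape!r}")


def fixture_series(
    shape: str,
    *,
    seed: int | np.random.Generator | None = None,
    noise_sd: float = 0.0,
    clade: str | None = None,
    ages_ma: np.ndarray | None = None,
    **params,
) -> DiversitySeries | tuple[DiversitySeries, DiversitySeries]:
    """Deterministic diversity-trajectory template, optionally with
    multiplicative log-normal noise.

    Shapes: ``exponential`` (n0, r), ``logistic`` (n0, K, r), ``rise_fall``
    (peak, center, sigma), ``extinct`` (rise_fall truncated at the last
    timepoint with richness >= 1, before the present), ``mass_extinction``
    (exponential with a proportional drop at ``drop_age_ma``), and
    ``offset_pair`` (two clades with identical trajectories offset by
    ``offset_my``; the younger clade's present-day ARR estimate exceeds the
    older clade's despite identical shapes).  All shapes need
    ``stem_age_ma``; sampling defaults to ~10-my bins.
    """
    if shape == "offset_pair":
        offset = params.pop("offset_my")
        base_shape = params.pop("base_shape", "logistic")
        stem_old = params.pop("stem_age_ma")
        rng = _as_rng(seed)
        old = fixture_series(
            base_shape,
            seed=rng,
            noise_sd=noise_sd,
            clade=(clade or "pair") + "_old",
            stem_age_ma=stem_old,
            **params,
        )
        young = fixture_series(
            base_shape,
            seed=rng,
            noise_sd=noise_sd,
            clade=(clade or "pair") + "_young",
            stem_age_ma=stem_old - offset,
            **params,
        )
        return old, young

    stem_age_ma = params["stem_age_ma"] = float(params["stem_age_ma"])
    ages = np.asarray(ages_ma, dtype=float) if ages_ma is not None else _default_ages(stem_age_ma)
    elapsed = stem_age_ma - ages
    values = _template(shape, elapsed, params)

    if shape == "extinct":
        # keep bins that still resolve >= 2 species after rounding; sampled
        # fossil series never bottom out at a final singleton bin
        alive = values >= 1.5
        if alive.all() or not alive.any():
            raise ValueError(
                f"extinct fixture must die out before the present: min richness {values.min():.3g}"
            )
        last = np.nonzero(alive)[0][-1] + 1
        ages, values = ages[:last], values[:last]
        if ages[-1] <= 0.0:
            raise ValueError("extinct fixture still extant at the present")
    elif np.any(values < 1.0):
        raise ValueError(
            f"{shape} fixture parameters produce richness < 1 at sampled times "
            f"(min {values.min():.3g})"
        )

    if noise_sd > 0.0:
        rng = _as_rng(seed)
        values = values * rng.lognormal(0.0, noise_sd, size=len(values))
    values = np.maximum(1.0, np.rint(values))
    return DiversitySeries(
        clade=clade or shape,
        stem_age_ma=stem_age_ma,
        ages_ma=ages,
        raw_richness=values,
        rescale_mode="none",
    )


def fixture_battery(seed: int | None = 0) -> list[DiversitySeries]:
    """Fifteen synthetic clades spanning the qualitative trajectory shapes
    of the Phanerozoic fossil record (monotonic rises, logistic plateaus,
    waxing-waning and extinct clades, mass-extinction survivors, offset
    pairs, and a flat trajectory), on ~10-my bins over 140-530 my.

    Synthetic stand-ins for the study's 15 fossil series; shapes and scales
    are chosen to be paleontologically plausible, not fitted to any
    deposited dataset.
    """
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.spawn(16))

    def nxt() -> np.random.Generator:
        return np.random.default_rng(next(seeds))

    series: list[DiversitySeries] = []
    series.append(
        fixture_series("exponential", clade="exp_slow", stem_age_ma=530, r=0.012, n0=2, noise_sd=0.1, seed=nxt())
    )
    series.append(
        fixture_series("exponential", clade="exp_fast", stem_age_ma=150, r=0.045, n0=2, noise_sd=0.1, seed=nxt())
    )
    series.append(
        fixture_series("exponential", clade="exp_noisy", stem_age_ma=300, r=0.02, n0=3, noise_sd=0.25, seed=nxt())
    )
    series.append(
        fixture_series("logistic", clade="logistic_plateau", stem_age_ma=400, K=800, r=0.06, n0=2, noise_sd=0.1, seed=nxt())
    )
    series.append(
        fixture_series("logistic", clade="logistic_slow", stem_age_ma=250, K=2000, r=0.03, n0=2, noise_sd=0.1, seed=nxt())
    )
    series.append(
        fixture_series("logistic", clade="flat", stem_age_ma=280, K=400, r=0.05, n0=400, noise_sd=0.1, seed=nxt())
    )
    series.append(
        fixture_series("rise_fall", clade="rise_fall_broad", stem_age_ma=450, peak=1500, center=200, sigma=120, noise_sd=0.1, seed=nxt())
    )
    series.append(
        fixture_series("rise_fall", clade="rise_fall_narrow", stem_age_ma=300, peak=600, center=150, sigma=80, noise_sd=0.1, seed=nxt())
    )
    series.append(
        fixture_series("extinct", clade="extinct_graptoloid_like", stem_age_ma=520, peak=300, center=120, sigma=60, seed=nxt())
    )
    series.append(
        fixture_series("extinct", clade="extinct_trilobite_like", stem_age_ma=530, peak=1000, center=150, sigma=100, seed=nxt())
    )
    series.append(
        fixture_series(
            "mass_extinction", clade="kpg_survivor", stem_age_ma=400, r=0.015, n0=2,
            drop_age_ma=66, survival_fraction=0.25, noise_sd=0.1, seed=nxt(),
        )
    )
    series.append(
        fixture_series(
            "mass_extinction", clade="ptr_survivor", stem_age_ma=350, r=0.02, n0=2,
            drop_age_ma=252, survival_fraction=0.2, noise_sd=0.1, seed=nxt(),
        )
    )
    old, young = fixture_series(
        "offset_pair", clade="offset_logistic", base_shape="logistic",
        stem_age_ma=320, offset_my=120, K=700, r=0.05, n0=2, noise_sd=0.1, seed=nxt(),
    )
    series.extend([old, young])
    series.append(
        fixture_series("logistic", clade="logistic_mid", stem_age_ma=350, K=500, r=0.05, n0=2, noise_sd=0.15, seed=nxt())
    )
    assert len(series) == 15
    return series


# ---------------------------------------------------------------------------
# brute-force oracle for the survival-conditioned geometric kernel


def _final_count(lam: float, mu: float, duration: float, rng: np.random.Generator) -> int:
    n = 1
    t = 0.0
    total = lam + mu
    p_birth = lam / total
    expo = rng.exponential
    unif = rng.random
    while n > 0:
        t += expo(1.0 / (total * n))
        if t >= duration:
            return n
        n += 1 if unif() < p_birth else -1
    return 0


def oracle_conditional_distribution(
    params: BirthDeathParams,
    t: float,
    replicates: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical richness pmf from forward birth-death simulation,
    conditioned on survival to time ``t``.

    Forward-simulates ``replicates`` trajectories, discards those extinct
    by ``t``, and tabulates final richness.  Returns (values, frequencies,
    survival fraction).  This is the independent brute-force check on the
    geometric likelihood kernel, so it never touches the closed forms.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = _as_rng(seed)
    finals = np.fromiter(
        (_final_count(params.lam, params.mu, t, rng) for _ in range(replicates)),
        dtype=int,
        count=replicates,
    )
    surviving = finals[finals > 0]
    if len(surviving) == 0:
        raise RuntimeError(
            f"all {replicates} replicates extinct by t={t}; "
            f"estimated survival probability < {1.0 / replicates:.2g}"
        )
    values, counts = np.unique(surviving, return_counts=True)
    return values, counts / len(surviving), len(surviving) / replicates


def tv_distance_to_geometric(
    values: np.ndarray, probs: np.ndarray, params: BirthDeathParams, t: float
) -> float:
    """Total-variation distance between an empirical richness pmf and the
    survival-conditioned geometric distribution at (params, t)."""
    if params.r == 0.0:
        beta, lb, l1mb = geometric_params_balanced(params.lam, t)
    else:
        beta, lb, l1mb = geometric_params_from_rate(params.r, params.eps, t)
    n_hi = int(values.max())
    geom = np.exp(l1mb + np.arange(n_hi) * lb)  # pmf at n = 1 .. n_hi
    emp = np.zeros(n_hi)
    emp[values - 1] = probs
    tail = beta**n_hi  # geometric mass beyond the observed support
    return 0.5 * (np.abs(emp - geom).sum() + tail)
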