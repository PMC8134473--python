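# arrkit

Age-richness-rate (ARR) diversification estimators, their identifiability
limits, and prediction tests against diversity time series.

## The problem

A large comparative literature estimates a clade's net diversification
rate from just two numbers — its stem age *t* and its extant species
richness *n* — using the "age-richness-rate" (ARR, a.k.a.
method-of-moments or Magallón–Sanderson) estimator for a constant-rate
birth–death process started from one lineage and conditioned on survival:

    r̂ = (1/t) · log[ n(1 − ε) + ε ]

where *r* = λ − μ is the net rate and ε = μ/λ the extinction fraction the
analyst must assume (0.5 and 0.9 are conventional). `arrkit` implements
this estimator together with the machinery needed to probe what it can and
cannot support:

* **The likelihood behind it.** Conditioned on survival, richness is
  geometric on {1, 2, …} with parameter 1 − β, where
  β = (e^{rt} − 1)/(e^{rt} − ε) for r > 0 and β = λt/(1 + λt) for the
  balanced r = 0 process. All probability mass is handled in natural-log
  space (β sits within 10⁻³⁰⁰ of 1 at fossil scales).
* **Non-identifiability.** The maximized probability of a single datum is
  P = (1/n)((n − 1)/n)^{n−1} — independent of both *t* and ε. Any
  extinction fraction, and even the zero-net-diversification process with
  λ̂ = (n − 1)/t, fits one age-richness pair exactly as well as any other.
  The package verifies this numerically (flat ε-profiles, closed-form vs.
  numerical MLEs, the ε̂ = (n − e^{rt})/(n − 1) inversion).
* **Prediction tests.** Given a diversity-through-time series, the rate
  fitted at one timepoint predicts richness at every other timepoint under
  the ARR, zero-rate (linear mean 1 + λ₁t₂), and constant (mean n₁) models;
  models are compared per lagged pair by Akaike weight
  P_ARR/(P_ARR + P_null), plus a uniform "random" model for absolute-error
  baselines.
* **Synthetic data.** Exact (event-driven) birth–death simulation, with
  optional conditioning on present-day richness by rejection sampling
  (push-of-the-past experiments), uniform-random richness nulls, and a
  15-clade battery of deterministic trajectory fixtures, so the whole
  pipeline runs with no external data.

The audience is macroevolution / paleobiology researchers who use or
review clade-level diversification estimates.

## Worked example

A Cambrian-origin gastropod-like clade (stem age 535 Ma) seen by an Early
Cretaceous observer (140 Ma) with 3,700 species — one tenth of the ~37,000
marine species alive today:

```python
from arrkit import arr_rate, elapsed_time, compare_models

t = elapsed_time(stem_age_ma=535, observation_age_ma=140)   # 395 my
arr_rate(3700, t, eps=0.9)    # 0.0150 per lineage per my
arr_rate(3700, t, eps=0.5)    # 0.0190 per lineage per my
```

Projecting the ε = 0.5 rate forward to the present
(`examples/predict_richness.py`) prints:

```
ARR fitted rate r1 = 0.0190 /my
     ARR: predicted mean =        53252 species, |error| =        16252
    ZERO: predicted mean =         5011 species, |error| =        31989
CONSTANT: predicted mean =         3700 species, |error| =        33300
```

On this deliberately ARR-friendly lag (a clade that really did rise
tenfold) the exponential projection overshoots the realized 37,000 species
by ~16,000 and still wins the AIC comparison; on flat, waxing–waning, or
plateaued trajectories it loses badly to the "constant" model — run
`examples/pipeline_fixture_battery.py` to see rejection rates pooled over
the synthetic battery, and `examples/simulation_nulls.py` for the 1/t
decay of ARR estimates under a richness null with no biology in it at all.

Each script in `examples/` is a short, self-contained narrative: a single
estimate (`point_estimate.py`), the flat likelihood profile
(`identifiability_profile.py`), cross-timepoint prediction
(`predict_richness.py`), the full pipeline (`pipeline_fixture_battery.py`),
and the null simulations (`simulation_nulls.py`).

A thin CLI wraps the same library for shell use:

```sh
arr estimate --n 3700 --t 395 --eps 0.9
arr fixtures --out fixtures/ --seed 0
arr pairs --config fixtures/study.yaml
```

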