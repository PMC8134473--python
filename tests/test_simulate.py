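"""Birth-death simulators, null generators, fixtures, and the brute-force
oracle for the geometric kernel."""

import math

import numpy as np
import pytest

from arrkit import (
    BirthDeathParams,
    SimulationConfig,
    arr_rate,
    arr_through_time,
    fixture_battery,
    fixture_series,
    oracle_conditional_distribution,
    random_uniform_series,
    rescale_series,
    simulate_bd_trajectory,
    simulate_conditioned_bd,
    stem_survival_beta,
    tv_distance_to_geometric,
)


def sample_ages(stem, step=10.0, first_offset=10.0):
    return list(np.arange(stem - first_offset, -step / 2, -step).clip(min=0.0))


class TestBdTrajectory:
    def test_pure_birth_is_nondecreasing(self):
        # lam * t = 4: big enough to see growth, small enough to stay exact
        cfg = SimulationConfig(lam=0.02, mu=0.0, stem_age_ma=200, sample_times_ma=sample_ages(200), seed=3)
        s = simulate_bd_trajectory(cfg)
        assert (np.diff(s.raw_richness) >= 0).all()
        assert s.raw_richness[-1] > 1

    def test_same_seed_identical_series(self):
        cfg = SimulationConfig(lam=0.3, mu=0.15, stem_age_ma=30, sample_times_ma=sample_ages(30, step=5.0, first_offset=5.0), seed=11)
        a = simulate_bd_trajectory(cfg)
        b = simulate_bd_trajectory(cfg)
        assert np.array_equal(a.raw_richness, b.raw_richness)

    def test_surviving_mean_matches_conditional_closed_form(self):
        # E[n | survival] = (e^{rt} - eps)/(1 - eps)
        lam, mu, t = 0.3, 0.15, 10.0
        cfg = SimulationConfig(lam=lam, mu=mu, stem_age_ma=t, sample_times_ma=[0.0])
        rng = np.random.default_rng(5)
        finals = np.array(
            [simulate_bd_trajectory(cfg, rng).raw_richness[-1] for _ in range(4000)]
        )
        surv = finals[finals > 0]
        expect = (math.exp((lam - mu) * t) - 0.5) / 0.5
        se = surv.std() / math.sqrt(len(surv))
        assert abs(surv.mean() - expect) < 4 * se

    def test_supercritical_extinction_outside_domain(self):
        # mu > lam falls outside the studied extinction-fraction domain
        with pytest.raises(ValueError):
            SimulationConfig(lam=0.05, mu=0.5, stem_age_ma=200, sample_times_ma=sample_ages(200))

    def test_extinct_samples_record_zero_and_truncate(self):
        # scan seeds until a critical-process run survives part-way and then
        # dies: zeros must form an absorbing suffix that truncation removes
        for seed in range(100):
            cfg = SimulationConfig(
                lam=0.2, mu=0.2, stem_age_ma=300, sample_times_ma=sample_ages(300), seed=seed
            )
            s = simulate_bd_trajectory(cfg)
            if (s.raw_richness == 0).any() and (s.raw_richness > 0).any():
                first_zero = int(np.argmax(s.raw_richness == 0))
                assert (s.raw_richness[first_zero:] == 0).all()  # extinction absorbs
                assert (s.truncate_extinct().raw_richness > 0).all()
                return
        pytest.fail("no partially surviving critical run in 100 seeds")


class TestConditionedBd:
    def test_infinite_tolerance_accepts_first_surviving(self):
        cfg = SimulationConfig(
            lam=0.3, mu=0.0, stem_age_ma=50, sample_times_ma=[25.0, 0.0],
            n_present_target=1, seed=2,
        )
        series, attempts = simulate_conditioned_bd(cfg, tolerance=math.inf)
        assert attempts == 1  # pure birth always survives
        assert series.raw_richness[-1] >= 1

    def test_accepted_run_within_tolerance(self):
        cfg = SimulationConfig(
            lam=0.08, mu=0.04, stem_age_ma=150, sample_times_ma=sample_ages(150),
            n_present_target=100, max_attempts=5000, seed=4,
        )
        series, _ = simulate_conditioned_bd(cfg, tolerance=0.3)
        n_final = series.raw_richness[-1]
        assert abs(n_final - 100) / 100 <= 0.3

    def test_exhausted_attempts_reports_diagnostics(self):
        cfg = SimulationConfig(
            lam=0.05, mu=0.0, stem_age_ma=20, sample_times_ma=[0.0],
            n_present_target=10_000, max_attempts=5, seed=0,
        )
        with pytest.raises(RuntimeError, match="widen the tolerance"):
            simulate_conditioned_bd(cfg, tolerance=0.01)

    def test_push_of_the_past_inflates_early_rates(self):
        # conditioning on a large present-day richness inflates early-time
        # ARR estimates relative to the true rate, and the inflation decays
        lam, mu = 0.08, 0.04  # r = 0.04, eps = 0.5
        rng = np.random.default_rng(8)
        early, late = [], []
        for _ in range(40):
            cfg = SimulationConfig(
                lam=lam, mu=mu, stem_age_ma=150, sample_times_ma=sample_ages(150),
                n_present_target=int(math.exp(0.04 * 150)), max_attempts=20_000,
            )
            s, _ = simulate_conditioned_bd(cfg, tolerance=0.5, rng=rng)
            df = arr_through_time(rescale_series(s.truncate_extinct()), 0.5)
            early.append(df["r"].iloc[0])
            late.append(df["r"].iloc[-1])
        assert np.median(early) > 0.04  # push of the past
        assert np.median(early) > np.median(late)
        assert np.median(late) == pytest.approx(0.04, rel=0.5)


class TestUniformNull:
    def test_degenerate_ceiling(self):
        s = random_uniform_series(1, [50.0, 0.0], 100.0, seed=0)
        assert (s.raw_richness == 1).all()

    def test_empirical_mean(self):
        s = random_uniform_series(1000, list(np.linspace(99, 0, 1000)), 100.0, seed=0)
        assert s.raw_richness.mean() == pytest.approx(500.5, rel=0.05)

    def test_median_rate_declines_like_one_over_t(self):
        # no biology at all, yet the ARR profile decays ~1/t
        times = list(np.round(300.0 - np.geomspace(10, 290, 12)).clip(min=0.0))
        rates = []
        for i in range(100):
            s = rescale_series(random_uniform_series(1000, times, 300.0, seed=i))
            rates.append(arr_through_time(s, 0.5)["r"].to_numpy())
        med = np.median(np.array(rates), axis=0)
        assert (np.diff(med) < 0).all()


class TestFixtures:
    def test_offset_pair_young_clade_looks_faster(self):
        # identical trajectories offset in time: the younger clade's
        # present-day ARR estimate exceeds the older clade's
        old, young = fixture_series(
            "offset_pair", base_shape="logistic", stem_age_ma=320, offset_my=120,
            K=700, r=0.05, n0=2, seed=0,
        )
        r_old = arr_rate(int(old.raw_richness[-1]), old.stem_age_ma, 0.5)
        r_young = arr_rate(int(young.raw_richness[-1]), young.stem_age_ma, 0.5)
        assert r_young > r_old

    def test_mass_extinction_penalizes_only_the_older_clade(self):
        # drop predates the younger clade's origin: identical rates while
        # contemporaneous, lower present-day ARR for the older clade
        r = 0.015
        old = fixture_series(
            "mass_extinction", stem_age_ma=400, r=r, n0=2, drop_age_ma=66,
            survival_fraction=0.25,
        )
        young = fixture_series("exponential", stem_age_ma=50, r=r, n0=2)
        r_old = arr_rate(int(old.raw_richness[-1]), old.stem_age_ma, 0.5)
        r_young = arr_rate(int(young.raw_richness[-1]), young.stem_age_ma, 0.5)
        assert r_old < r_young

    def test_logistic_plateau_rate_decays_like_one_over_t(self):
        s = rescale_series(fixture_series("logistic", stem_age_ma=400, K=800, r=0.08, n0=2))
        df = arr_through_time(s, 0.5)
        plateau = df[df["elapsed_my"] > 200]
        assert np.allclose(plateau["r"] * plateau["elapsed_my"], plateau["r"].iloc[0] * plateau["elapsed_my"].iloc[0], rtol=0.02)

    def test_extinct_fixture_truncates_before_present(self):
        s = fixture_series("extinct", stem_age_ma=520, peak=300, center=120, sigma=60)
        assert s.ages_ma[-1] > 0
        assert (s.raw_richness >= 1).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="richness < 1"):
            fixture_series("exponential", stem_age_ma=300, r=0.01, n0=0.1)
        with pytest.raises(ValueError, match="extinct"):
            fixture_series("extinct", stem_age_ma=300, peak=300, center=150, sigma=500)

    def test_battery_is_deterministic_and_valid(self):
        a = fixture_battery(7)
        b = fixture_battery(7)
        assert len(a) == 15
        for sa, sb in zip(a, b):
            assert sa.clade == sb.clade
            assert np.array_equal(sa.raw_richness, sb.raw_richness)
            assert (sa.raw_richness >= 1).all()


class TestOracle:
    def test_tv_distance_to_geometric_kernel(self):
        params = BirthDeathParams(0.3, 0.15)
        vals, probs, _ = oracle_conditional_distribution(params, 10.0, 100_000, seed=0)
        assert tv_distance_to_geometric(vals, probs, params, 10.0) < 0.01

    def test_pure_birth_head_probability(self):
        # mu = 0: P(n = 1 | survival) = 1 - beta = e^{-lam t}
        lam, t = 0.2, 5.0
        params = BirthDeathParams(lam, 0.0)
        vals, probs, surv = oracle_conditional_distribution(params, t, 50_000, seed=1)
        assert surv == 1.0  # pure birth never goes extinct
        p1 = probs[vals == 1][0]
        assert p1 == pytest.approx(math.exp(-lam * t), abs=0.01)

    def test_survival_fraction_matches_closed_form(self):
        # P(survival) = 1 - eps * (e^{rt} - 1)/(e^{rt} - eps) = 1 - eps * beta
        lam, mu, t = 0.3, 0.15, 10.0
        params = BirthDeathParams(lam, mu)
        _, _, surv = oracle_conditional_distribution(params, t, 50_000, seed=2)
        expect = 1.0 - params.eps * stem_survival_beta(params, t)
        assert surv == pytest.approx(expect, abs=0.01)

    def test_all_extinct_raises_with_diagnostics(self):
        # critical process with lam*t = 1e5: survival probability ~1e-5, so
        # a handful of replicates is all but certain to go extinct
        with pytest.raises(RuntimeError, match="extinct"):
            oracle_conditional_distribution(BirthDeathParams(10.0, 10.0), 10_000.0, 10, seed=0)
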