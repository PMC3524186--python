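import numpy as np
import pytest
from scipy import stats

from droughtpop.drought_indices import MarkovDroughtParams
from droughtpop.projection import (
    SCENARIOS,
    SimulationConfig,
    SimulatorParams,
    apply_scenario,
    calibrate_intercept,
    expected_drought_months,
    growth_step,
    project_population,
    sample_initial_drought,
    scenario,
    step_drought,
    summarize_species,
)


def uniform_markov(p_init=0.4, ddt=0.5, nddt=0.8, max_len=6):
    dist = np.zeros(12)
    dist[:max_len] = 1.0 / max_len
    return MarkovDroughtParams(p_init, ddt, nddt, dist)


def point_mass_markov(p_init, ddt, nddt, length=3):
    dist = np.zeros(12)
    dist[length - 1] = 1.0
    return MarkovDroughtParams(p_init, ddt, nddt, dist)


class TestDroughtGenerator:
    def test_initial_never_drought(self):
        m = point_mass_markov(0.0, 0.5, 0.5)
        rng = np.random.default_rng(0)
        assert all(sample_initial_drought(m, rng) == 0 for _ in range(100))

    def test_initial_point_mass(self):
        m = point_mass_markov(1.0, 0.5, 0.5, length=3)
        rng = np.random.default_rng(0)
        assert all(sample_initial_drought(m, rng) == 3 for _ in range(100))

    def test_initial_frequency(self):
        m = uniform_markov(p_init=0.4)
        rng = np.random.default_rng(1)
        draws = [sample_initial_drought(m, rng) > 0 for _ in range(10000)]
        assert np.mean(draws) == pytest.approx(0.40, abs=0.02)

    def test_absorbing_drought(self):
        m = point_mass_markov(0.5, 1.0, 0.5)
        rng = np.random.default_rng(2)
        assert all(step_drought(3, m, rng) > 0 for _ in range(100))

    def test_absorbing_nondrought(self):
        m = point_mass_markov(0.5, 0.5, 1.0)
        rng = np.random.default_rng(3)
        assert all(step_drought(0, m, rng) == 0 for _ in range(100))

    def test_stationary_frequency(self):
        # two-state chain: pi = (1-nddt)/((1-nddt)+(1-ddt)) = 0.2/0.7
        m = uniform_markov(ddt=0.5, nddt=0.8)
        rng = np.random.default_rng(4)
        d, hits = 0, 0
        n = 100_000
        for _ in range(n):
            d = step_drought(d, m, rng)
            hits += d > 0
        assert hits / n == pytest.approx(0.2 / 0.7, abs=0.01)

    def test_run_lengths_are_geometric(self):
        # drought runs ~ Geometric(1-ddt), non-drought runs ~ Geometric(1-nddt)
        m = uniform_markov(ddt=0.5, nddt=2 / 3)
        rng = np.random.default_rng(5)
        d = 0
        flags = []
        while True:
            d = step_drought(d, m, rng)
            flags.append(d > 0)
            if len(flags) > 60_000:
                break
        from droughtpop.drought_indices import run_lengths

        rl = run_lengths(flags)
        for runs, p in ((rl.drought_run_lengths[1:-1], 0.5),
                        (rl.nondrought_run_lengths[1:-1], 1 / 3)):
            assert len(runs) > 10_000
            kmax = 8
            obs = np.bincount(np.minimum(runs, kmax), minlength=kmax + 1)[1:]
            probs = np.array([(1 - p) ** (k - 1) * p for k in range(1, kmax)])
            probs = np.append(probs, (1 - p) ** (kmax - 1))
            chi2 = stats.chisquare(obs, probs * len(runs))
            assert chi2.pvalue > 0.01

    def test_step_rejects_invalid_state(self):
        with pytest.raises(ValueError):
            step_drought(13, uniform_markov(), np.random.default_rng(0))


class TestScenarios:
    def test_registry(self):
        assert SCENARIOS["20C"].occurrence_multiplier == 1.0
        assert (SCENARIOS["B1"].occurrence_multiplier, SCENARIOS["B1"].onset_year) == (2.0, 2025)
        assert (SCENARIOS["A2"].occurrence_multiplier, SCENARIOS["A2"].onset_year) == (3.0, 2040)
        with pytest.raises(ValueError):
            scenario("RCP8.5")

    def test_identity_scenario(self):
        m = uniform_markov()
        assert apply_scenario(m, scenario("20C"), 2050) is m

    def test_pre_onset_unchanged(self):
        m = uniform_markov()
        assert apply_scenario(m, scenario("B1"), 2024) is m
        assert apply_scenario(m, scenario("A2"), 2039) is m

    def test_doubling_algebra(self):
        # pi = 0.2/0.7 = 0.2857 -> pi' = 0.5714 -> p_enter' = 2/3
        m = uniform_markov(ddt=0.5, nddt=0.8)
        out = apply_scenario(m, scenario("B1"), 2030)
        assert out.nddt == pytest.approx(1 / 3)
        assert out.ddt == m.ddt
        assert out.stationary_drought_frequency == pytest.approx(
            2 * m.stationary_drought_frequency
        )

    def test_frequency_cap(self):
        # high-persistence chain: tripling overshoots, frequency caps at 0.95
        m = uniform_markov(ddt=0.96, nddt=0.97)  # pi = 0.03/0.07 ~ 0.43
        out = apply_scenario(m, scenario("A2"), 2050)
        assert out.stationary_drought_frequency == pytest.approx(0.95)
        assert out.nddt == pytest.approx(1.0 - 0.95 * 0.04 / 0.05)

    def test_entry_probability_cap(self):
        # with low drought persistence even p_enter = 1 cannot reach 0.95:
        # the entry probability saturates instead
        m = uniform_markov(ddt=0.5, nddt=0.2)  # pi = 0.8/1.3
        out = apply_scenario(m, scenario("A2"), 2050)
        assert out.nddt == 0.0
        assert out.stationary_drought_frequency == pytest.approx(1.0 / 1.5)


class TestGrowthStep:
    def test_drought_free_factor(self):
        p = SimulatorParams("sp", 0.05, -0.04, uniform_markov())
        assert growth_step(100.0, p, 0) == pytest.approx(100 * np.exp(0.05))

    def test_direct_evaluation(self):
        p = SimulatorParams("sp", 0.0, -0.04, uniform_markov())
        assert growth_step(100.0, p, 5) == pytest.approx(100 * np.exp(-0.2))

    def test_negative_abundance_rejected(self):
        p = SimulatorParams("sp", 0.0, 0.0, uniform_markov())
        with pytest.raises(ValueError):
            growth_step(-1.0, p, 0)


class TestProjection:
    def test_deterministic_decline_goes_extinct(self):
        # b = 0: N_t = 1000 * 0.92^t crosses 5 at t ~ 64 < 129 years
        p = SimulatorParams("sp", np.log(0.92), 0.0, uniform_markov())
        proj = project_population(1000, 1970, p, "20C", SimulationConfig(n_sims=50, rng_seed=0))
        assert proj.extinction_probability == 1.0

    def test_deterministic_growth_exact_lambda(self):
        p = SimulatorParams("sp", np.log(1.05), 0.0, uniform_markov())
        proj = project_population(1000, 1970, p, "20C", SimulationConfig(n_sims=50, rng_seed=0))
        assert proj.extinction_probability == 0.0
        assert proj.lambda_mean == pytest.approx(1.05, rel=1e-12)
        assert proj.lambda_sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_without_drought_effect(self):
        p = SimulatorParams("sp", 0.03, 0.0, uniform_markov())
        cfg = SimulationConfig(n_sims=3, end_year=2000, rng_seed=1, store_trajectories=True)
        proj = project_population(500, 1970, p, "20C", cfg)
        t = np.arange(proj.trajectories.shape[1])
        expected = 500 * np.exp(0.03 * t)
        assert np.allclose(proj.trajectories, expected[None, :], rtol=1e-9)

    def test_seeded_reproducibility(self):
        p = SimulatorParams("sp", -0.01, -0.04, uniform_markov())
        cfg = SimulationConfig(n_sims=1, rng_seed=77, store_trajectories=True)
        a = project_population(1000, 1970, p, "B1", cfg)
        b = project_population(1000, 1970, p, "B1", cfg)
        assert np.array_equal(a.trajectories, b.trajectories)
        assert a.lambda_mean == b.lambda_mean

    def test_replicate_order_independence(self):
        # replicate k of a 10-replicate run equals replicate k of a 3-replicate
        # run under the same master seed (independent substreams)
        p = SimulatorParams("sp", -0.01, -0.04, uniform_markov())
        big = project_population(
            1000, 1970, p, "20C",
            SimulationConfig(n_sims=10, rng_seed=5, store_trajectories=True),
        )
        small = project_population(
            1000, 1970, p, "20C",
            SimulationConfig(n_sims=3, rng_seed=5, store_trajectories=True),
        )
        assert np.array_equal(big.trajectories[:3], small.trajectories)

    def test_extinction_is_absorbing(self):
        p = SimulatorParams("sp", -0.08, -0.04, uniform_markov())
        cfg = SimulationConfig(n_sims=200, rng_seed=3, store_trajectories=True)
        proj = project_population(100, 1970, p, "20C", cfg)
        assert proj.extinction_probability == 1.0
        for traj in proj.trajectories:
            first = np.argmax(traj <= 5.0)
            assert np.all(traj[first:] == traj[first])

    def test_extinction_monotone_in_n0_and_a(self):
        m = uniform_markov(p_init=0.4, ddt=0.5, nddt=0.71)
        cfg = SimulationConfig(n_sims=300, rng_seed=9)
        es_n0 = [
            project_population(
                n0, 1970, SimulatorParams("sp", -0.035, -0.04, m), "20C", cfg
            ).extinction_probability
            for n0 in (50, 500, 5000)
        ]
        assert es_n0 == sorted(es_n0, reverse=True)
        es_a = [
            project_population(
                500, 1970, SimulatorParams("sp", a, -0.04, m), "20C", cfg
            ).extinction_probability
            for a in (-0.06, -0.03, 0.0)
        ]
        assert es_a == sorted(es_a, reverse=True)

    def test_rejects_n0_at_threshold(self):
        p = SimulatorParams("sp", 0.0, 0.0, uniform_markov())
        with pytest.raises(ValueError):
            project_population(5.0, 1970, p)


class TestCalibration:
    def test_expected_drought_months_matches_simulation(self):
        m = uniform_markov(p_init=0.4, ddt=0.5, nddt=0.71)
        analytic = expected_drought_months(m, "20C", 1970, 2099)
        p = SimulatorParams("sp", 0.0, 1.0, m)  # R_t = D_t, so lambda logs mean D
        proj = project_population(
            10, 1970, p, "20C", SimulationConfig(n_sims=2000, rng_seed=13)
        )
        simulated = np.log(proj.lambdas).mean()
        assert simulated == pytest.approx(analytic, abs=0.05)

    def test_calibrated_intercept_hits_target_lambda(self):
        m = uniform_markov(p_init=0.4, ddt=0.5, nddt=0.71)
        a = calibrate_intercept(0.92, -0.04, m)
        p = SimulatorParams("sp", a, -0.04, m)
        proj = project_population(
            1000, 1970, p, "20C", SimulationConfig(n_sims=2000, rng_seed=21)
        )
        assert proj.lambda_mean == pytest.approx(0.92, abs=0.005)


class TestSummaries:
    def _proj(self, e, lam):
        from droughtpop.projection import PopulationProjection

        return PopulationProjection(
            population_id="p", start_year=1970, end_year=2099,
            lambda_mean=lam, lambda_sd=0.0, extinction_probability=e,
            n_sims=1, lambdas=np.array([lam]), extinct=np.array([e == 1.0]),
        )

    def test_single_population(self):
        s = summarize_species([self._proj(0.0, 1.0)])
        assert s["lambda_mean"] == 1.0 and s["extinction_probability"] == 0.0

    def test_unweighted_means(self):
        s = summarize_species([self._proj(0.0, 1.0), self._proj(1.0, 1.1)])
        assert s["extinction_probability"] == 0.5
        assert s["lambda_mean"] == pytest.approx(1.05)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            summarize_species([])
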