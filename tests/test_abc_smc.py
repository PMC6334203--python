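"""ABC-SMC engine: priors, distances, generations and posterior summaries."""

import numpy as np
import pytest
from scipy.stats import kstest

from epmodkit.abc_smc import (PriorSpec, SMCConfig, distance,
                              posterior_kde, posterior_predictive,
                              posterior_summary, run_abcsmc, run_generation,
                              sodium_prior, sodium_steady_state_simulator)
from epmodkit.sodium_channel import PRIOR_BOUNDS


class TestPrior:
    def test_samples_inside_bounds_and_uniform(self):
        prior = sodium_prior()
        x = prior.sample(np.random.default_rng(0), 10_000)
        assert np.all(prior.in_support(x))
        for i, name in enumerate(prior.names):
            lo, hi = PRIOR_BOUNDS[name]
            assert kstest(x[:, i], "uniform", args=(lo, hi - lo)).pvalue > 0.01

    def test_seeded_determinism(self):
        prior = sodium_prior()
        a = prior.sample(np.random.default_rng(1), 5)
        b = prior.sample(np.random.default_rng(1), 5)
        np.testing.assert_array_equal(a, b)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="lo < hi"):
            PriorSpec({"a": (1.0, 1.0)})


class TestDistance:
    def test_identical_sets_give_zero(self):
        c = {"a": np.linspace(0, 1, 10), "b": np.ones(5)}
        assert distance(c, c) == 0.0

    def test_constant_offset_single_curve(self):
        a = {"c": np.zeros(7)}
        b = {"c": np.full(7, 0.3)}
        assert distance(a, b) == pytest.approx(0.3)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(2)
        sim = {"u": rng.standard_normal(9), "v": rng.standard_normal(4)}
        obs = {"u": rng.standard_normal(9), "v": rng.standard_normal(4)}
        manual = 0.5 * (np.sqrt(np.mean((sim["u"] - obs["u"])**2))
                        + np.sqrt(np.mean((sim["v"] - obs["v"])**2)))
        assert distance(sim, obs) == pytest.approx(manual, abs=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            distance({"a": np.zeros(3)}, {"a": np.zeros(4)})
        with pytest.raises(ValueError, match="differ"):
            distance({"a": np.zeros(3)}, {"b": np.zeros(3)})


def _toy_problem(seed=11, n_data=25):
    rng = np.random.default_rng(seed)
    true = np.array([1.0, -0.5])
    obs = {"mean": true + rng.normal(0, 1, (n_data, 2)).mean(axis=0)}
    prior = PriorSpec({"mu1": (-5.0, 5.0), "mu2": (-5.0, 5.0)})

    def simulate(theta, r):
        return {"mean": theta + r.normal(0, 1, (n_data, 2)).mean(axis=0)}

    return prior, obs, simulate


class TestGenerations:
    def test_infinite_epsilon_accepts_everything_with_uniform_weights(self):
        prior, obs, sim = _toy_problem()
        gen = run_generation(None, prior, obs, np.inf, sim,
                             SMCConfig(population_size=50),
                             np.random.default_rng(0))
        assert gen.acceptance_rate == 1.0
        np.testing.assert_allclose(gen.weights, 1 / 50)

    def test_weights_normalised_every_generation(self):
        prior, obs, sim = _toy_problem()
        pop = run_abcsmc(prior, obs, sim,
                         SMCConfig(population_size=80, max_generations=4), 1)
        for gen in pop.generations:
            assert np.sum(gen.weights) == pytest.approx(1.0)
            assert np.all(np.isfinite(gen.weights))
            assert gen.ess > 1.0

    def test_epsilons_non_increasing_and_seeded_rerun_identical(self):
        prior, obs, sim = _toy_problem()
        cfg = SMCConfig(population_size=60, max_generations=4)
        a = run_abcsmc(prior, obs, sim, cfg, 5)
        b = run_abcsmc(prior, obs, sim, cfg, 5)
        assert np.all(np.diff(a.epsilons) <= 0)
        np.testing.assert_array_equal(a.final.particles, b.final.particles)

    def test_conjugate_gaussian_posterior_mean_recovered(self):
        """ABC posterior for a Gaussian mean with a flat prior should match
        the analytic posterior (centred on the observed summary) within
        Monte-Carlo error."""
        prior, obs, sim = _toy_problem()
        pop = run_abcsmc(prior, obs, sim,
                         SMCConfig(population_size=300, max_generations=9), 3)
        mean, sd = pop.weighted_mean(), pop.weighted_sd()
        se = sd / np.sqrt(pop.final.ess)
        assert np.all(np.abs(mean - obs["mean"]) < 3 * se)
        # ABC variance is inflated relative to the analytic sd, never below
        assert np.all(sd > 1 / np.sqrt(25) * 0.5)


class TestPosteriorOutputs:
    def _small_pop(self, seed=4):
        prior, obs, sim = _toy_problem()
        return run_abcsmc(prior, obs, sim,
                          SMCConfig(population_size=100, max_generations=3),
                          seed), obs, sim

    def test_summary_orders_min_mean_max(self):
        pop, _, _ = self._small_pop()
        df = posterior_summary(pop)
        assert np.all(df["min"] <= df["mean"] + 1e-12)
        assert np.all(df["mean"] <= df["max"] + 1e-12)

    def test_single_particle_collapses_summary(self):
        pop, _, _ = self._small_pop()
        g = pop.final
        g.particles = g.particles[:1]
        g.distances = g.distances[:1]
        g.weights = np.array([1.0])
        df = posterior_summary(pop)
        np.testing.assert_allclose(df["mean"], df["min"])
        np.testing.assert_allclose(df["mean"], df["max"])

    def test_kde_integrates_to_one(self):
        pop, _, _ = self._small_pop()
        xg, yg, dens = posterior_kde(pop, ("mu1", "mu2"), grid_size=80)
        integral = np.trapezoid(np.trapezoid(dens, yg, axis=1), xg)
        assert integral == pytest.approx(1.0, abs=0.05)

    def test_kde_rejects_degenerate_population(self):
        pop, _, _ = self._small_pop()
        g = pop.final
        g.particles = np.tile(g.particles[:1], (20, 1))
        g.weights = np.full(20, 1 / 20)
        with pytest.raises(ValueError, match="degenerate"):
            posterior_kde(pop, ("mu1", "mu2"))

    def test_predictive_envelope_contains_median(self):
        pop, obs, sim = self._small_pop()
        env = posterior_predictive(pop, sim, n_samples=100, rng=0)
        e = env["mean"]
        assert e["samples"].shape[0] == 100
        assert np.all(e["lo"] <= e["median"] + 1e-12)
        assert np.all(e["median"] <= e["hi"] + 1e-12)

    def test_degenerate_population_gives_zero_width_envelope(self):
        pop, obs, _ = self._small_pop()
        g = pop.final
        g.particles = np.tile(np.array([[1.0, -0.5]]), (30, 1))
        g.weights = np.full(30, 1 / 30)
        env = posterior_predictive(pop, lambda t, r: {"mean": t},
                                   n_samples=20, rng=0)
        np.testing.assert_allclose(env["mean"]["lo"], env["mean"]["hi"])


class TestSodiumForwardModel:
    def test_steady_state_simulator_round_trip(self):
        vg = np.arange(-120.0, 21.0, 5.0)
        prior = sodium_prior()
        sim = sodium_steady_state_simulator(vg, names=prior.names)
        from epmodkit.sodium_channel import ORIG_PARAMS
        theta = np.array([ORIG_PARAMS[n] for n in prior.names])
        curves = sim(theta, None)
        assert set(curves) == {"ss_activation", "ss_inactivation"}
        assert curves["ss_activation"].y[list(vg).index(-45.0)] == pytest.approx(0.5)
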