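"""Objective function, GA operators, ensembles and their statistics."""

import numpy as np
import pytest

from pi3knet.calibration import (
    GAConfig,
    ObservationSet,
    ParameterEnsemble,
    build_ensemble,
    ensemble_statistics,
    make_objective,
    mutation_sigma,
    objective_J,
    run_ga,
)
from pi3knet.network import StimulusInput
from pi3knet.presets import toy_pi3k_chain
from pi3knet.synthetic import NoiseModel, generate_observations, generate_truth


@pytest.fixture(scope="module")
def toy_obs():
    """Noiseless observations from the toy chain at its default parameters."""
    model = toy_pi3k_chain()
    free = ["k_Ract", "k_Pact"]
    truth = generate_truth.__wrapped__ if hasattr(generate_truth, "__wrapped__") \
        else None
    from pi3knet.synthetic import GroundTruth, toy_battery

    log10 = np.log10([model.parameters[n] for n in free])
    gt = GroundTruth(free, log10, seed=0, battery=toy_battery())
    obs = generate_observations(gt, model, NoiseModel(scale=0.0))
    return model, free, log10, obs


class TestObjective:
    def test_perfect_fit_gives_zero(self, toy_obs):
        model, free, log10, obs = toy_obs
        J = objective_J(log10, obs, model, free_names=free,
                        scale_per_observable=False)
        assert J == pytest.approx(0.0, abs=1e-12)

    def test_direct_sum_of_squares(self):
        # residuals (1, 2) with sigma = 1 -> J = 1 + 4 = 5, via a synthetic
        # observation against a frozen zero-dynamics model
        from pi3knet.presets import toy_birth_death

        model = toy_birth_death(k_s=0.0, k_d=0.0)
        model.observable_map = {"X": ["X"]}
        obs = [ObservationSet("c", StimulusInput("IGF-1", 0.0), (), "X",
                              times=[1.0, 2.0], means=[1.0, 2.0])]
        model.ligand_map = {"IGF-1": "L"}
        J = objective_J(np.array([]), obs, model, free_names=[],
                        scale_per_observable=False)
        assert J == pytest.approx(5.0)

    def test_weighted_two_dataset_sum(self):
        # residuals (1) and (3) with sigma (1, 2) -> 1 + 2.25 = 3.25,
        # cross-checked by an independent hand-coded loop
        from pi3knet.presets import toy_birth_death

        model = toy_birth_death(k_s=0.0, k_d=0.0)
        model.observable_map = {"X": ["X"]}
        model.ligand_map = {"IGF-1": "L"}
        obs = [
            ObservationSet("c1", StimulusInput("IGF-1", 0.0), (), "X",
                           times=[1.0], means=[1.0], variances=[1.0]),
            ObservationSet("c2", StimulusInput("IGF-1", 0.0), (), "X",
                           times=[1.0], means=[3.0], variances=[4.0]),
        ]
        J = objective_J(np.array([]), obs, model, free_names=[],
                        scale_per_observable=False)
        by_hand = 0.0
        for o in obs:
            for y_d, var in zip(o.means, o.variances):
                by_hand += ((y_d - 0.0) / np.sqrt(var)) ** 2
        assert J == pytest.approx(by_hand) == pytest.approx(3.25)

    def test_zero_iff_all_residuals_zero(self, toy_obs):
        model, free, log10, obs = toy_obs
        assert objective_J(log10, obs, model, free_names=free,
                           scale_per_observable=False) == pytest.approx(0.0)
        off = log10 + 0.3
        assert objective_J(off, obs, model, free_names=free,
                           scale_per_observable=False) > 0

    def test_variance_must_be_positive(self):
        with pytest.raises(ValueError, match="variances"):
            ObservationSet("c", StimulusInput("IGF-1", 1.0), (), "X",
                           times=[1.0], means=[1.0], variances=[0.0])


class TestMutationSigma:
    def test_printed_schedule_values(self):
        cfg = GAConfig(generations=100)
        assert mutation_sigma(0, cfg) == 1.0
        assert mutation_sigma(1, cfg) == pytest.approx(0.99)
        assert mutation_sigma(100, cfg) == 0.0

    def test_non_increasing_and_terminal_zero(self):
        cfg = GAConfig(generations=30)
        values = [mutation_sigma(k, cfg) for k in range(31)]
        assert all(b <= a for a, b in zip(values, values[1:]))
        assert values[-1] == 0.0

    def test_out_of_range_generation_rejected(self):
        cfg = GAConfig(generations=10)
        with pytest.raises(ValueError):
            mutation_sigma(11, cfg)


class TestRunGA:
    def quad(self, x):
        return float(np.sum((x - 0.3) ** 2))

    def test_recovers_convex_quadratic(self):
        cfg = GAConfig(population_size=60, generations=25, seed=1)
        fit = run_ga(self.quad, cfg, n_params=1)
        assert abs(fit.best_params[0] - 0.3) < 1e-2

    def test_seeded_determinism(self):
        cfg = GAConfig(population_size=40, generations=15, seed=7)
        a = run_ga(self.quad, cfg, n_params=2)
        b = run_ga(self.quad, cfg, n_params=2)
        assert np.array_equal(a.best_params, b.best_params)
        assert a.J == b.J
        assert np.array_equal(a.trace, b.trace)

    def test_best_of_generation_non_increasing(self):
        cfg = GAConfig(population_size=40, generations=20, seed=3)
        fit = run_ga(self.quad, cfg, n_params=3)
        assert np.all(np.diff(fit.trace) <= 0)

    def test_elite_count_matches_printed_fraction(self):
        assert GAConfig(population_size=2000).elite_count == 100
        assert GAConfig(population_size=200).elite_count == 10

    def test_population_too_small_rejected(self):
        cfg = GAConfig(population_size=2, generations=5, elite_fraction=0.5)
        with pytest.raises(ValueError, match="population too small"):
            run_ga(self.quad, cfg, n_params=1)


class TestBuildEnsemble:
    def test_identifiable_problem_retains_all_starts(self):
        def quad(x):
            return float(np.sum((x - 0.3) ** 2))

        cfg = GAConfig(population_size=60, generations=25, seed=1)
        ens = build_ensemble(quad, cfg, n_starts=5, tau=0.2, n_params=1)
        assert len(ens) == 5
        assert np.all(np.abs(ens.sets[:, 0] - 0.3) < 1e-2)

    def test_retention_bound_holds(self):
        def rough(x):
            return float(np.sum(x**2) + 0.05 * np.sin(20 * x[0]) + 0.06)

        cfg = GAConfig(population_size=40, generations=15, seed=2)
        ens = build_ensemble(rough, cfg, n_starts=6, tau=0.2, n_params=2)
        assert ens.J_values.max() <= (1 + 0.2) * ens.J_values.min() + 1e-12

    def test_replication_preset_targets_77_sets(self):
        from pi3knet.calibration import REPLICATION_PRESET

        assert REPLICATION_PRESET["n_starts"] == 77
        assert REPLICATION_PRESET["population_size"] == 2000
        assert REPLICATION_PRESET["generations"] == 100

    def test_compensating_parameters_spread_but_product_agrees(self):
        # only the product k1*k2 is identifiable: J depends on x[0]+x[1]
        # (log-scale product); retained sets must agree on the sum while
        # individual coordinates spread
        def objective(x):
            return float((x[0] + x[1] - 0.5) ** 2)

        cfg = GAConfig(population_size=150, generations=30, seed=4)
        ens = build_ensemble(objective, cfg, n_starts=8, tau=0.2, n_params=2)
        sums = ens.sets.sum(axis=1)
        assert np.all(np.abs(sums - 0.5) < 0.05 * 1.0 + 0.05)
        spread = ens.sets[:, 0].max() - ens.sets[:, 0].min()
        assert spread > np.log10(2.0)  # individual values vary > 2-fold


class TestEnsembleStatistics:
    def test_identical_sets_have_zero_se(self):
        ens = ParameterEnsemble(["a"], np.zeros((4, 1)), np.ones(4),
                                np.arange(4))
        stats = ensemble_statistics(ens, lambda p: np.array([1.0, 2.0]))
        assert np.allclose(stats["se"], 0.0)

    def test_two_value_hand_computation(self):
        ens = ParameterEnsemble(["a"], np.array([[0.0], [1.0]]),
                                np.ones(2), np.arange(2))
        stats = ensemble_statistics(ens, lambda p: np.array([1.0 + 2 * p[0]]))
        # outputs 1 and 3: mean 2, SE = SD/sqrt(2) = sqrt(2)/sqrt(2) = 1
        assert stats["mean"][0] == pytest.approx(2.0)
        assert stats["se"][0] == pytest.approx(1.0)

    def test_se_equals_independent_recomputation(self):
        rng = np.random.default_rng(0)
        sets = rng.normal(size=(10, 3))
        ens = ParameterEnsemble([f"p{i}" for i in range(3)], sets,
                                np.ones(10), np.arange(10))

        def sim(p):
            return np.array([p @ np.array([1.0, -2.0, 0.5]), p.sum()])

        stats = ensemble_statistics(ens, sim)
        outputs = np.array([sim(p) for p in sets])
        mean = outputs.mean(axis=0)
        se = outputs.std(axis=0, ddof=1) / np.sqrt(10)
        assert np.allclose(stats["mean"], mean, atol=1e-12)
        assert np.allclose(stats["se"], se, atol=1e-12)

    def test_empty_ensemble_rejected(self):
        ens = ParameterEnsemble(["a"], np.zeros((1, 1)), np.ones(1),
                                np.arange(1))
        ens.sets = np.zeros((0, 1))
        with pytest.raises(ValueError, match="empty"):
            ensemble_statistics(ens, lambda p: p)
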