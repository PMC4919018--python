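"""Linear combination, logistic calibration, fitness and PSO fitting."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from viscomplexity import (
    LogisticParams,
    PsoConfig,
    evaluate,
    fitness_pcc,
    gen_study,
    lc_score,
    logistic_fit,
    preset,
    pso_optimize,
)
from viscomplexity.model import PRESETS, _pcc


def cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestLcScore:
    def test_basis_vector_selects_feature(self, rng):
        x = rng.uniform(0, 1, size=11)
        e8 = np.zeros(11)
        e8[7] = 1.0
        assert lc_score(x, e8) == pytest.approx(x[7])

    def test_preset_weights_on_unit_features(self):
        assert lc_score(np.ones(11), preset("LC_RS1")) == pytest.approx(1.1899)
        assert lc_score(np.zeros(11), preset("LC_RS1")) == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            lc_score(np.ones(10), preset("LC_RS1"))


class TestPresets:
    def test_printed_coefficients(self):
        assert preset("LC_RS1")[7] == 0.6167  # number-of-regions weight
        assert preset("LC_TXT1")[4] == -0.7150  # frequency-factor weight

    def test_all_within_search_space(self):
        for a in PRESETS.values():
            assert np.all(np.abs(a) <= 1.0)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset("LC_UNKNOWN")


class TestLogisticFit:
    def test_affine_target_reproduced(self, rng):
        x = rng.uniform(0, 1, 40)
        y = 2.5 * x - 0.7
        fit = logistic_fit(x, y)
        np.testing.assert_allclose(fit.predict(x), y, atol=1e-8)

    def test_known_curve_round_trip(self, rng):
        x = rng.uniform(0, 1, 60)
        truth = LogisticParams(2.0, 8.0, 0.5, 0.3, 1.0)
        y = truth.predict(x)
        fit = logistic_fit(x, y)
        rmse = np.sqrt(np.mean((fit.predict(x) - y) ** 2))
        assert rmse < 1e-6

    def test_constant_x_errors(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(10), np.arange(10.0))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            logistic_fit(np.arange(5.0), np.arange(5.0))


class TestFitnessPcc:
    def test_exact_monotone_relation_gives_one(self, rng):
        x = rng.uniform(0, 1, 50)
        y = LogisticParams(1.0, 6.0, 0.4, 0.0, 0.0).predict(x)
        assert fitness_pcc(x, y) == pytest.approx(1.0, abs=1e-9)

    def test_independent_scores_near_zero(self, rng):
        x = rng.uniform(0, 1, 1000)
        y = rng.normal(0, 1, 1000)
        assert abs(fitness_pcc(x, y)) < 0.1

    def test_invariant_to_positive_affine_transform(self, rng):
        x = rng.uniform(0, 1, 50)
        y = LogisticParams(1.0, 6.0, 0.4, 0.0, 0.0).predict(x)
        y = y + rng.normal(0, 0.05, 50)
        f0 = fitness_pcc(x, y)
        assert fitness_pcc(3.7 * x - 1.2, y) == pytest.approx(f0, abs=1e-6)
        assert fitness_pcc(0.01 * x + 5.0, y) == pytest.approx(f0, abs=1e-6)

    def test_matches_scipy_pearson_after_calibration(self, rng):
        x = rng.uniform(0, 1, 50)
        y = x**2 + rng.normal(0, 0.05, 50)
        fx = logistic_fit(x, y).predict(x)
        assert _pcc(fx, y) == pytest.approx(pearsonr(fx, y)[0], abs=1e-12)


class TestEvaluate:
    def test_self_evaluation_is_one(self, rng):
        x = rng.uniform(0, 1, 30)
        assert evaluate(x, x).pcc == pytest.approx(1.0, abs=1e-9)

    def test_report_carries_fitted_curve(self, rng):
        x = rng.uniform(0, 1, 30)
        y = 2 * x + rng.normal(0, 0.01, 30)
        rep = evaluate(x, y, name="demo")
        assert rep.name == "demo"
        assert rep.n == 30
        assert np.all(np.isfinite(rep.logistic.predict(x)))


class TestPso:
    def test_recovers_planted_direction(self):
        study = gen_study(11, n_images=50, noise_sd=0.05)
        cfg = PsoConfig(swarm=25, iterations=50, runs=2, seed=5)
        res = pso_optimize(study.X, study.y, cfg)
        assert cosine(res.weights_mean, study.weights) >= 0.9

    def test_single_feature_sign_recovered(self, rng):
        x = rng.uniform(0, 1, size=(40, 1))
        y = 1.0 / (1.0 + np.exp(-6 * (-0.8 * x[:, 0] + 0.4)))
        cfg = PsoConfig(swarm=10, iterations=25, runs=1, seed=0)
        res = pso_optimize(x, y, cfg)
        assert res.weights_mean[0] < 0

    def test_seeded_rerun_bit_identical(self):
        study = gen_study(2, n_images=30, noise_sd=0.05)
        cfg = PsoConfig(swarm=10, iterations=15, runs=2, seed=9)
        a = pso_optimize(study.X, study.y, cfg)
        b = pso_optimize(study.X, study.y, cfg)
        np.testing.assert_array_equal(a.run_weights, b.run_weights)
        np.testing.assert_array_equal(a.run_fitness, b.run_fitness)
        assert a.to_json() == b.to_json()

    def test_beats_trivial_baselines(self):
        study = gen_study(4, n_images=40, noise_sd=0.1)
        cfg = PsoConfig(swarm=20, iterations=40, runs=1, seed=1)
        res = pso_optimize(study.X, study.y, cfg)
        baselines = []
        for k in range(11):
            e = np.zeros(11)
            e[k] = 1.0
            baselines.append(fitness_pcc(study.X @ e, study.y))
        assert res.fitness_max >= max(baselines)

    def test_two_feature_grid_search_oracle(self, rng):
        """On K=2 the PSO must reach the best fitness of a 21 x 21 weight grid."""
        x = rng.uniform(0, 1, size=(40, 2))
        y = 1.0 / (1.0 + np.exp(-4 * (0.9 * x[:, 0] - 0.5 * x[:, 1])))
        y = y + rng.normal(0, 0.03, 40)
        grid = np.linspace(-1, 1, 21)
        best_grid = -np.inf
        for a1 in grid:
            for a2 in grid:
                if a1 == 0 and a2 == 0:
                    continue
                s = x @ np.array([a1, a2])
                if s.std() > 0:
                    best_grid = max(best_grid, fitness_pcc(s, y))
        cfg = PsoConfig(swarm=15, iterations=40, runs=1, seed=3)
        res = pso_optimize(x, y, cfg)
        assert res.fitness_max >= best_grid - 0.005

    def test_fitness_statistics_aggregate_runs(self):
        study = gen_study(6, n_images=30, noise_sd=0.1)
        cfg = PsoConfig(swarm=10, iterations=10, runs=3, seed=2)
        res = pso_optimize(study.X, study.y, cfg)
        assert res.fitness_min <= res.fitness_mean <= res.fitness_max
        assert res.fitness_sd >= 0
        np.testing.assert_allclose(
            res.weights_mean, res.run_weights.mean(axis=0)
        )
        assert np.all(np.abs(res.run_weights) <= 1.0)

    def test_weight_rescaling_leaves_fitness_unchanged(self):
        study = gen_study(8, n_images=40, noise_sd=0.05)
        a = study.weights
        f1 = fitness_pcc(study.X @ a, study.y)
        f2 = fitness_pcc(study.X @ (0.25 * a), study.y)
        assert f2 == pytest.approx(f1, abs=1e-6)
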