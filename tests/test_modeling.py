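import numpy as np
import pytest
from scipy.optimize import differential_evolution as scipy_de

from conftest import make_recovery_table
from soyspec.containers import SpectraTable, WavelengthGrid
from soyspec.modeling import (DEFAULT_RF_PARAMS, HyperparamSpace,
                              OptimizerConfig, cv_fitness, de_optimize,
                              predict, pso_optimize, train_classifier,
                              tune_rf)


def separable_table(n_per=10):
    X = np.concatenate([np.full((n_per, 1), 0.2), np.full((n_per, 1), 0.8)])
    X = X + np.linspace(0, 0.01, 2 * n_per)[:, None]
    return SpectraTable(X, WavelengthGrid(np.array([500.0])),
                        np.array(["a"] * n_per + ["b"] * n_per))


SPHERE_SPACE = HyperparamSpace(bounds={"x": (-5.0, 5.0, False),
                                       "y": (-5.0, 5.0, False)})


def neg_sphere(p):
    return -(p["x"] ** 2 + p["y"] ** 2)


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["RF", "KNN", "SVM"])
    def test_separable_data_trains_perfectly(self, kind):
        model = train_classifier(separable_table(), kind, seed=0)
        assert model.train_accuracy == 1.0

    def test_rf_importance_normalized(self, small_table):
        model = train_classifier(small_table, "RF", seed=0)
        assert model.band_importance.shape == (small_table.n_bands,)
        assert np.all(model.band_importance >= 0)
        assert model.band_importance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_class_rejected(self):
        t = SpectraTable(np.random.default_rng(0).random((5, 2)),
                         WavelengthGrid(np.array([500.0, 600.0])),
                         np.array(["a"] * 5))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(t, "RF")

    def test_memorizing_rf_recovers_training_labels(self, small_table):
        model = train_classifier(small_table, "RF", seed=0)
        np.testing.assert_array_equal(predict(model, small_table),
                                      small_table.labels)

    def test_predict_band_mismatch_names_counts(self, small_table):
        model = train_classifier(small_table, "RF", seed=0)
        with pytest.raises(ValueError, match="expects 4.*got 2"):
            predict(model, small_table.take_bands([0, 1]))

    def test_single_row_prediction(self, small_table):
        model = train_classifier(small_table, "RF", seed=0)
        assert predict(model, small_table.take_rows([0])).shape == (1,)

    def test_ground_truth_bands_dominate_importance(self):
        for seed in range(5):
            t, truth = make_recovery_table(seed)
            model = train_classifier(t, "RF", seed=seed)
            truth = sorted(truth)
            noise = [b for b in range(t.n_bands) if b not in truth][: len(truth)]
            assert model.band_importance[truth].sum() > \
                model.band_importance[noise].sum()


class TestCvFitness:
    def test_separable_reaches_one(self):
        assert cv_fitness(separable_table(), DEFAULT_RF_PARAMS, folds=2) == 1.0

    def test_permuted_labels_hit_chance_level(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.random((60, 5))
            t = SpectraTable(X, WavelengthGrid(400.0 + 10.0 * np.arange(5)),
                             rng.permutation(np.repeat(["a", "b", "c"], 20)))
            accs.append(cv_fitness(t, DEFAULT_RF_PARAMS, folds=3, seed=seed))
        assert np.mean(accs) == pytest.approx(1 / 3, abs=0.1)

    def test_deterministic(self, small_table):
        a = cv_fitness(small_table, DEFAULT_RF_PARAMS, folds=3, seed=5)
        b = cv_fitness(small_table, DEFAULT_RF_PARAMS, folds=3, seed=5)
        assert a == b

    def test_small_class_suggests_fewer_folds(self, small_table):
        with pytest.raises(ValueError, match="folds <= 3"):
            cv_fitness(small_table, DEFAULT_RF_PARAMS, folds=5)


class TestOptimizers:
    @pytest.mark.parametrize("optimize,pop", [(pso_optimize, 20), (de_optimize, 30)])
    def test_sphere_optimum_within_tolerance(self, optimize, pop):
        dists = []
        for seed in range(10):
            cfg = OptimizerConfig(population=pop, iterations=50, seed=seed)
            best, _, _ = optimize(SPHERE_SPACE, neg_sphere, cfg)
            dists.append(np.hypot(best["x"], best["y"]))
        assert np.median(dists) < 0.1

    def test_scipy_de_agrees_on_sphere(self):
        # independent reference optimizer on the same benchmark
        ref = scipy_de(lambda v: v[0] ** 2 + v[1] ** 2, [(-5, 5), (-5, 5)],
                       seed=0, maxiter=60, tol=1e-8)
        best, fit, _ = de_optimize(SPHERE_SPACE, neg_sphere,
                                   OptimizerConfig(population=30, iterations=60,
                                                   seed=0))
        assert abs(-fit - ref.fun) < 0.01

    @pytest.mark.parametrize("optimize", [pso_optimize, de_optimize])
    def test_history_monotone_nondecreasing(self, optimize):
        cfg = OptimizerConfig(population=8, iterations=15, seed=3)
        _, _, history = optimize(SPHERE_SPACE, neg_sphere, cfg)
        assert np.all(np.diff(history) >= 0)

    @pytest.mark.parametrize("optimize", [pso_optimize, de_optimize])
    def test_same_seed_same_result(self, optimize):
        cfg = OptimizerConfig(population=8, iterations=10, seed=11)
        a = optimize(SPHERE_SPACE, neg_sphere, cfg)
        b = optimize(SPHERE_SPACE, neg_sphere, cfg)
        assert a[0] == b[0] and a[1] == b[1]

    def test_de_small_population_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            de_optimize(SPHERE_SPACE, neg_sphere,
                        OptimizerConfig(population=3, iterations=2))

    def test_pso_pure_inertia_degenerate_dynamics(self):
        # one particle, no attraction terms: position follows constant-ish
        # velocity, so pbest history only improves when the drift helps
        cfg = OptimizerConfig(population=1, iterations=10, seed=0,
                              inertia=1.0, cognitive=0.0, social=0.0)
        _, _, history = pso_optimize(SPHERE_SPACE, neg_sphere, cfg)
        assert np.all(np.diff(history) >= 0)

    def test_x0_seeds_initial_member(self):
        # with zero iterations the evaluated population contains x0, so the
        # tuned fitness can never fall below the default's
        cfg = OptimizerConfig(population=5, iterations=1, seed=0)
        x0 = {"x": 0.0, "y": 0.0}
        for optimize in (pso_optimize, de_optimize):
            _, fit, _ = optimize(SPHERE_SPACE, neg_sphere, cfg, x0=x0)
            assert fit >= neg_sphere(x0)


class TestTuneRf:
    def test_tuned_never_below_default(self):
        t, _ = make_recovery_table(0, n_per=12, p=6, bands=(1, 4))
        cfg = OptimizerConfig(population=4, iterations=2, seed=0)
        space = HyperparamSpace()
        for algo in ("PSO", "DE"):
            params, best, history = tune_rf(t, algo, space=space, config=cfg,
                                            folds=3)
            default_fit = cv_fitness(t, DEFAULT_RF_PARAMS, folds=3, seed=0)
            assert best >= default_fit
            assert np.all(np.diff(history) >= 0)
            for name, (lo, hi, is_int) in space.bounds.items():
                assert lo <= params[name] <= hi
                if is_int:
                    assert params[name] == int(params[name])
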