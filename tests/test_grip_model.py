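"""Grip-force model: split, fitness, tuning, metrics, persistence."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from semgrip.bes import BESConfig
from semgrip.errors import ConfigError
from semgrip.grip_model import (
    Dataset,
    EvaluationReport,
    HyperparamSpace,
    PredictionSet,
    SplitConfig,
    evaluate,
    load_model,
    predict,
    rf_fitness,
    save_model,
    split,
    train_final,
    tune,
)


def toy_dataset(n=200, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"a": rng.uniform(0, 1, n), "b": rng.uniform(0, 1, n)})
    y = 100 * X["a"] + noise * rng.standard_normal(n)
    return Dataset(X=X, y=y)


def fraction_metrics(f_true, f_pred):
    """Arbitrary-precision evaluation of MAE / MSE / R^2."""
    ft = [Fraction(v).limit_denominator(10**12) for v in f_true]
    fp = [Fraction(v).limit_denominator(10**12) for v in f_pred]
    n = len(ft)
    mae = sum(abs(a - b) for a, b in zip(ft, fp)) / n
    mse = sum((a - b) ** 2 for a, b in zip(ft, fp)) / n
    mean = sum(ft) / n
    ss_tot = sum((a - mean) ** 2 for a in ft)
    r2 = 1 - sum((b - a) ** 2 for a, b in zip(ft, fp)) / ss_tot
    return float(mae), float(mse), float(r2)


class TestSplit:
    def test_70_30_sizes(self):
        tr, te = split(toy_dataset(200), SplitConfig(seed=0))
        assert len(tr) == 140 and len(te) == 60

    def test_partition_is_disjoint_and_complete(self):
        ds = toy_dataset(100)
        tr, te = split(ds, SplitConfig(seed=1))
        idx = sorted(list(tr.X.index) + list(te.X.index))
        assert idx == list(range(100))

    def test_same_seed_same_split(self):
        ds = toy_dataset(100)
        a = split(ds, SplitConfig(seed=7))[0].X.index
        b = split(ds, SplitConfig(seed=7))[0].X.index
        assert list(a) == list(b)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ConfigError):
            split(toy_dataset(8))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SplitConfig(train_fraction=1.0)


class TestMetrics:
    def test_perfect_predictions(self):
        p = PredictionSet(f_true=[40.0, 60.0, 80.0], f_pred=[40.0, 60.0, 80.0])
        r = evaluate(p)
        assert (r.mae, r.mse, r.r2) == (0.0, 0.0, 1.0)

    def test_constant_offset(self):
        truth = np.array([40.0, 60.0, 80.0, 100.0])
        r = evaluate(PredictionSet(f_true=truth, f_pred=truth + 3.0))
        assert r.mae == pytest.approx(3.0)
        assert r.mse == pytest.approx(9.0)

    def test_predicting_the_mean_gives_zero_r2(self):
        truth = np.array([40.0, 60.0, 80.0, 100.0])
        r = evaluate(PredictionSet(f_true=truth, f_pred=np.full(4, truth.mean())))
        assert r.r2 == pytest.approx(0.0)

    def test_constant_truth_undefined_r2(self):
        with pytest.raises(ConfigError):
            evaluate(PredictionSet(f_true=[50.0, 50.0], f_pred=[49.0, 51.0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_arbitrary_precision_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.uniform(40, 100, 50)
        pred = truth + rng.standard_normal(50)
        r = evaluate(PredictionSet(f_true=truth, f_pred=pred))
        mae, mse, r2 = fraction_metrics(truth, pred)
        assert r.mae == pytest.approx(mae, abs=1e-12)
        assert r.mse == pytest.approx(mse, abs=1e-12)
        assert r.r2 == pytest.approx(r2, abs=1e-12)


class TestFitness:
    def test_noiseless_relationship_reaches_near_zero_fitness(self):
        ds = toy_dataset(300, seed=2, noise=0.0)
        tr, te = split(ds, SplitConfig(seed=2))
        ev = rf_fitness((300, 1), tr, te, seed=2)
        # labels span [0, 100]; deep forest nails a noiseless 1-D rule
        assert ev.fitness < 1e-2 * np.var(ds.y.to_numpy())

    def test_fitness_is_sum_of_train_and_test_mse(self):
        ds = toy_dataset(100, seed=3, noise=5.0)
        tr, te = split(ds, SplitConfig(seed=3))
        ev = rf_fitness((50, 2), tr, te, seed=3)
        assert ev.fitness == pytest.approx(ev.mse_train + ev.mse_test)
        assert ev.fitness >= max(ev.mse_train, ev.mse_test) >= 0

    def test_deterministic_given_params_and_seed(self):
        ds = toy_dataset(100, seed=4, noise=5.0)
        tr, te = split(ds, SplitConfig(seed=4))
        a = rf_fitness((80, 3), tr, te, seed=4)
        b = rf_fitness((80, 3), tr, te, seed=4)
        assert a.fitness == b.fitness
        assert np.array_equal(a.t_sim2, b.t_sim2)

    def test_params_rounded_half_up_and_clipped(self):
        space = HyperparamSpace(n_estimators=(10, 500), min_samples_leaf=(1, 20))
        assert space.round_point((99.5, 2.5)) == (100, 3)
        assert space.round_point((3.0, 25.0)) == (10, 20)


class TestTune:
    def test_returned_params_in_space_and_history_non_increasing(self):
        ds = toy_dataset(120, seed=5, noise=5.0)
        tr, te = split(ds, SplitConfig(seed=5))
        space = HyperparamSpace(n_estimators=(10, 100))
        bes_cfg = BESConfig(pop_size=4, max_iter=3, lo=(10, 1), hi=(100, 20), seed=5)
        result = tune(tr, te, space, bes_cfg, rf_seed=5)
        assert 10 <= result.n_estimators <= 100
        assert 1 <= result.min_samples_leaf <= 20
        assert all(a >= b for a, b in zip(result.history, result.history[1:]))
        assert result.best_fitness == min(result.evaluations.values())

    def test_cross_validated_fitness_option_runs(self):
        ds = toy_dataset(120, seed=6, noise=5.0)
        tr, te = split(ds, SplitConfig(seed=6))
        space = HyperparamSpace(n_estimators=(10, 50))
        bes_cfg = BESConfig(pop_size=3, max_iter=2, lo=(10, 1), hi=(50, 20), seed=6)
        result = tune(tr, te, space, bes_cfg, rf_seed=6, cv_folds=3)
        assert result.best_fitness >= 0


class TestFinalModel:
    def test_noiseless_monotone_data_r2_above_095(self):
        ds = toy_dataset(300, seed=7, noise=0.0)
        tr, te = split(ds, SplitConfig(seed=7))
        model = train_final(tr, 200, 1, seed=7)
        report = evaluate(predict(model, te))
        assert report.r2 >= 0.95

    def test_saved_model_reloads_with_identical_predictions(self, tmp_path):
        ds = toy_dataset(100, seed=8, noise=5.0)
        tr, te = split(ds, SplitConfig(seed=8))
        model = train_final(tr, 50, 2, seed=8)
        path = tmp_path / "model.joblib"
        save_model(model, path, meta={"n_estimators": 50})
        loaded, meta = load_model(path)
        assert meta["n_estimators"] == 50
        assert np.array_equal(predict(model, te).f_pred, predict(loaded, te).f_pred)

    def test_predictions_are_finite(self):
        ds = toy_dataset(100, seed=9, noise=5.0)
        tr, te = split(ds, SplitConfig(seed=9))
        preds = predict(train_final(tr, 30, 1, seed=9), te)
        assert np.all(np.isfinite(preds.f_pred))


class TestDataset:
    def test_rejects_non_finite_features(self):
        with pytest.raises(ConfigError):
            Dataset(X=pd.DataFrame({"a": [1.0, np.nan]}), y=[1.0, 2.0])

    def test_from_feature_table_strips_label_columns(self):
        table = pd.DataFrame({"ch1_rms": [1.0, 2.0], "percent_mvc": [40.0, 60.0],
                              "window_start": [0, 56]})
        ds = Dataset.from_feature_table(table)
        assert list(ds.X.columns) == ["ch1_rms"]
        assert list(ds.y) == [40.0, 60.0]
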