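"""Surrogate networks: partitioning, rescaling, training and importance."""

import numpy as np
import pandas as pd
import pytest

from gwhazard.metrics import r_squared, sose
from gwhazard.surrogate import (
    MLPConfig,
    Partition,
    RBFConfig,
    SurrogateModel,
    _fit_adjusted_normalizer,
    _fit_standardizer,
    _target_forward,
    _target_inverse,
    importance,
    partition,
    train_mlp,
    train_rbf,
)


class TestPartition:
    @pytest.mark.parametrize("n,frac,n_train", [
        (40, 0.75, 30), (40, 0.85, 34), (40, 0.80, 32), (40, 0.70, 28),
    ])
    def test_observed_counts(self, n, frac, n_train):
        p = partition(list(range(n)), frac, seed=1)
        assert len(p.train_ids) == n_train
        assert len(p.test_ids) == n - n_train
        assert set(p.train_ids) | set(p.test_ids) == set(range(n))
        assert not set(p.train_ids) & set(p.test_ids)

    def test_reproducible_from_seed(self):
        assert partition(list(range(40)), 0.75, 9) == partition(list(range(40)), 0.75, 9)
        assert partition(list(range(40)), 0.75, 9) != partition(list(range(40)), 0.75, 10)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            partition(list(range(10)), 0.99, 1)
        with pytest.raises(ValueError):
            partition(list(range(3)), 0.5, 1)


class TestRescaling:
    def test_standardizer_round_trip(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(3, 2, (20, 2))
        sc = _fit_standardizer(Y)
        assert np.max(np.abs(_target_inverse(_target_forward(Y, sc), sc) - Y)) < 1e-10

    def test_adjusted_normalizer_round_trip_and_range(self):
        rng = np.random.default_rng(1)
        Y = rng.uniform(-5, 7, (30, 1))
        sc = _fit_adjusted_normalizer(Y, 0.02)
        Ys = _target_forward(Y, sc)
        assert Ys.min() >= -1.0 and Ys.max() <= 1.0
        # training extremes land strictly inside (-1, 1) by the correction
        assert Ys.min() == pytest.approx(-1 / 1.04, rel=1e-9)
        assert Ys.max() == pytest.approx(1 / 1.04, rel=1e-9)
        assert np.max(np.abs(_target_inverse(Ys, sc) - Y)) < 1e-10


def _toy_data(n=60, d=3, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(0, 1, (n, d)), columns=[f"x{i}" for i in range(d)])
    return X


class TestRBF:
    def test_interpolation_regime_train_sose_vanishes(self):
        rng = np.random.default_rng(2)
        X = _toy_data(8, 2, seed=2)
        Y = pd.DataFrame({"y": rng.normal(size=8)})
        part = Partition(tuple(X.index[:5]), tuple(X.index[5:]), 5 / 8, 0)
        m = train_rbf(X, Y, part, RBFConfig(hidden_units=5), seed=1)
        tr = list(part.train_ids)
        assert sose(Y.loc[tr].to_numpy(), m.predict(X.loc[tr]).to_numpy()) < 1e-6

    def test_constant_target_reproduced(self):
        X = _toy_data(20, 2, seed=3)
        Y = pd.DataFrame({"y": np.full(20, 4.25)})  # exactly representable
        part = partition(list(X.index), 0.75, 0)
        m = train_rbf(X, Y, part, RBFConfig(hidden_units=3), seed=1)
        assert np.allclose(m.predict(X).to_numpy(), 4.25, atol=1e-8)
        # R^2 on a constant target is undefined and reported as NaN
        assert np.isnan(r_squared(Y["y"], m.predict(X)["y"]))

    def test_hidden_activations_sum_to_one_in_unit_interval(self):
        X = _toy_data(30, 4, seed=4)
        Y = pd.DataFrame({"y": X.sum(axis=1)})
        part = partition(list(X.index), 0.75, 2)
        m = train_rbf(X, Y, part, RBFConfig(), seed=3)
        u = m.hidden_activations(X.to_numpy())
        assert np.allclose(u.sum(axis=1), 1.0)
        assert (u > 0).all() and (u < 1).all()

    def test_smooth_target_recovered(self):
        X = _toy_data(200, 6, seed=5)
        Y = pd.DataFrame({"y": X.to_numpy() @ np.array([1, 0.5, 0.2, 0.1, 2, 1.5])})
        part = partition(list(X.index), 0.75, 6)
        m = train_rbf(X, Y, part, RBFConfig(), seed=7)
        te = list(part.test_ids)
        assert r_squared(Y.loc[te, "y"], m.predict(X.loc[te])["y"]) >= 0.9

    def test_determinism(self):
        X = _toy_data(40, 3, seed=8)
        Y = pd.DataFrame({"y": X["x0"] ** 2})
        part = partition(list(X.index), 0.75, 1)
        m1 = train_rbf(X, Y, part, RBFConfig(), seed=5)
        m2 = train_rbf(X, Y, part, RBFConfig(), seed=5)
        assert np.array_equal(m1.predict(X).to_numpy(), m2.predict(X).to_numpy())


class TestMLP:
    def test_linear_target_high_r2(self):
        X = _toy_data(200, 4, seed=9)
        Y = pd.DataFrame({"y": X.sum(axis=1)})
        part = partition(list(X.index), 0.75, 3)
        m = train_mlp(X, Y, part, MLPConfig(), seed=11)
        te = list(part.test_ids)
        assert r_squared(Y.loc[te, "y"], m.predict(X.loc[te])["y"]) >= 0.99

    def test_zero_epoch_predictions_reproducible(self):
        X = _toy_data(30, 3, seed=10)
        Y = pd.DataFrame({"y": X["x1"]})
        part = partition(list(X.index), 0.75, 4)
        cfg = MLPConfig(hidden_units=5, max_epochs=0)
        p1 = train_mlp(X, Y, part, cfg, seed=2).predict(X)
        p2 = train_mlp(X, Y, part, cfg, seed=2).predict(X)
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())
        assert train_mlp(X, Y, part, cfg, seed=2).metadata["epochs"] == 0

    def test_nonconvergence_flagged_not_fatal(self):
        X = _toy_data(40, 3, seed=12)
        Y = pd.DataFrame({"y": np.sin(8 * X["x0"]) + X["x1"]})
        part = partition(list(X.index), 0.75, 5)
        m = train_mlp(X, Y, part, MLPConfig(hidden_units=4, max_epochs=3), seed=6)
        assert m.metadata["converged"] is False
        assert np.isfinite(m.predict(X).to_numpy()).all()


class TestPredict:
    def test_column_permutation_with_name_matching(self):
        X = _toy_data(50, 3, seed=13)
        Y = pd.DataFrame({"y": X["x0"] + 2 * X["x2"]})
        part = partition(list(X.index), 0.75, 7)
        m = train_rbf(X, Y, part, RBFConfig(hidden_units=6), seed=8)
        shuffled = X[["x2", "x0", "x1"]]
        assert np.array_equal(m.predict(X).to_numpy(), m.predict(shuffled).to_numpy())

    def test_missing_column_rejected(self):
        X = _toy_data(30, 2, seed=14)
        Y = pd.DataFrame({"y": X["x0"]})
        part = partition(list(X.index), 0.75, 8)
        m = train_rbf(X, Y, part, RBFConfig(hidden_units=3), seed=9)
        with pytest.raises(ValueError, match="missing input"):
            m.predict(X[["x0"]])


class TestSerialization:
    @pytest.mark.parametrize("family", ["rbf", "mlp"])
    def test_bit_identical_reload(self, tmp_path, family):
        X = _toy_data(40, 3, seed=15)
        Y = pd.DataFrame({"y": X["x0"] * X["x1"]})
        part = partition(list(X.index), 0.75, 9)
        if family == "rbf":
            m = train_rbf(X, Y, part, RBFConfig(hidden_units=4), seed=10)
        else:
            m = train_mlp(X, Y, part, MLPConfig(hidden_units=4, max_epochs=50), seed=10)
        path = tmp_path / "model.json"
        m.save(path)
        m2 = SurrogateModel.load(path)
        assert np.array_equal(m.predict(X).to_numpy(), m2.predict(X).to_numpy())
        assert m2.hidden_units == m.hidden_units
        assert m2.to_json() == m.to_json()


class TestImportance:
    def test_scores_sum_to_one_and_single_driver_dominates(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.uniform(0, 1, (500, 4)),
                         columns=["Cr", "Ni", "As", "Mo"])
        Y = pd.DataFrame({"y": 3 * X["Cr"] ** 2 + 1})
        part = partition(list(X.index), 0.75, 10)
        m = train_rbf(X, Y, part, RBFConfig(), seed=11)
        imp = importance(m, X, Y, n_repeats=5, seed=12)
        assert imp.sum() == pytest.approx(1.0)
        assert imp["Cr"] > 0.8

    def test_ignored_feature_scores_zero(self):
        rng = np.random.default_rng(17)
        X = pd.DataFrame(rng.uniform(0, 1, (100, 2)), columns=["a", "b"])
        Y = pd.DataFrame({"y": X["a"]})
        # hand-built linear MLP-like model that ignores column b entirely
        m = train_rbf(X, Y, partition(list(X.index), 0.75, 11),
                      RBFConfig(hidden_units=8), seed=13)
        imp = importance(m, X, Y, n_repeats=5, seed=14)
        assert imp["b"] < 0.05

    def test_constant_column_warns_and_scores_zero(self):
        rng = np.random.default_rng(18)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 60), "c": np.ones(60)})
        Y = pd.DataFrame({"y": X["a"]})
        m = train_rbf(X, Y, partition(list(X.index), 0.75, 12),
                      RBFConfig(hidden_units=5), seed=15)
        with pytest.warns(UserWarning, match="constant"):
            imp = importance(m, X, Y, n_repeats=3, seed=16)
        assert imp["c"] == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame(rng.uniform(0, 1, (80, 3)), columns=list("abc"))
        Y = pd.DataFrame({"y": X["a"] + X["b"]})
        m = train_rbf(X, Y, partition(list(X.index), 0.75, 13),
                      RBFConfig(hidden_units=6), seed=17)
        i1 = importance(m, X, Y, n_repeats=4, seed=18)
        i2 = importance(m, X, Y, n_repeats=4, seed=18)
        pd.testing.assert_series_equal(i1, i2)
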