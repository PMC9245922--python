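"""Ensemble training, Chebyshev reject mechanics, and RFE."""

import math

import numpy as np
import pytest

from varitol.core import BENIGN, PATHOGENIC
from varitol.features import FeatureVector
from varitol.model import (
    UV,
    EnsembleModel,
    PredictionResult,
    chebyshev_k,
    load_model,
    predict_batch,
    predict_with_reject,
    rfe_select,
    save_model,
    train_ensemble,
    two_mode_predict,
    _decide,
)


def separable_data(n=200, d=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y, 2.0, -2.0)  # wide margin
    return X, y


class TestChebyshev:
    def test_k_at_95(self):
        assert chebyshev_k(0.95) == pytest.approx(math.sqrt(20), abs=1e-12)

    def test_k_at_75(self):
        assert chebyshev_k(0.75) == pytest.approx(2.0)

    def test_monotone_in_confidence(self):
        grid = [chebyshev_k(c) for c in np.linspace(0.05, 0.99, 25)]
        assert all(a < b for a, b in zip(grid, grid[1:]))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            chebyshev_k(bad)


class TestDecisionRule:
    k = math.sqrt(20)

    @pytest.mark.parametrize(
        "mu, sigma, expected",
        [
            (0.9, 0.0, PATHOGENIC),       # degenerate sigma, clear call
            (0.1, 0.0, BENIGN),
            (0.6, 0.2, UV),               # interval [-0.29, 1.49] spans 0.5
            (0.5, 0.0, UV),               # exact boundary -> UV
            (0.9, 0.05, PATHOGENIC),      # interval [0.676, 1.124]
            (0.1, 0.05, BENIGN),
        ],
    )
    def test_interval_rule(self, mu, sigma, expected):
        assert _decide(mu, sigma, self.k) == expected

    def test_boundary_inclusive(self):
        # lower bound exactly 0.5: ties go to UV
        mu, sigma = 0.6, 0.1 / self.k
        assert mu - self.k * sigma == pytest.approx(0.5)
        assert _decide(mu, sigma, self.k) == UV


class TestTrainEnsemble:
    def test_determinism(self):
        X, y = separable_data()
        a = train_ensemble(X, y, B=5, seed=3)
        b = train_ensemble(X, y, B=5, seed=3)
        assert np.array_equal(a.member_probabilities(X), b.member_probabilities(X))

    def test_separable_training_accuracy(self):
        X, y = separable_data()
        model = train_ensemble(X, y, B=5, seed=0)
        mu = model.member_probabilities(X).mean(axis=0)
        assert ((mu > 0.5) == y).mean() >= 0.99

    def test_b_must_be_at_least_two(self):
        X, y = separable_data(n=50)
        with pytest.raises(ValueError):
            train_ensemble(X, y, B=1, seed=0)

    def test_single_class_rejected(self):
        X, _ = separable_data(n=50)
        with pytest.raises(ValueError):
            train_ensemble(X, np.zeros(50, dtype=int), B=3, seed=0)

    def test_sigma_shrinks_with_ensemble_size(self):
        X, y = separable_data(n=150, seed=2)
        X_test, _ = separable_data(n=60, seed=9)
        small = train_ensemble(X, y, B=10, seed=0)
        large = train_ensemble(X, y, B=100, seed=0)
        sig_small = small.member_probabilities(X_test).std(axis=0).mean()
        sig_large = large.member_probabilities(X_test).std(axis=0).mean()
        # more members do not reduce member spread, but the estimate of mu
        # stabilizes; here we check spread does not blow up and stays close
        assert sig_large <= sig_small * 1.25

    def test_coverage_monotone_in_confidence(self):
        X, y = separable_data(n=150, seed=4)
        X_test, _ = separable_data(n=100, seed=5)
        model = train_ensemble(X, y, B=10, seed=0)
        coverages = []
        for conf in (0.5, 0.75, 0.9, 0.95, 0.99):
            preds = predict_batch(model, X_test, confidence=conf)
            coverages.append(sum(p.decision != UV for p in preds))
        assert all(a >= b for a, b in zip(coverages, coverages[1:]))


class TestPredict:
    def test_feature_vector_name_check(self):
        X, y = separable_data(n=60)
        model = train_ensemble(X, y, B=3, seed=0, feature_names=list("abcde"))
        fv = FeatureVector(names=list("vwxyz"), values=np.zeros(5),
                           mask=np.ones(5, bool))
        with pytest.raises(ValueError, match="feature names"):
            predict_with_reject(model, fv)

    def test_two_mode_routing(self):
        X, y = separable_data(n=80, d=3)
        with_go = train_ensemble(X, y, B=3, seed=0,
                                 feature_names=["f0", "f1", "go:lr"])
        without_go = train_ensemble(X[:, :2], y, B=3, seed=0,
                                    feature_names=["f0", "f1"])
        models = {"with_go": with_go, "without_go": without_go}
        names = ["f0", "f1", "go:lr"]
        annotated = FeatureVector(names=names, values=X[0].copy(),
                                  mask=np.array([True, True, True]))
        bare = FeatureVector(names=names, values=X[0].copy(),
                             mask=np.array([True, True, False]))
        assert two_mode_predict(models, annotated).mode == "with_go"
        assert two_mode_predict(models, bare).mode == "without_go"

    def test_two_mode_requires_a_model(self):
        fv = FeatureVector(names=["go:lr"], values=np.zeros(1),
                           mask=np.ones(1, bool))
        with pytest.raises(ValueError):
            two_mode_predict({}, fv)


class TestRfe:
    def test_planted_signal_survives_to_one_feature(self):
        rng = np.random.default_rng(0)
        n = 300
        X = rng.normal(size=(n, 10))
        y = (X[:, 7] > 0).astype(int)  # feature 7 perfectly predictive
        names = [f"f{i}" for i in range(10)]
        selection = rfe_select(X, y, names, target_counts=[1], seed=0)
        assert selection[1] == ["f7"]

    def test_snapshots_nested_and_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 40))
        y = ((X[:, 0] + 0.5 * X[:, 1]) > 0).astype(int)
        names = [f"f{i}" for i in range(40)]
        sel_a = rfe_select(X, y, names, target_counts=[20, 10, 5], seed=2)
        sel_b = rfe_select(X, y, names, target_counts=[20, 10, 5], seed=2)
        assert sel_a == sel_b
        assert set(sel_a[5]) <= set(sel_a[10]) <= set(sel_a[20])

    def test_target_must_be_below_feature_count(self):
        X = np.zeros((10, 5))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            rfe_select(X, y, list("abcde"), target_counts=[5], seed=0)


class TestSerialization:
    def test_round_trip_bit_identical_predictions(self, tmp_path):
        X, y = separable_data(n=80)
        model = train_ensemble(X, y, B=3, seed=1)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert np.array_equal(
            model.member_probabilities(X), loaded.member_probabilities(X)
        )
        assert loaded.feature_names == model.feature_names

    def test_checksum_detects_tampering(self, tmp_path):
        import joblib

        X, y = separable_data(n=80)
        model = train_ensemble(X, y, B=3, seed=1)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        payload = joblib.load(path)
        payload["feature_names"] = ["tampered"] * len(model.feature_names)
        joblib.dump(payload, path)
        with pytest.raises(ValueError, match="checksum"):
            load_model(path)
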