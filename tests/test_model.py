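"""Stability selection, logistic fitting, ROC/threshold metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_auc_score

import sigbridge as sb


def _design(seed=0, n=120, n_noise=20, informative=True):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    rng.shuffle(y)
    X = pd.DataFrame(rng.normal(size=(n, n_noise)),
                     columns=[f"noise{i}" for i in range(n_noise)],
                     index=[f"s{i}" for i in range(n)])
    if informative:
        X.insert(0, "signal", y + rng.normal(0, 0.1, n))
    return X, pd.Series(y, index=X.index)


class TestCvLasso:
    def test_informative_feature_dominates(self):
        X, y = _design(seed=1)
        freqs, info = sb.cv_lasso_frequencies(X, y, repeats=20, folds=10,
                                              seed=3, n_lambda=40)
        assert freqs["signal"] >= 19
        assert freqs.drop("signal").median() <= 2

    def test_pure_noise_rarely_selected(self):
        # n large enough that no single noise feature is spuriously
        # informative in-sample (a fixed lucky draw would legitimately be
        # selected stably across fold splits)
        X, y = _design(seed=2, n=300, informative=False)
        freqs, _ = sb.cv_lasso_frequencies(X, y, repeats=20, folds=5,
                                           seed=5, n_lambda=40)
        assert (freqs <= 0.6 * 20).all()

    def test_deterministic_given_seed(self):
        X, y = _design(seed=3, n=60, n_noise=5)
        a, _ = sb.cv_lasso_frequencies(X, y, repeats=2, seed=11, n_lambda=20)
        b, _ = sb.cv_lasso_frequencies(X, y, repeats=2, seed=11, n_lambda=20)
        pd.testing.assert_series_equal(a, b)

    def test_single_class_errors(self):
        X, _ = _design(n=20)
        with pytest.raises(ValueError, match="both classes"):
            sb.cv_lasso_frequencies(X, np.ones(20), repeats=1)


class TestSelectFeatures:
    def test_majority_rule(self):
        freqs = pd.Series({"A": 990, "B": 870, "C": 120})
        assert sb.select_features(freqs, 1000) == ["A", "B"]

    def test_fallback_top_two(self):
        freqs = pd.Series({"A": 400, "B": 300, "C": 120})
        with pytest.warns(UserWarning, match="falling back"):
            assert sb.select_features(freqs, 1000) == ["A", "B"]

    def test_tie_at_cutoff_inclusive(self):
        freqs = pd.Series({"A": 500, "B": 500, "C": 100})
        assert sb.select_features(freqs, 1000) == ["A", "B"]


class TestFitLogistic:
    def test_perfect_separation_falls_back_rank_perfect(self):
        X = pd.DataFrame({"f": np.r_[np.zeros(10), np.ones(10)]},
                         index=[f"s{i}" for i in range(20)])
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        model = sb.fit_logistic(X, y)
        assert model.separation_fallback
        assert model.train_auc == pytest.approx(1.0)

    def test_independent_labels_auc_near_half(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.normal(size=400)})
        y = rng.integers(0, 2, 400)
        model = sb.fit_logistic(X, y)
        assert abs(model.coef["f"]) < 0.3
        assert abs(model.train_auc - 0.5) < 0.08

    def test_intercept_only_predicts_base_rate(self):
        X = pd.DataFrame(index=[f"s{i}" for i in range(10)])
        y = np.array([1] * 6 + [0] * 4)
        model = sb.fit_logistic(X, y, selected=[])
        probs = model.predict_proba(X)
        assert np.allclose(probs, 0.6)


class TestRocAuc:
    @pytest.mark.parametrize("pos,neg,expected", [
        ([0.9, 0.8], [0.7, 0.1], 1.0),
        ([0.9, 0.3], [0.5, 0.1], 0.75),   # 3 of 4 ordered pairs correct
        ([0.4, 0.4], [0.4, 0.4], 0.5),    # ties contribute one half
    ])
    def test_rank_formula(self, pos, neg, expected):
        probs = np.array(pos + neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        auc, _ = sb.roc_auc(probs, labels)
        assert auc == pytest.approx(expected)

    def test_matches_trapezoid_and_sklearn(self):
        rng = np.random.default_rng(9)
        probs = rng.random(200)
        labels = rng.integers(0, 2, 200)
        auc, roc = sb.roc_auc(probs, labels)
        assert auc == pytest.approx(roc_auc_score(labels, probs))
        assert auc == pytest.approx(sk_auc(roc["fpr"], roc["tpr"]))

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            sb.roc_auc([0.1, 0.9], [1, 1])


class TestClassifyEvaluate:
    def test_perfect_confusion(self):
        m = sb.classify_evaluate([0.9, 0.1], [1, 0], 0.5)
        assert (m.tp, m.tn, m.fp, m.fn) == (1, 1, 0, 0)
        assert m.mcc == 1.0 and m.sensitivity == 1.0 and m.specificity == 1.0

    def test_hand_evaluated_mcc(self):
        # TP=3, TN=4, FP=1, FN=2 -> MCC = 10 / sqrt(600)
        probs = [0.9] * 3 + [0.1] * 2 + [0.9] * 1 + [0.1] * 4
        labels = [1] * 5 + [0] * 5
        m = sb.classify_evaluate(probs, labels, 0.5)
        assert (m.tp, m.fn, m.fp, m.tn) == (3, 2, 1, 4)
        assert m.mcc == pytest.approx(10 / np.sqrt(600))

    def test_nothing_called_responder_sensitivity_missing(self):
        m = sb.classify_evaluate([0.1, 0.2, 0.3], [1, 1, 0], 0.5)
        assert np.isnan(m.sensitivity)   # missing, not zero
        assert m.specificity == 1.0
        assert m.mcc == 0.0              # zero-factor convention

    def test_boundary_counts_as_responder(self):
        m = sb.classify_evaluate([0.5], [1], 0.5)
        assert m.tp == 1


class TestThresholdsAndPrediction:
    def test_youden_threshold_attained_and_monotone(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(50), np.zeros(50)].astype(int)
        probs = np.clip(rng.normal(0.6, 0.2, 100) * y
                        + rng.normal(0.4, 0.2, 100) * (1 - y), 0, 1)
        X = pd.DataFrame({"f": probs})
        model = sb.fit_logistic(X, y)
        t = model.threshold_youden
        assert 0 <= t <= 1
        model_probs = model.predict_proba(X).to_numpy()
        # a stricter threshold never increases sensitivity
        sens = [sb.classify_evaluate(model_probs, y, thr).sensitivity
                for thr in (0.2, 0.5, 0.8)]
        sens = [s for s in sens if not np.isnan(s)]
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_target_equals_training_reproduces_metrics(self):
        X, y = _design(seed=7, n=80, n_noise=3)
        model = sb.fit_logistic(X, y, selected=["signal"],
                                train_patients=[f"p{i}" for i in range(80)])
        res = sb.cross_platform_predict(model, X, y)
        probs = model.predict_proba(X)
        direct = sb.classify_evaluate(probs.to_numpy(), y, 0.5)
        assert res["default"].as_dict() == direct.as_dict()

    def test_patient_leakage_guard(self):
        X, y = _design(seed=8, n=40, n_noise=3)
        model = sb.fit_logistic(X, y, selected=["signal"],
                                train_patients=["p1", "p2"])
        with pytest.raises(ValueError, match="leakage"):
            sb.cross_platform_predict(model, X, y,
                                      target_patients=pd.Series(["p2", "p9"]))

    def test_missing_signature_listed(self):
        X, y = _design(seed=9, n=40, n_noise=3)
        model = sb.fit_logistic(X, y, selected=["signal"])
        with pytest.raises(KeyError, match="signal"):
            model.predict_proba(X.drop(columns=["signal"]))
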