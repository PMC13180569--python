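"""Classifier benchmark: metric identities, training, validation levels."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from bametrics.bench import (
    MODEL_KINDS,
    _confusion_metrics,
    metrics_at_best_threshold,
    metrics_at_threshold,
    metrics_from_rates,
    summarize_logistic,
    three_level_validation,
    train_model,
)


def make_separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = pd.DataFrame({
        "f1": y * 10.0 + rng.normal(0, 0.1, n),
        "f2": rng.normal(0, 1, n),
    })
    return X, y


class TestMetricArithmetic:
    def test_seronegative_marker_operating_point(self):
        """sens 1.0 / spec 0.9 with 32 vs 50 -> acc .939, F1 .928, J .900."""
        m = metrics_from_rates(1.0, 0.9, n_positive=32, n_negative=50)
        assert m["accuracy"] == pytest.approx(0.939, abs=5e-4)
        assert m["f1"] == pytest.approx(0.928, abs=5e-4)
        assert m["balanced_accuracy"] == pytest.approx(0.950, abs=5e-4)
        assert m["youden"] == pytest.approx(0.900, abs=5e-4)

    def test_stable_features_model_operating_point(self):
        """sens 0.9 / spec 0.826 -> balanced accuracy 0.863, J 0.726."""
        m = metrics_from_rates(0.9, 0.826)
        assert m["balanced_accuracy"] == pytest.approx(0.863, abs=5e-4)
        assert m["youden"] == pytest.approx(0.726, abs=5e-4)

    def test_perfect_classifier_panel(self):
        p = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        m = metrics_at_best_threshold(p, y)
        assert (m.auc, m.accuracy, m.sensitivity, m.specificity, m.f1) == (1, 1, 1, 1, 1)
        assert m.youden == 1.0

    def test_identities_hold_on_all_small_confusion_matrices(self):
        """Brute-force oracle over integer 2x2 tables with n <= 30."""
        for tp, fn, fp, tn in product(range(8), repeat=4):
            n = tp + fn + fp + tn
            if n == 0 or n > 30 or tp + fn == 0 or fp + tn == 0:
                continue
            m = _confusion_metrics(tp, fn, fp, tn)
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
            assert m["balanced_accuracy"] == pytest.approx((sens + spec) / 2, abs=1e-12)
            assert m["youden"] == pytest.approx(sens + spec - 1, abs=1e-12)
            assert m["accuracy"] == pytest.approx((tp + tn) / n, abs=1e-12)
            if 2 * tp + fp + fn:
                assert m["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn), abs=1e-12)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            metrics_at_threshold(np.array([0.2, 0.8]), np.array([1, 1]), 0.5)


class TestTrainModel:
    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_separable_data_perfect_holdout_auc(self, kind):
        X, y = make_separable(seed=1)
        model = train_model(kind, X, y, ["f1", "f2"], positive_label=1,
                            inner_k=3, seed=0)
        p = model.predict_proba(X)
        m = metrics_at_best_threshold(p, y)
        assert m.auc == 1.0

    def test_determinism_of_selected_hyperparameters(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=["a", "b", "c"])
        y = (X["a"] + rng.normal(0, 1, 80) > 0).astype(int).to_numpy()
        m1 = train_model("random_forest", X, y, ["a", "b", "c"], 1, inner_k=3, seed=5)
        m2 = train_model("random_forest", X, y, ["a", "b", "c"], 1, inner_k=3, seed=5)
        assert m1.hyperparameters == m2.hyperparameters

    def test_unknown_kind_rejected(self):
        X, y = make_separable()
        with pytest.raises(ValueError, match="kind"):
            train_model("deep_net", X, y, ["f1"], 1)


class TestThreeLevelValidation:
    def test_separable_data_saturates_all_levels(self):
        X, y = make_separable(n=80, seed=2)
        Xte, yte = make_separable(n=40, seed=3)
        res = three_level_validation(
            {"logistic": ["f1", "f2"]}, X, y, Xte, yte, positive_label=1,
            reps=2, k=5, boot_B=50, seed=0)
        s = res.summaries["logistic"]
        assert s.cv_mean == 1.0 and s.cv_sd == 0.0
        assert s.bootstrap_ci95 == (1.0, 1.0)
        assert s.holdout_best.auc == 1.0

    def test_fold_and_bootstrap_matrices_shapes(self):
        X, y = make_separable(n=60, seed=4)
        Xte, yte = make_separable(n=30, seed=5)
        res = three_level_validation(
            {"logistic": ["f1", "f2"], "random_forest": ["f1", "f2"]},
            X, y, Xte, yte, positive_label=1, reps=2, k=3, boot_B=40, seed=0)
        assert res.fold_auc_matrix.shape == (2, 6)
        assert res.bootstrap_matrix.shape == (2, 40)
        assert res.summaries["logistic"].cv_coefficient == pytest.approx(
            res.summaries["logistic"].cv_sd / res.summaries["logistic"].cv_mean)

    def test_null_scores_cv_auc_near_half(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 2)), columns=["f1", "f2"])
        y = rng.integers(0, 2, size=120)
        Xte = pd.DataFrame(rng.normal(size=(40, 2)), columns=["f1", "f2"])
        yte = rng.integers(0, 2, size=40)
        yte[:2] = [0, 1]
        res = three_level_validation({"logistic": ["f1", "f2"]}, X, y, Xte, yte,
                                     positive_label=1, reps=4, k=5, boot_B=50, seed=2)
        assert res.summaries["logistic"].cv_mean == pytest.approx(0.5, abs=0.06)

    def test_single_class_test_set_rejected(self):
        X, y = make_separable(n=40)
        with pytest.raises(ValueError, match="test set"):
            three_level_validation({"logistic": ["f1", "f2"]}, X, y,
                                   X.iloc[:5], np.ones(5, dtype=int),
                                   positive_label=1, reps=1, k=2, boot_B=10)


class TestLogisticSummary:
    def test_wald_arithmetic_identities(self):
        """z = B/SE and OR = exp(B) for a well-conditioned fit."""
        rng = np.random.default_rng(8)
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["u", "v"])
        logits = 0.744 * X["u"] - 0.3 * X["v"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int).to_numpy()
        tab = summarize_logistic(X, y, ["u", "v"], positive_label=1)
        row = tab.set_index("feature").loc["u"]
        assert row["z"] == pytest.approx(row["B"] / row["SE"])
        assert row["OR"] == pytest.approx(np.exp(row["B"]))
        assert row["CI_low"] == pytest.approx(np.exp(row["B"] - 1.96 * row["SE"]))
        assert not row["separation_flag"]

    def test_consistency_at_large_n(self):
        """Estimated coefficient within 3 SE of the generating value."""
        rng = np.random.default_rng(12)
        n = 10_000
        X = pd.DataFrame({"u": rng.normal(size=n)})
        beta = 0.8
        y = (rng.random(n) < 1 / (1 + np.exp(-beta * X["u"]))).astype(int).to_numpy()
        tab = summarize_logistic(X, y, ["u"], positive_label=1).set_index("feature")
        assert abs(tab.loc["u", "B"] - beta) < 3 * tab.loc["u", "SE"]

    def test_separation_flagged_and_cis_suppressed(self):
        X = pd.DataFrame({"u": np.r_[np.ones(10), -np.ones(10)]})
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        tab = summarize_logistic(X, y, ["u"], positive_label=1)
        assert tab["separation_flag"].any()
        flagged = tab[tab["separation_flag"]]
        assert flagged["CI_low"].isna().all()
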