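"""Classifier harness: metric formulas, leakage protection, determinism
and separability/null behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eegstress as es
from eegstress.evaluation import (
    CLASSIFIER_NAMES,
    ConfusionCounts,
    run_benchmark,
    summarize_reports,
)
from eegstress.exceptions import DomainError


class TestMetrics:
    def test_hand_computed_example(self):
        m = es.metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["precision"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["f_measure"] == pytest.approx(0.6667, abs=1e-4)

    def test_perfect_prediction(self):
        m = es.metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_policy(self):
        m = es.metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
        assert m["precision"] == 0.0
        assert m["f_measure"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            es.metrics(ConfusionCounts(0, 0, 0, 0))

    @given(
        tp=st.integers(0, 50), tn=st.integers(0, 50),
        fp=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_identities_on_random_confusions(self, tp, tn, fp, fn):
        """accuracy*total == tp+tn and F is the harmonic mean of precision
        and sensitivity, exactly, on every confusion matrix."""
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        if c.total == 0:
            return
        m = es.metrics(c)
        assert m["accuracy"] * c.total == pytest.approx(tp + tn)
        assert 0.0 <= min(m.values()) and max(m.values()) <= 1.0
        p, s = m["precision"], m["sensitivity"]
        if p + s > 0:
            assert m["f_measure"] == pytest.approx(2 * p * s / (p + s))


def separable_table(rng, n=40, n_cols=10, n_informative=4, shift=2.0):
    labels = np.array(["rest"] * (n // 2) + ["stress"] * (n // 2))
    data = rng.standard_normal((n, n_cols))
    data[labels == "stress", :n_informative] += shift
    return pd.DataFrame(data, columns=[f"f{i}" for i in range(n_cols)]), labels


class TestTrainEval:
    def test_separable_data_high_holdout_accuracy(self):
        """A 2-SD multi-feature contrast must yield >=0.9 held-out SVM
        accuracy in the median over 20 seeds."""
        accs = []
        for seed in range(20):
            X, y = separable_table(np.random.default_rng(seed))
            rep = es.train_eval(X, y, "SVM", es.SplitSpec(seed=seed))
            accs.append(rep["holdout_accuracy"])
        assert np.median(accs) >= 0.9

    def test_label_permutation_collapses_to_chance(self):
        cv = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            X, y = separable_table(rng)
            rep = es.train_eval(X, rng.permutation(y), "SVM",
                                es.SplitSpec(seed=seed))
            cv.append(rep["cv_accuracy_mean"])
        assert abs(np.mean(cv) - 0.5) < 0.15

    def test_seeded_determinism(self):
        X, y = separable_table(np.random.default_rng(1))
        a = es.train_eval(X, y, "RF", es.SplitSpec(seed=3))
        b = es.train_eval(X, y, "RF", es.SplitSpec(seed=3))
        assert a == b

    def test_in_harness_selection_runs_on_training_rows_only(self):
        """Shifting a noise column in rows the split holds out must leave
        every training-fold (CV) number untouched."""
        from sklearn.model_selection import train_test_split

        rng = np.random.default_rng(9)
        X, y = separable_table(rng, n_cols=12)
        split = es.SplitSpec(seed=4)
        idx = np.arange(len(X))
        tr_idx, te_idx = train_test_split(
            idx, test_size=0.2, stratify=y, random_state=split.seed
        )
        X_shifted = X.copy()
        X_shifted.iloc[te_idx, 11] += 50.0  # test-block-only contamination
        sel = {"alpha": 0.05, "correction": "none"}
        rep_clean = es.train_eval(X, y, "LR", split, selection=sel)
        rep_shift = es.train_eval(X_shifted, y, "LR", split, selection=sel)
        for key in rep_clean:
            if str(key).startswith("cv_"):
                assert rep_clean[key] == rep_shift[key]

    def test_single_class_rejected(self):
        X, _ = separable_table(np.random.default_rng(0))
        with pytest.raises(DomainError):
            es.train_eval(X, np.array(["rest"] * len(X)), "SVM")

    def test_unknown_classifier_rejected(self):
        X, y = separable_table(np.random.default_rng(0))
        with pytest.raises(DomainError):
            es.train_eval(X, y, "MLP")

    def test_missing_values_rejected(self):
        X, y = separable_table(np.random.default_rng(0))
        X.iloc[0, 0] = np.nan
        with pytest.raises(DomainError):
            es.train_eval(X, y, "SVM")


class TestBenchmark:
    def test_seven_rows_and_all_metrics(self):
        X, y = separable_table(np.random.default_rng(2))
        report = run_benchmark(X, y, es.SplitSpec(seed=0))
        assert list(report.index) == list(CLASSIFIER_NAMES)
        for m in ("accuracy", "precision", "sensitivity", "specificity", "f_measure"):
            assert f"cv_{m}_mean" in report.columns
            assert f"holdout_{m}" in report.columns
        vals = report.filter(like="accuracy").to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_pinned_hyperparameters(self):
        svm = es.make_classifier("SVM")
        assert svm.C == 1.0 and svm.kernel == "rbf" and svm.tol == 1e-3
        knn = es.make_classifier("KNN")
        assert knn.n_neighbors == 5 and knn.metric == "euclidean"
        nb = es.make_classifier("NB")
        assert nb.var_smoothing == 1e-9
        rf = es.make_classifier("RF")
        assert rf.n_estimators == 100 and rf.criterion == "gini"
        dt = es.make_classifier("DT")
        assert dt.criterion == "gini"
        lr = es.make_classifier("LR")
        # ridge (L2) regularization is the estimator default in sklearn
        assert lr.tol == 1e-4 and lr.C == 1.0 and lr.l1_ratio in (None, 0.0)
        lda = es.make_classifier("LDA")
        assert lda.solver == "svd" and lda.tol == 1e-4

    def test_summary_aggregates_over_subjects(self):
        reports = []
        for seed in range(3):
            X, y = separable_table(np.random.default_rng(seed))
            reports.append(
                run_benchmark(X, y, es.SplitSpec(seed=seed), classifiers=("SVM", "LDA"))
            )
        summary = summarize_reports(reports)
        assert list(summary.index) == ["SVM", "LDA"]
        assert "holdout_accuracy_mean" in summary.columns
        assert (summary["holdout_accuracy_sd"] >= 0).all()
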