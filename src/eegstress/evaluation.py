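"""Seven-classifier benchmark with confusion-matrix metrics.

Classifiers and hyperparameters (fixed, not tuned): RBF-SVM (C=1, tol
1e-3), KNN (k=5, Euclidean), Gaussian NB (variance smoothing 1e-9), Random
Forest (100 trees, Gini), CART decision tree (Gini), L2 logistic
regression (C=1, tol 1e-4) and LDA (SVD solver, tol 1e-4).

Protocol: stratified 80/20 epoch split; z-score standardization and
(optionally) t-test feature selection are fitted on training rows only to
avoid test-set leakage; 5-fold cross-validation inside the training
portion provides the reported mean +/- SD and the held-out 20% is scored
once.  'stress' is the positive class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import DomainError
from .selection import select_significant

logger = logging.getLogger(__name__)

POSITIVE = "stress"
NEGATIVE = "rest"

CLASSIFIER_NAMES = ("SVM", "KNN", "NB", "RF", "DT", "LR", "LDA")

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f_measure")


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the seven benchmark classifiers with its pinned
    hyperparameters."""
    if name == "SVM":
        return SVC(C=1.0, kernel="rbf", tol=1e-3, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if name == "NB":
        return GaussianNB(var_smoothing=1e-9)
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=100, criterion="gini", random_state=seed
        )
    if name == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if name == "LR":
        # L2 penalty is the estimator default; naming it explicitly is
        # deprecated in scikit-learn >= 1.8
        return LogisticRegression(tol=1e-4, C=1.0, max_iter=1000)
    if name == "LDA":
        return LinearDiscriminantAnalysis(solver="svd", tol=1e-4)
    raise DomainError(f"unknown classifier {name!r}; known: {CLASSIFIER_NAMES}")


@dataclass(frozen=True)
class SplitSpec:
    """Evaluation protocol: 80/20 stratified epoch split with 5-fold CV on
    the training portion.  ``mode`` selects how a cohort is aggregated:
    per-subject splits averaged over subjects, all epochs pooled, or
    leave-one-subject-out."""

    train_fraction: float = 0.8
    cv_folds: int = 5
    mode: str = "per_subject_epochs"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise DomainError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise DomainError("cv_folds must be >= 2")
        if self.mode not in ("per_subject_epochs", "pooled_epochs", "leave_subject_out"):
            raise DomainError(f"unknown split mode {self.mode!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((yt == POSITIVE) & (yp == POSITIVE))),
        tn=int(np.sum((yt == NEGATIVE) & (yp == NEGATIVE))),
        fp=int(np.sum((yt == NEGATIVE) & (yp == POSITIVE))),
        fn=int(np.sum((yt == POSITIVE) & (yp == NEGATIVE))),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, sensitivity (recall), specificity and
    F-measure from confusion counts; zero-denominator ratios are 0."""
    if c.total == 0:
        raise DomainError("empty confusion matrix")
    precision = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    sensitivity = _safe_ratio(c.tp, c.tp + c.fn, "sensitivity")
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": _safe_ratio(c.tn, c.tn + c.fp, "specificity"),
        "f_measure": _safe_ratio(
            2 * precision * sensitivity, precision + sensitivity, "f_measure"
        ),
    }


def _validate_xy(features: pd.DataFrame, labels) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.asarray(labels)
    if len(y) != len(features):
        raise DomainError("one label per row required")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DomainError("need both classes present")
    if counts.min() < 2:
        raise DomainError("need at least 2 rows per class")
    if features.isna().any().any():
        raise DomainError("feature table contains missing values")
    return features, y


def _fit_score(clf_name, seed, X_tr, y_tr, X_te, y_te, selection):
    """Fit selection -> scaler -> classifier on the training block and
    score the test block.  Returns a metrics dict."""
    if selection is not None:
        sel = select_significant(
            X_tr, y_tr,
            alpha=selection.get("alpha", 0.05),
            correction=selection.get("correction", "none"),
            welch=selection.get("welch", False),
        )
        feats = sel.selected_features
        if not feats:
            logger.warning("selection kept no features; using all columns")
        else:
            X_tr = X_tr.loc[:, feats]
            X_te = X_te.loc[:, feats]
    scaler = StandardScaler().fit(X_tr)
    clf = make_classifier(clf_name, seed=seed)
    clf.fit(scaler.transform(X_tr), y_tr)
    pred = clf.predict(scaler.transform(X_te))
    return metrics(confusion_from_predictions(y_te, pred))


def train_eval(
    features: pd.DataFrame,
    labels,
    classifier: str,
    split: SplitSpec | None = None,
    selection: Mapping | None = None,
) -> dict:
    """Evaluate one classifier on one epoch table (pooled protocol).

    Returns CV mean/SD per metric over ``split.cv_folds`` stratified folds
    of the 80% training portion, plus the single held-out 20% score.
    Deterministic for a fixed split seed.
    """
    split = split or SplitSpec()
    X, y = _validate_xy(features, labels)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y,
        test_size=1.0 - split.train_fraction,
        stratify=y,
        random_state=split.seed,
    )
    skf = StratifiedKFold(
        n_splits=split.cv_folds, shuffle=True, random_state=split.seed
    )
    fold_metrics: list[dict[str, float]] = []
    for tr_idx, va_idx in skf.split(X_tr, y_tr):
        fold_metrics.append(
            _fit_score(
                classifier, split.seed,
                X_tr.iloc[tr_idx], y_tr[tr_idx],
                X_tr.iloc[va_idx], y_tr[va_idx],
                selection,
            )
        )
    holdout = _fit_score(classifier, split.seed, X_tr, y_tr, X_te, y_te, selection)
    out: dict = {"classifier": classifier}
    for m in METRIC_NAMES:
        vals = np.array([fm[m] for fm in fold_metrics])
        out[f"cv_{m}_mean"] = float(vals.mean())
        out[f"cv_{m}_sd"] = float(vals.std(ddof=0))
        out[f"holdout_{m}"] = float(holdout[m])
    return out


def run_benchmark(
    features: pd.DataFrame,
    labels,
    split: SplitSpec | None = None,
    classifiers: Sequence[str] = CLASSIFIER_NAMES,
    selection: Mapping | None = None,
) -> pd.DataFrame:
    """``train_eval`` over a classifier set; one row per classifier.
    A failing classifier is logged and reported as NaN without aborting
    the others."""
    rows = []
    for name in classifiers:
        try:
            rows.append(train_eval(features, labels, name, split, selection))
        except DomainError:
            raise
        except Exception as exc:
            logger.warning("classifier %s failed: %s", name, exc)
            row = {"classifier": name}
            for m in METRIC_NAMES:
                row[f"cv_{m}_mean"] = np.nan
                row[f"cv_{m}_sd"] = np.nan
                row[f"holdout_{m}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index("classifier")


def summarize_reports(reports: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-subject benchmark tables: mean and SD across subjects
    of each classifier's CV-mean and held-out metrics."""
    if not reports:
        raise DomainError("no reports to summarize")
    stacked = pd.concat(reports, keys=range(len(reports)), names=["subject"])
    grouped = stacked.groupby(level="classifier", sort=False)
    out = {}
    for m in METRIC_NAMES:
        out[f"cv_{m}_mean"] = grouped[f"cv_{m}_mean"].mean()
        out[f"cv_{m}_sd"] = grouped[f"cv_{m}_mean"].std(ddof=0)
        out[f"holdout_{m}_mean"] = grouped[f"holdout_{m}"].mean()
        out[f"holdout_{m}_sd"] = grouped[f"holdout_{m}"].std(ddof=0)
    return pd.DataFrame(out).loc[list(reports[0].index)]


def report_to_tsv(summary: pd.DataFrame, path) -> None:
    """Human-readable TSV: one row per classifier, ``mean +/- SD`` cells."""
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [m for m in METRIC_NAMES]
    lines = ["classifier\t" + "\t".join(cols)]
    for clf in summary.index:
        cells = []
        for m in cols:
            if f"holdout_{m}_mean" in summary.columns:
                mean = summary.loc[clf, f"holdout_{m}_mean"]
                sd = summary.loc[clf, f"holdout_{m}_sd"]
            else:
                mean = summary.loc[clf, f"cv_{m}_mean"]
                sd = summary.loc[clf, f"cv_{m}_sd"]
            cells.append(f"{mean:.3f} ± {sd:.3f}")
        lines.append(clf + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
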