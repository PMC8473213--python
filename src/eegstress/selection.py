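"""Two-sample t-test feature screening and multi-domain fusion.

Every feature column is tested stress vs rest with a classic
pooled-variance independent two-sample t-test (Welch's variant available by
flag); columns with (optionally Bonferroni-adjusted) two-sided p below the
significance level survive.  The surviving columns from the time, spectral
and connectivity tables are then concatenated into one hybrid feature
vector; provenance stays recoverable from the ``time__`` / ``freq__`` /
``plv__`` column-name prefixes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSignalError, DomainError


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float


@dataclass
class SelectionResult:
    """Per-feature test report plus the boolean selection mask."""

    report: pd.DataFrame  # columns: feature, t, p, p_adj, selected
    alpha: float
    correction: str

    @property
    def mask(self) -> pd.Series:
        return self.report.set_index("feature")["selected"]

    @property
    def selected_features(self) -> list[str]:
        return list(self.report.loc[self.report["selected"], "feature"])

    @property
    def n_selected(self) -> int:
        return int(self.report["selected"].sum())

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path


def ttest_feature(group_a, group_b, welch: bool = False) -> TTestResult:
    """Independent two-sample t-test (pooled variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 observations")
    if np.var(a, ddof=1) + np.var(b, ddof=1) <= 0:
        raise DegenerateSignalError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else a.size + b.size - 2
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=float(df))


def select_significant(
    table: pd.DataFrame,
    labels: Sequence[str],
    alpha: float = 0.05,
    correction: str = "none",
    welch: bool = False,
) -> SelectionResult:
    """Screen every column with a stress-vs-rest t-test.

    ``correction`` is ``"none"`` (per-test alpha) or ``"bonferroni"``
    (familywise).  Columns with zero pooled variance or missing values get
    p = 1 and are never selected.
    """
    if correction not in ("none", "bonferroni"):
        raise DomainError(f"unknown correction {correction!r}")
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise DomainError("one label per row required")
    groups = set(labels.tolist())
    if groups != {"stress", "rest"}:
        raise DomainError(f"need both 'stress' and 'rest' labels, got {groups}")
    is_stress = labels == "stress"
    m = table.shape[1]
    a = table.loc[is_stress].to_numpy(dtype=float)
    b = table.loc[~is_stress].to_numpy(dtype=float)
    # columns with missing values or zero pooled variance get p = 1
    bad = (
        np.isnan(a).any(axis=0)
        | np.isnan(b).any(axis=0)
        | ((np.nan_to_num(a).var(axis=0) + np.nan_to_num(b).var(axis=0)) <= 0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    tvals = np.where(bad, np.nan, res.statistic)
    pvals = np.where(bad, 1.0, res.pvalue)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    report = pd.DataFrame(
        {"feature": list(table.columns), "t": tvals, "p": pvals}
    )
    if correction == "bonferroni":
        report["p_adj"] = np.minimum(report["p"] * m, 1.0)
    else:
        report["p_adj"] = report["p"]
    report["selected"] = report["p_adj"] < alpha
    return SelectionResult(report=report, alpha=alpha, correction=correction)


def fuse(
    tables: Sequence[pd.DataFrame],
    selections: Sequence[SelectionResult] | None = None,
) -> pd.DataFrame:
    """Column-wise concatenation of the selected columns of row-aligned
    feature tables.  With ``selections=None`` all columns pass through."""
    if not tables:
        raise DomainError("no tables to fuse")
    index = tables[0].index
    for t in tables[1:]:
        if len(t) != len(index) or not (t.index == index).all():
            raise DomainError("tables are not row-aligned")
    if selections is None:
        parts = list(tables)
    else:
        if len(selections) != len(tables):
            raise DomainError("one selection per table required")
        parts = [
            t.loc[:, sel.selected_features] for t, sel in zip(tables, selections)
        ]
    fused = pd.concat(parts, axis=1)
    if fused.shape[1] == 0:
        raise DomainError("fusion produced an empty table (no features selected)")
    if fused.columns.duplicated().any():
        raise DomainError("duplicate feature names across fused tables")
    return fused
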