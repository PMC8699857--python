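"""Normality checks, per-feature two-sample t-tests, and feature selection.

Each symmetry feature is compared between the paralysis and control groups
with a two-sided Welch (unequal-variance) t-test; features with p < alpha
(default 0.05, no multiple-testing correction by default) are selected for
the classifier.  Shapiro-Wilk normality results are reported as advisory
context but never gate the selection.

Two selection modes exist.  ``paper_faithful`` tests once on the full
cohort, which leaks test-set information into the feature choice when the
same cohort is later cross-validated; ``leak_free`` defers selection to the
training fold of each split (see :mod:`thermasym.classify_eval`) and is what
should be trusted on real data.

A scikit-learn compatible :class:`TTestSelector` exposes the same selection
as a fit/transform estimator usable inside sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data
from statsmodels.stats.multitest import multipletests

from .errors import GroupingError, SizeError

POSITIVE_GROUP = "paralysis"
NEGATIVE_GROUP = "normal"


def shapiro_wilk_check(values, alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk normality p-value and pass flag (p >= alpha).

    Advisory only: selection proceeds regardless of the outcome.
    """
    values = np.asarray(values, dtype=float).ravel()
    if not (3 <= values.size <= 5000):
        raise SizeError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise SizeError("Shapiro-Wilk undefined for a constant sample")
    p = float(stats.shapiro(values).pvalue)
    return p, p >= alpha


def t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test; returns (t statistic, p-value).

    Two zero-variance samples with equal means give (0, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise SizeError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise SizeError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _welch_pvalues(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Vectorized Welch p-values, one per column; NaN-safe for degenerate
    columns (zero variance in both groups -> p = 1)."""
    res = stats.ttest_ind(xa, xb, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (xa.std(axis=0) == 0) & (xb.std(axis=0) == 0)
    p[degenerate & (xa.mean(axis=0) == xb.mean(axis=0))] = 1.0
    p[degenerate & (xa.mean(axis=0) != xb.mean(axis=0))] = 0.0
    return p


@dataclass
class SelectionResult:
    """Per-feature group statistics, p-values, and the selected name list."""

    table: pd.DataFrame  # columns: mean_pos, sd_pos, mean_neg, sd_neg, p_value, selected
    alpha: float
    mode: str
    selected: list[str] = field(init=False)

    def __post_init__(self):
        self.selected = list(self.table.index[self.table["selected"]])

    def to_tsv(self, path=None) -> str:
        out = self.table.copy()
        text = out.to_csv(path, sep="\t", float_format="%.6g")
        return text if path is None else ""


def select_features(features: pd.DataFrame, groups, alpha: float = 0.05,
                    mode: str = "paper_faithful",
                    correction: str | None = None) -> SelectionResult:
    """Welch-test every feature between the two groups; select p < alpha.

    ``features`` is subjects x features; ``groups`` holds the group label
    per subject (positive = 'paralysis').  ``correction='bh'`` applies
    Benjamini-Hochberg to the p-values before thresholding (off by default).
    """
    groups = np.asarray(groups)
    labels = set(groups)
    if labels != {POSITIVE_GROUP, NEGATIVE_GROUP}:
        raise GroupingError(
            f"need groups {{{POSITIVE_GROUP!r}, {NEGATIVE_GROUP!r}}}, got {sorted(labels)}"
        )
    xa = features.loc[groups == POSITIVE_GROUP].to_numpy(dtype=float)
    xb = features.loc[groups == NEGATIVE_GROUP].to_numpy(dtype=float)
    p = _welch_pvalues(xa, xb)
    if correction == "bh":
        p = multipletests(p, method="fdr_bh")[1]
    elif correction is not None:
        raise GroupingError(f"unknown correction {correction!r}")
    table = pd.DataFrame(
        {
            "mean_pos": xa.mean(axis=0),
            "sd_pos": xa.std(axis=0, ddof=1),
            "mean_neg": xb.mean(axis=0),
            "sd_neg": xb.std(axis=0, ddof=1),
            "p_value": p,
            "selected": p < alpha,
        },
        index=features.columns,
    )
    return SelectionResult(table=table, alpha=alpha, mode=mode)


class TTestSelector(SelectorMixin, BaseEstimator):
    """Select features whose Welch-test p-value between classes is < alpha.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance threshold on the raw (or BH-adjusted) p-values.
    correction : {None, 'bh'}, default None
        Optional Benjamini-Hochberg adjustment.

    Attributes
    ----------
    pvalues_ : ndarray of shape (n_features,)
    support_ : boolean mask of selected features
    """

    def __init__(self, alpha: float = 0.05, correction: str | None = None):
        self.alpha = alpha
        self.correction = correction

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise GroupingError(f"TTestSelector needs exactly 2 classes, got {classes.size}")
        p = _welch_pvalues(X[y == classes[0]], X[y == classes[1]])
        if self.correction == "bh":
            p = multipletests(p, method="fdr_bh")[1]
        self.pvalues_ = p
        self.support_ = p < self.alpha
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_
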