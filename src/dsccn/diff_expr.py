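"""Differential-expression filtering: Welch t-test plus fold-change rules.

A feature is called *lowly expressed* when its two-sided t-test p-value is
below ``p_thresh`` and its fold change (disease-mean / healthy-mean, raw
scale) is below ``fc_low``; *highly expressed* when the p-value passes and the
fold change exceeds ``fc_high``; *normal* otherwise.  The defaults
(p < 0.01, FC < 0.5 low, FC > 1 high) are applied exactly as stated, including
the asymmetric dead zone 0.5 <= FC <= 1 in which no call is made.  No
multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DEResult",
    "ttest_pvalues",
    "fold_changes",
    "de_filter",
    "volcano_table",
    "DifferentialExpressionSelector",
]

CALL_LEVELS = ("low", "normal", "high")


@dataclass
class DEResult:
    """Per-feature differential-expression outcome for one omics."""

    feature_ids: list[str]
    p_values: np.ndarray
    fold_changes: np.ndarray
    calls: np.ndarray
    thresholds: tuple[float, float, float]  # (p_thresh, fc_low, fc_high)

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        if not (len(self.p_values) == len(self.fold_changes) == len(self.calls) == n):
            raise ValueError("DEResult fields must have equal length")

    @property
    def de_mask(self) -> np.ndarray:
        """True where the feature is called low or high (the DE set)."""
        return self.calls != "normal"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "p_value": self.p_values,
                "fold_change": self.fold_changes,
                "call": self.calls,
            }
        )


def _as_2d(mat) -> np.ndarray:
    arr = np.asarray(mat, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    return arr


def ttest_pvalues(case, ctrl) -> np.ndarray:
    """Two-sided Welch t-test p-value per feature (column).

    Features with zero variance in both groups and equal means have an
    undefined t statistic; their p-value is defined as 1 and a warning is
    emitted.
    """
    case, ctrl = _as_2d(case), _as_2d(ctrl)
    if case.shape[1] != ctrl.shape[1]:
        raise ValueError("case and ctrl must have the same feature count")
    if case.shape[0] < 2 or ctrl.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    undefined = np.isnan(p)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} feature(s) with undefined t statistic; "
            "p-value set to 1",
            stacklevel=2,
        )
        p[undefined] = 1.0
    return p


def fold_changes(case, ctrl) -> np.ndarray:
    """Fold change per feature: mean(case) / mean(ctrl) on the raw scale."""
    case, ctrl = _as_2d(case), _as_2d(ctrl)
    if case.shape[1] != ctrl.shape[1]:
        raise ValueError("case and ctrl must have the same feature count")
    ctrl_mean = ctrl.mean(axis=0)
    bad = np.flatnonzero(ctrl_mean <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive control-group mean for feature index {bad[0]}; "
            "fold change requires a positive raw scale"
        )
    return case.mean(axis=0) / ctrl_mean


def de_filter(
    pvals,
    fcs,
    p_thresh: float = 0.01,
    fc_low: float = 0.5,
    fc_high: float = 1.0,
) -> np.ndarray:
    """Apply the two-rule call: low/high need p < p_thresh and FC outside [fc_low, fc_high]."""
    pvals = np.asarray(pvals, dtype=float)
    fcs = np.asarray(fcs, dtype=float)
    if pvals.shape != fcs.shape:
        raise ValueError("p-value and fold-change vectors must have equal length")
    sig = pvals < p_thresh
    return np.select(
        [sig & (fcs < fc_low), sig & (fcs > fc_high)],
        ["low", "high"],
        default="normal",
    ).astype(object)


def volcano_table(result: DEResult) -> pd.DataFrame:
    """Plottable volcano table: one row per feature with log2 FC and -log10 p."""
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "feature_id": result.feature_ids,
                "log2_fc": np.log2(result.fold_changes),
                "neg_log10_p": -np.log10(result.p_values),
                "call": result.calls,
            }
        )


class DifferentialExpressionSelector(TransformerMixin, BaseEstimator):
    """Feature selector keeping differentially expressed columns.

    Parameters
    ----------
    p_thresh, fc_low, fc_high : float
        Call thresholds (see :func:`de_filter`).
    case_label : str
        Value of ``y`` marking the case (disease) group; every other value is
        treated as control.

    Attributes
    ----------
    result_ : DEResult
        Per-feature p-values, fold changes and calls from :meth:`fit`.
    support_mask_ : ndarray of bool
        True for columns retained by :meth:`transform`.
    """

    def __init__(
        self,
        p_thresh: float = 0.01,
        fc_low: float = 0.5,
        fc_high: float = 1.0,
        case_label: str = "disease",
    ):
        self.p_thresh = p_thresh
        self.fc_low = fc_low
        self.fc_high = fc_high
        self.case_label = case_label

    def fit(self, X, y):
        feature_ids = (
            list(X.columns)
            if isinstance(X, pd.DataFrame)
            else [f"f{j}" for j in range(np.shape(X)[1])]
        )
        arr = _as_2d(X)
        y = np.asarray(y)
        case_mask = y == self.case_label
        if case_mask.sum() < 2 or (~case_mask).sum() < 2:
            raise ValueError("need at least 2 case and 2 control samples")
        case, ctrl = arr[case_mask], arr[~case_mask]
        p = ttest_pvalues(case, ctrl)
        fc = fold_changes(case, ctrl)
        calls = de_filter(p, fc, self.p_thresh, self.fc_low, self.fc_high)
        self.result_ = DEResult(
            feature_ids=feature_ids,
            p_values=p,
            fold_changes=fc,
            calls=calls,
            thresholds=(self.p_thresh, self.fc_low, self.fc_high),
        )
        self.support_mask_ = self.result_.de_mask
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_mask_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_mask_]
        return _as_2d(X)[:, self.support_mask_]
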