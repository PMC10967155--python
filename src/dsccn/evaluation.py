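"""Classification metrics, the repeated stratified CV protocol, and the
selected-gene pairwise correlation analysis.

Binary metrics follow the standard contingency formulas (ACC, Precision,
Recall, F1); multi-class performance is summarized by macro averaging —
one-vs-rest Precision/Recall/F1 per class, then the unweighted arithmetic
mean.  Zero-division cases (no predicted positives, or P + R = 0) are defined
as 0 with a warning, following the dominant community convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "binary_metrics",
    "macro_metrics",
    "roc_auc",
    "normalize_confusion",
    "stratified_repeated_cv",
    "pairwise_gene_correlation",
    "evaluate_predictions",
]


@dataclass
class ConfusionMatrix:
    """Count matrix with rows = true labels, columns = predicted labels."""

    counts: np.ndarray
    labels: list

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class EvalReport:
    """Aggregated classification metrics."""

    accuracy: float
    precision_per_class: dict
    recall_per_class: dict
    f1_per_class: dict
    precision_macro: float
    recall_macro: float
    f1_macro: float
    auc: float | None
    confusion: ConfusionMatrix | None = None
    normalized_confusion: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "auc": self.auc,
            "precision_per_class": self.precision_per_class,
            "recall_per_class": self.recall_per_class,
            "f1_per_class": self.f1_per_class,
        }
        if self.normalized_confusion is not None:
            out["normalized_confusion"] = self.normalized_confusion.tolist()
            out["labels"] = list(map(str, self.confusion.labels))
        out.update(self.extras)
        return out


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Tally counts[a, b] = #{i : true = a, pred = b}."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred])).tolist()
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside the declared alphabet: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=list(labels))


def _prf(tp: float, fp: float, fn: float, context: str) -> tuple[float, float, float]:
    if tp + fp == 0:
        warnings.warn(f"no predicted positives for {context}; precision set to 0",
                      stacklevel=3)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if precision + recall == 0:
        warnings.warn(f"P + R = 0 for {context}; F1 set to 0", stacklevel=3)
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def binary_metrics(cm: ConfusionMatrix, positive=None) -> tuple[float, float, float, float]:
    """(ACC, Precision, Recall, F1) for a 2x2 confusion matrix.

    The positive class defaults to the smaller true class (overridable).
    """
    counts = cm.counts
    if counts.shape != (2, 2):
        raise ValueError("binary_metrics requires a 2x2 confusion matrix")
    if positive is None:
        positive = cm.labels[int(np.argmin(counts.sum(axis=1)))]
    pos = cm.labels.index(positive)
    neg = 1 - pos
    tp, fn = counts[pos, pos], counts[pos, neg]
    fp, tn = counts[neg, pos], counts[neg, neg]
    acc = (tp + tn) / max(tp + tn + fp + fn, 1)
    precision, recall, f1 = _prf(tp, fp, fn, f"class {positive!r}")
    return float(acc), float(precision), float(recall), float(f1)


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Unweighted means of one-vs-rest per-class Precision/Recall/F1."""
    counts = cm.counts
    if counts.shape[0] < 2:
        raise ValueError("macro metrics require at least two classes")
    ps, rs, fs = [], [], []
    for c, lab in enumerate(cm.labels):
        tp = counts[c, c]
        fp = counts[:, c].sum() - tp
        fn = counts[c, :].sum() - tp
        p, r, f = _prf(tp, fp, fn, f"class {lab!r}")
        ps.append(p)
        rs.append(r)
        fs.append(f)
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


def per_class_metrics(cm: ConfusionMatrix) -> tuple[dict, dict, dict]:
    ps, rs, fs = {}, {}, {}
    for c, lab in enumerate(cm.labels):
        tp = cm.counts[c, c]
        fp = cm.counts[:, c].sum() - tp
        fn = cm.counts[c, :].sum() - tp
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f = _prf(tp, fp, fn, str(lab))
        ps[lab], rs[lab], fs[lab] = p, r, f
    return ps, rs, fs


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve for binary labels and continuous scores."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) != 2:
        raise ValueError("roc_auc requires exactly two classes in y_true")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def normalize_confusion(cm: ConfusionMatrix) -> np.ndarray:
    """Row-normalize counts so each true-class row sums to 1."""
    row_sums = cm.counts.sum(axis=1, keepdims=True)
    empty = np.flatnonzero(row_sums.ravel() == 0)
    if empty.size:
        raise ValueError(f"empty true class {cm.labels[empty[0]]!r}")
    return cm.counts / row_sums


def evaluate_predictions(y_true, y_pred, labels=None, scores=None) -> EvalReport:
    """Full report: accuracy, per-class and macro metrics, optional binary AUC."""
    cm = confusion(y_true, y_pred, labels)
    acc = float(np.trace(cm.counts) / max(cm.n_samples, 1))
    p_macro, r_macro, f_macro = macro_metrics(cm)
    ps, rs, fs = per_class_metrics(cm)
    auc = None
    if scores is not None and len(cm.labels) == 2:
        auc = roc_auc(np.asarray(y_true) == cm.labels[1], scores)
    return EvalReport(
        accuracy=acc,
        precision_per_class=ps,
        recall_per_class=rs,
        f1_per_class=fs,
        precision_macro=p_macro,
        recall_macro=r_macro,
        f1_macro=f_macro,
        auc=auc,
        confusion=cm,
        normalized_confusion=normalize_confusion(cm),
    )


def stratified_repeated_cv(
    y,
    runner,
    k: int = 5,
    repeats: int = 30,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation repeated with fresh seeded partitions.

    ``runner(train_idx, test_idx)`` must return ``(y_true, y_pred)`` (optionally
    ``(y_true, y_pred, scores)``) for the held-out fold.  Repeat r uses seed
    ``seed + r`` for its partition.  Returns per-fold metrics and their means.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has fewer than k={k} samples"
        )
    rows = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            out = runner(tr, te)
            y_true, y_pred = out[0], out[1]
            scores = out[2] if len(out) > 2 else None
            rep = evaluate_predictions(y_true, y_pred, labels=list(classes),
                                       scores=scores)
            rows.append(
                {
                    "repeat": r,
                    "fold": fold,
                    "accuracy": rep.accuracy,
                    "precision_macro": rep.precision_macro,
                    "recall_macro": rep.recall_macro,
                    "f1_macro": rep.f1_macro,
                    "auc": rep.auc,
                }
            )
    per_fold = pd.DataFrame(rows)
    means = per_fold[
        ["accuracy", "precision_macro", "recall_macro", "f1_macro"]
    ].mean().to_dict()
    if per_fold["auc"].notna().all():
        means["auc"] = float(per_fold["auc"].mean())
    return {"mean": means, "per_fold": per_fold}


def pairwise_gene_correlation(
    X_sel, Y_sel, alpha: float = 1e-5
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Pearson r, two-sided p, and a significance mask for all cross-omics pairs.

    Returns (r matrix [g1 x g2], p matrix, mask at p < alpha, significant
    fraction).  Pairs involving a constant column are reported as missing
    (NaN, mask False).
    """
    X = np.asarray(X_sel, dtype=float)
    Y = np.asarray(Y_sel, dtype=float)
    s = X.shape[0]
    if s < 3 or Y.shape[0] != s:
        raise ValueError("need >= 3 aligned samples in both matrices")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.linalg.norm(Xc, axis=0)
    sy = np.linalg.norm(Yc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Yc) / np.outer(sx, sy)
    r[np.outer(sx == 0, np.ones_like(sy, dtype=bool))] = np.nan
    r[np.outer(np.ones_like(sx, dtype=bool), sy == 0)] = np.nan
    r = np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((s - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=s - 2)
    p[np.isnan(r)] = np.nan
    p[np.abs(r) == 1.0] = 0.0
    mask = p < alpha
    valid = ~np.isnan(p)
    frac = float(mask[valid].mean()) if valid.any() else np.nan
    return r, p, mask, frac
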