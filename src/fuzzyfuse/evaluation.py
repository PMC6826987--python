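"""Segmentation and classification metrics plus the CV harness.

Segmentation quality is scored by the Tanimoto coefficient (per-tissue
overlap of automated and reference labelings) and the Jaccard
similarity of binary masks. Classifier quality uses sensitivity,
specificity, accuracy, the ROC curve and its area. The
cross-validation harness reproduces the 10x random 70/30 stratified
resampling protocol (with standard disjoint k-fold available as an
option) and summarises per-split metrics with boxplot five-number
statistics and outlier flags.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

__all__ = [
    "ConfusionCounts", "tanimoto", "jaccard", "confusion",
    "sensitivity", "specificity", "accuracy", "roc_auc", "equal_error_rate",
    "cross_validate", "summarize",
]


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def tanimoto(auto, ref, tissue) -> float:
    """Tanimoto coefficient TC(T) = v_ART / (v_AT + v_RT - v_ART).

    ``auto``/``ref`` are label grids (or LabelMap objects); ``tissue``
    is the integer id compared. Both-empty tissues return 0 by
    convention.
    """
    a = np.asarray(getattr(auto, "labels", auto))
    r = np.asarray(getattr(ref, "labels", ref))
    if a.shape != r.shape:
        raise ValueError("label grids must share a shape")
    am = a == tissue
    rm = r == tissue
    inter = int((am & rm).sum())
    union = int(am.sum() + rm.sum() - inter)
    if union == 0:
        return 0.0
    return inter / union


def jaccard(seg: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard similarity |S n G| / |S u G| of two binary masks."""
    s = np.asarray(seg, dtype=bool)
    g = np.asarray(truth, dtype=bool)
    union = int((s | g).sum())
    if union == 0:
        return 0.0
    return int((s & g).sum()) / union


def confusion(pred, true, positive_class=1) -> ConfusionCounts:
    """Binary confusion counts with an explicit positive class."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    pp = pred == positive_class
    tp_ = true == positive_class
    return ConfusionCounts(
        tp=int((pp & tp_).sum()),
        fp=int((pp & ~tp_).sum()),
        tn=int((~pp & ~tp_).sum()),
        fn=int((~pp & tp_).sum()),
    )


def sensitivity(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when there are no positives."""
    denom = c.tp + c.fn
    return None if denom == 0 else c.tp / denom


def specificity(c: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when there are no negatives."""
    denom = c.tn + c.fp
    return None if denom == 0 else c.tn / denom


def accuracy(c: ConfusionCounts) -> float | None:
    """(TP + TN) / all."""
    return None if c.total == 0 else (c.tp + c.tn) / c.total


def roc_auc(scores, labels, positive_class=1):
    """ROC curve (FPR, TPR points) and trapezoidal AUC.

    Thresholds sweep the unique scores; the trapezoid area equals the
    Mann-Whitney concordance statistic (ties counting one half).
    """
    scores = np.asarray(scores, dtype=float)
    y = (np.asarray(labels) == positive_class).astype(int)
    if y.min() == y.max():
        raise ValueError("need both classes to build a ROC curve")
    fpr, tpr, _ = _skm.roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def equal_error_rate(scores, labels, positive_class=1) -> float:
    """Operating point where the false-accept rate equals the
    false-reject rate, linearly interpolated along the ROC curve."""
    curve, _ = roc_auc(scores, labels, positive_class)
    fpr, tpr = curve[:, 0], curve[:, 1]
    fnr = 1.0 - tpr
    diff = fpr - fnr
    idx = int(np.argmax(diff >= 0))
    if idx == 0:
        return float((fpr[0] + fnr[0]) / 2)
    # interpolate between the bracketing points
    x0, x1 = diff[idx - 1], diff[idx]
    w = 0.0 if x1 == x0 else -x0 / (x1 - x0)
    return float((1 - w) * fpr[idx - 1] + w * fpr[idx])


def summarize(values: np.ndarray) -> dict:
    """Boxplot five-number summary plus mean/Sdev and outlier flags.

    Mild outliers fall outside Q1 - 1.5 IQR / Q3 + 1.5 IQR, extreme
    outliers outside 3 IQR.
    """
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    mild = ((v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr))
    extreme = ((v < q1 - 3.0 * iqr) | (v > q3 + 3.0 * iqr))
    return {
        "min": float(v.min()), "q1": float(q1), "median": float(med),
        "q3": float(q3), "max": float(v.max()),
        "mean": float(v.mean()), "sdev": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        "iqr": float(iqr),
        "n_mild_outliers": int(mild.sum() - extreme.sum()),
        "n_extreme_outliers": int(extreme.sum()),
    }


def cross_validate(X, y, model_factory, n_splits: int = 10,
                   train_fraction: float = 0.7, seed: int = 0,
                   scheme: str = "resample") -> pd.DataFrame:
    """Repeated stratified splitting with per-split metrics.

    ``scheme="resample"`` draws ``n_splits`` independent stratified
    70/30 train/test partitions (the protocol used throughout);
    ``scheme="kfold"`` runs standard disjoint stratified k-fold
    instead. ``model_factory()`` must return an object with
    ``fit(X, y)``, ``predict(X)`` and, optionally, ``score_samples(X)``
    for ROC construction.

    Returns a DataFrame with one row per split (se, sp, ca, auc).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if scheme == "resample":
        splitter = StratifiedShuffleSplit(n_splits=n_splits,
                                          train_size=train_fraction,
                                          random_state=seed)
    elif scheme == "kfold":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                   random_state=seed)
    else:
        raise ValueError("scheme must be 'resample' or 'kfold'")

    rows = []
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        model = model_factory()
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        c = confusion(pred, y[te])
        row = {"fold": fold, "se": sensitivity(c), "sp": specificity(c),
               "ca": accuracy(c)}
        if hasattr(model, "score_samples") and len(np.unique(y[te])) > 1:
            _, auc = roc_auc(model.score_samples(X[te]), y[te])
            row["auc"] = auc
        rows.append(row)
    return pd.DataFrame(rows)
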