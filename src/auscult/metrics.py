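"""Confusion matrices, macro one-vs-rest metrics, hold-out and k-fold protocols.

Convention: confusion-matrix rows index the *predicted* class and columns the *true*
class, in the fixed vocabulary order. Macro metrics are the unweighted mean of the
per-class one-vs-rest rates, reported as percentages rounded to two decimals
(round-half-even); 0/0 ratios (a class absent and never predicted) count as 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .vocab import CLASSES


@dataclass
class ConfusionMatrix:
    """Counts[p, t]: samples with predicted class p and true class t."""

    counts: np.ndarray
    classes: tuple = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError(f"counts must be a nonnegative {k}x{k} matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_errors(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class MetricsReport:
    """Macro one-vs-rest percentages plus the per-class breakdown."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    per_class: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "f1": self.f1}

    def to_csv(self, path) -> None:
        pd.DataFrame([self.as_dict()]).to_csv(path, index=False)

    def __str__(self) -> str:
        return ("accuracy {accuracy:.2f}%  precision {precision:.2f}%  "
                "sensitivity {sensitivity:.2f}%  specificity {specificity:.2f}%  "
                "f1 {f1:.2f}%").format(**self.as_dict())


def confusion(y_true, y_pred, classes: tuple = CLASSES) -> ConfusionMatrix:
    """Build the (predicted x true) count matrix."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        ti = index[t] if t in index else _bad_label(t, classes)
        pi = index[p] if p in index else _bad_label(p, classes)
        counts[pi, ti] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def _bad_label(label, classes):
    raise ValueError(f"label {label!r} not in vocabulary {classes}")


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return 1.0  # class absent and never predicted
    return num / den


def macro_report(cm: ConfusionMatrix) -> MetricsReport:
    """Macro one-vs-rest metrics from a (predicted x true) confusion matrix."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(np.float64)
    rows = []
    for i, name in enumerate(cm.classes):
        tp = c[i, i]
        fp = c[i, :].sum() - tp   # predicted i but true something else
        fn = c[:, i].sum() - tp   # true i but predicted something else
        tn = total - tp - fp - fn
        rows.append({
            "class": name,
            "accuracy": (tp + tn) / total,
            "precision": _ratio(tp, tp + fp),
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
        })
    per = pd.DataFrame(rows).set_index("class")
    ps = per["precision"] + per["sensitivity"]
    per["f1"] = np.where(ps > 0, 2 * per["precision"] * per["sensitivity"] / ps, 0.0)

    def pct(col: str) -> float:
        # percent, two decimals, round-half-even
        return float(np.round(per[col].mean() * 100.0, 2))

    return MetricsReport(accuracy=pct("accuracy"), precision=pct("precision"),
                         sensitivity=pct("sensitivity"), specificity=pct("specificity"),
                         f1=pct("f1"), per_class=per)


def evaluate(y_true, y_pred, classes: tuple = CLASSES) -> tuple[ConfusionMatrix, MetricsReport]:
    cm = confusion(y_true, y_pred, classes)
    return cm, macro_report(cm)


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------

def holdout_split(n_or_labels, train_frac: float = 0.8, seed: int = 0,
                  stratify: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Index split with train size floor(train_frac * N); disjoint and exhaustive.

    Pass the label sequence to stratify by class (the default; prevents empty
    classes at small N), or a plain integer N with ``stratify=False``.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if np.isscalar(n_or_labels):
        n = int(n_or_labels)
        labels = None
    else:
        labels = np.asarray(n_or_labels)
        n = labels.size
    if n < 2:
        raise ValueError("need at least two samples to split")
    idx = np.arange(n)
    n_train = int(np.floor(train_frac * n))
    if stratify and labels is not None:
        tr, te = train_test_split(idx, train_size=n_train, random_state=seed,
                                  stratify=labels, shuffle=True)
        return np.sort(tr), np.sort(te)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def kfold_cv(labels, trainer, k: int = 10, seed: int = 0,
             stratify: bool = True) -> tuple[MetricsReport, list[MetricsReport]]:
    """k-fold cross-validation driver.

    ``trainer(train_idx, test_idx)`` must return predicted labels for ``test_idx``.
    Returns the unweighted mean of the per-fold macro reports plus the fold reports.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if labels.size < k:
        raise ValueError("need at least k samples")
    splitter = (StratifiedKFold(k, shuffle=True, random_state=seed) if stratify
                else KFold(k, shuffle=True, random_state=seed))
    reports = []
    for train_idx, test_idx in splitter.split(np.zeros(labels.size), labels):
        y_pred = trainer(train_idx, test_idx)
        cm = confusion(labels[test_idx], y_pred)
        reports.append(macro_report(cm))
    mean = {key: float(np.round(np.mean([r.as_dict()[key] for r in reports]), 2))
            for key in reports[0].as_dict()}
    return MetricsReport(**mean), reports


#: the printed hold-out confusion matrices of the published experiment, used as a
#: worked example for the metric arithmetic (rows = predicted, columns = true)
PUBLISHED_HYBRID_CONFUSION = np.array([
    [121, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 125, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 179, 1, 1, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 144, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 148, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 133, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 155, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 158, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 148, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 156, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 145],
], dtype=np.int64)

PUBLISHED_CNN_CONFUSION = np.array([
    [120, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 125, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [1, 0, 179, 5, 4, 2, 0, 0, 0, 0, 0],
    [0, 0, 0, 140, 1, 1, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 144, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 130, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 154, 0, 1, 1, 0],
    [0, 0, 0, 0, 0, 0, 0, 158, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 147, 0, 0],
    [0, 0, 0, 0, 0, 0, 1, 0, 0, 155, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 145],
], dtype=np.int64)
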