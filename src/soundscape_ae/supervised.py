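"""Supervised forest/non-forest baseline over acoustic feature spaces.

A Random Forest (100 trees, max depth 16) is trained on a seeded
stratified 80/20 split to predict the recording site's cover type from a
feature space — the full autoencoder embedding or any of its reduced
projections — and scored with accuracy, recall and F1 computed directly
from the confusion matrix:

    accuracy = (TP+TN)/(TP+TN+FP+FN)
    recall   = TP/(TP+FN)
    F1       = 2·precision·recall/(precision+recall)

Positive-class and macro-averaged recall/F1 are both reported, since
class imbalance makes the distinction matter.  ``compare_feature_spaces``
evaluates several spaces under the identical split and hyperparameters so
their scores are directly comparable; externally computed feature tables
(e.g. acoustic-index vectors) can be passed in the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np

__all__ = ["ClassificationReport", "train_eval_rf", "compare_feature_spaces", "metrics_from_confusion"]

POSITIVE_LABEL = "forest"


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    recall: float
    f1: float
    precision: float
    recall_macro: float
    f1_macro: float
    confusion: tuple  # (TP, FP, FN, TN) with "forest" as positive class
    feature_space: str
    n_train: int
    n_test: int


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> Dict[str, float]:
    """Accuracy/precision/recall/F1 (positive class and macro) from counts."""
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else 0.0

    def _prf(tp_, fp_, fn_):
        prec = tp_ / (tp_ + fp_) if (tp_ + fp_) else 0.0
        rec = tp_ / (tp_ + fn_) if (tp_ + fn_) else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        return prec, rec, f1

    prec_p, rec_p, f1_p = _prf(tp, fp, fn)
    prec_n, rec_n, f1_n = _prf(tn, fn, fp)  # negative class mirrors the counts
    return {
        "accuracy": accuracy,
        "precision": prec_p,
        "recall": rec_p,
        "f1": f1_p,
        "recall_macro": (rec_p + rec_n) / 2,
        "f1_macro": (f1_p + f1_n) / 2,
    }


def _binary_labels(labels: Sequence) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    positive = POSITIVE_LABEL if POSITIVE_LABEL in classes else classes[0]
    return (y == positive).astype(int)


def train_eval_rf(
    features: np.ndarray,
    labels: Sequence,
    split_fraction: float = 0.8,
    max_depth: int = 16,
    seed: int = 0,
    n_estimators: int = 100,
    feature_space: str = "features",
) -> ClassificationReport:
    """Stratified split, Random Forest fit, confusion-matrix metrics."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split

    X = np.asarray(features, dtype=np.float64)
    y = _binary_labels(labels)
    if len(X) != len(y):
        raise ValueError("features and labels must align")
    if len(X) < 10:
        raise ValueError("need at least 10 samples")

    idx_train, idx_test = train_test_split(
        np.arange(len(X)), train_size=split_fraction, stratify=y, random_state=seed
    )
    clf = RandomForestClassifier(n_estimators=n_estimators, max_depth=max_depth, random_state=seed)
    clf.fit(X[idx_train], y[idx_train])
    pred = clf.predict(X[idx_test])
    truth = y[idx_test]

    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    m = metrics_from_confusion(tp, fp, fn, tn)
    return ClassificationReport(
        accuracy=m["accuracy"],
        recall=m["recall"],
        f1=m["f1"],
        precision=m["precision"],
        recall_macro=m["recall_macro"],
        f1_macro=m["f1_macro"],
        confusion=(tp, fp, fn, tn),
        feature_space=feature_space,
        n_train=len(idx_train),
        n_test=len(idx_test),
    )


def compare_feature_spaces(
    spaces: Mapping[str, np.ndarray],
    labels: Sequence,
    split_fraction: float = 0.8,
    max_depth: int = 16,
    seed: int = 0,
):
    """One report per named feature space under an identical split and
    hyperparameters; returns a pandas DataFrame, one row per space."""
    import pandas as pd

    n = None
    for name, X in spaces.items():
        if n is None:
            n = len(X)
        elif len(X) != n:
            raise ValueError(f"feature space {name!r} has {len(X)} rows, expected {n}")
    if n != len(labels):
        raise ValueError("labels do not align with the feature spaces")

    rows = []
    for name, X in spaces.items():
        rep = train_eval_rf(
            X, labels, split_fraction=split_fraction, max_depth=max_depth, seed=seed, feature_space=name
        )
        rows.append(
            {
                "space": name,
                "accuracy": rep.accuracy,
                "recall": rep.recall,
                "f1": rep.f1,
                "recall_macro": rep.recall_macro,
                "f1_macro": rep.f1_macro,
                "n_train": rep.n_train,
                "n_test": rep.n_test,
            }
        )
    return pd.DataFrame(rows)
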