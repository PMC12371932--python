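"""Linear-SVM pairwise baseline for part-property relation classification.

Every observed (plant-part, property) co-occurrence becomes a candidate pair
instance encoded as a two-hot vector (one-hot part + one-hot property).  A
soft-margin linear maximum-margin classifier separates related from
unrelated pairs; the decision rule is f(x) = <w, x> + b >= 0 -> related.
Positive pairs are grouped by plant part (a star graph per part), and the
usual accuracy / precision / recall / F1 metrics are computed per part with
unweighted macro averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .corpus_io import BinaryVector

__all__ = [
    "PairInstance",
    "LinearModel",
    "pair_space",
    "make_pairs",
    "train_linear_svm",
    "group_by_pp",
    "evaluate",
    "evaluate_by_part",
    "macro_average",
    "cross_validate_pairs",
]


@dataclass(frozen=True)
class PairInstance:
    """One candidate (part i, property j) pair with its two-hot encoding."""

    pp_index: int
    mp_index: int
    n_parts: int
    n_properties: int
    label: Optional[int] = None
    part_label: str = ""
    property_label: str = ""

    @property
    def features(self) -> np.ndarray:
        x = np.zeros(self.n_parts + self.n_properties, dtype=float)
        x[self.pp_index] = 1.0
        x[self.n_parts + self.mp_index] = 1.0
        return x


@dataclass
class LinearModel:
    w: np.ndarray
    b: float
    margin: float = float("nan")

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.w + self.b

    def classify(self, X: np.ndarray) -> np.ndarray:
        """f(x) >= 0 -> positive class, exactly at the boundary too."""
        return (self.decision(X) >= 0).astype(int)


def pair_space(n_parts: int = 9, n_properties: int = 88) -> int:
    """Size of the full candidate pair space (9 x 88 = 792 by default)."""
    return n_parts * n_properties


def make_pairs(
    vectors: Sequence[BinaryVector],
    labels: Optional[Mapping[tuple[int, int], int]] = None,
    part_labels: Optional[Sequence[str]] = None,
    mp_labels: Optional[Sequence[str]] = None,
) -> list[PairInstance]:
    """Enumerate observed (part, property) co-occurrences as pair instances.

    One instance is emitted per (vector, set property bit) event, so a pair
    seen in several vectors yields several instances (and may carry both
    labels across the corpus).  ``labels`` maps (pp_index, mp_index) to 0/1;
    unknown pairs raise.
    """
    out: list[PairInstance] = []
    n_parts = len(vectors[0].pp_indicators) if vectors else 9
    n_props = len(vectors[0].mp_indicators) if vectors else 0
    for v in vectors:
        i = int(np.argmax(v.pp_indicators))
        for j in np.flatnonzero(v.mp_indicators):
            j = int(j)
            label = None
            if labels is not None:
                if (i, j) not in labels:
                    raise KeyError(f"no label for pair ({i}, {j})")
                label = int(labels[(i, j)])
            out.append(
                PairInstance(
                    pp_index=i,
                    mp_index=j,
                    n_parts=n_parts,
                    n_properties=n_props,
                    label=label,
                    part_label=part_labels[i] if part_labels else v.ppart,
                    property_label=mp_labels[j] if mp_labels else str(j),
                )
            )
    return out


def _as_xy(
    instances: Sequence[PairInstance] | np.ndarray,
    y: Optional[Sequence[int]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    if y is not None:
        X = np.atleast_2d(np.asarray(instances, dtype=float))
        return X, np.asarray(y, dtype=int)
    X = np.vstack([inst.features for inst in instances])
    yy = np.array([inst.label for inst in instances], dtype=float)
    if np.any(np.isnan(yy)):
        raise ValueError("unlabeled instance in training set")
    return X, yy.astype(int)


def train_linear_svm(
    instances: Sequence[PairInstance] | np.ndarray,
    y: Optional[Sequence[int]] = None,
    C: float = 1.0,
) -> LinearModel:
    """Fit a soft-margin linear SVM; accepts pair instances or raw (X, y).

    Deterministic for a fixed input (the linear-kernel solver has no random
    component at these sizes).  Raises on single-class input.
    """
    X, yy = _as_xy(instances, y)
    if len(np.unique(yy)) < 2:
        raise ValueError("training data contains a single class")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, yy)
    w = np.asarray(clf.coef_).ravel()
    b = float(clf.intercept_[0])
    margin = 2.0 / np.linalg.norm(w) if np.linalg.norm(w) > 0 else float("inf")
    return LinearModel(w=w, b=b, margin=margin)


def group_by_pp(positives: Iterable[PairInstance]) -> dict[str, set[str]]:
    """Partition positive pairs by plant part (the star-graph view)."""
    groups: dict[str, set[str]] = {}
    for inst in positives:
        part = inst.part_label or str(inst.pp_index)
        prop = inst.property_label or str(inst.mp_index)
        groups.setdefault(part, set()).add(prop)
    return groups


def evaluate(predictions: Sequence[int], truth: Sequence[int]) -> dict[str, float]:
    """Accuracy, precision, recall and F1 for one prediction set."""
    truth = np.asarray(truth, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if truth.size == 0:
        raise ValueError("empty truth")
    if truth.shape != predictions.shape:
        raise ValueError("predictions and truth are not aligned")
    return {
        "accuracy": float(accuracy_score(truth, predictions)),
        "precision": float(precision_score(truth, predictions, zero_division=0)),
        "recall": float(recall_score(truth, predictions, zero_division=0)),
        "f1": float(f1_score(truth, predictions, zero_division=0)),
    }


def evaluate_by_part(
    instances: Sequence[PairInstance],
    predictions: Sequence[int],
    truth: Sequence[int],
) -> dict[str, dict[str, float]]:
    """Per-part metric records."""
    parts = sorted({inst.part_label or str(inst.pp_index) for inst in instances})
    out = {}
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    for part in parts:
        idx = [
            k
            for k, inst in enumerate(instances)
            if (inst.part_label or str(inst.pp_index)) == part
        ]
        out[part] = evaluate(predictions[idx], truth[idx])
    return out


def macro_average(
    records: Sequence[Mapping[str, float]], ndigits: Optional[int] = 3
) -> dict[str, float]:
    """Unweighted mean of metric records, rounded as configured."""
    if not records:
        raise ValueError("no records to average")
    keys = records[0].keys()
    out = {}
    for key in keys:
        v = float(np.mean([r[key] for r in records]))
        out[key] = round(v, ndigits) if ndigits is not None else v
    return out


def cross_validate_pairs(
    instances: Sequence[PairInstance],
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> dict:
    """Seeded stratified k-fold harness over pair instances.

    Returns overall pooled metrics, per-part pooled metrics and the pooled
    out-of-fold predictions.
    """
    X, y = _as_xy(instances)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    for train_idx, test_idx in skf.split(X, y):
        model = train_linear_svm(X[train_idx], y[train_idx], C=C)
        preds[test_idx] = model.classify(X[test_idx])
    per_part = evaluate_by_part(instances, preds, y)
    return {
        "overall": evaluate(preds, y),
        "per_part": per_part,
        "macro": macro_average(list(per_part.values())),
        "predictions": preds,
    }
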