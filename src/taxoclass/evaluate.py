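"""Per-rank evaluation: confusion projection, multiclass MCC,
precision/recall, and the unseen-taxa species false-positive rate.

The headline metric is the multiclass Matthews correlation coefficient

    MCC = (c*s - sum_k p_k t_k) /
          sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

over a K-class confusion matrix with row sums t_k (true occurrences of
class k), column sums p_k (predictions of class k), trace c (correct
calls) and grand total s. Unclassified reads form a predicted-only
pseudo-class: they depress MCC through p_k but can never be correct, so
non-classification is penalized symmetrically with misclassification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .classify import Prediction
from .errors import (
    EmptyMatrixError,
    MissingTruthError,
    NoUnseenReadsError,
)
from .taxonomy import Taxonomy

#: Terminal pseudo-label for reads without a prediction at the rank.
UNCLASSIFIED = "unclassified"


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions.

    The label list always ends with the ``unclassified`` pseudo-label,
    whose row is all zeros (no read is truly unclassified).
    """

    labels: list[object]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise EmptyMatrixError("confusion matrix must be square")
        if c.shape[0] != len(self.labels):
            raise EmptyMatrixError("labels do not match matrix size")
        if (c < 0).any():
            raise EmptyMatrixError("negative counts")
        self.counts = c

    @property
    def t_k(self) -> np.ndarray:
        """True occurrences per class (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def p_k(self) -> np.ndarray:
        """Predictions per class (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def c(self) -> int:
        """Correctly classified reads (trace)."""
        return int(np.trace(self.counts))

    @property
    def s(self) -> int:
        """Total evaluated reads."""
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels,
                            columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="true\\pred")


def confusion_at_rank(
    truth: Mapping[str, int],
    preds: Sequence[Prediction],
    t: Taxonomy,
    rank: str,
    unclassified: str = "count",
) -> ConfusionMatrix:
    """Project truth and predictions to ``rank`` and count the confusion.

    Predictions whose taxon sits above the rank (or which are
    unclassified) land in the ``unclassified`` column. With
    ``unclassified="drop"`` those reads are excluded from the matrix
    entirely instead of forming the pseudo-class.
    """
    if unclassified not in ("count", "drop"):
        raise ValueError("unclassified must be 'count' or 'drop'")
    pairs: list[tuple[object, object]] = []
    for pred in preds:
        if pred.read_id not in truth:
            raise MissingTruthError(f"no ground truth for {pred.read_id!r}")
        true_label = t.project(truth[pred.read_id], rank)
        if true_label is None:
            raise MissingTruthError(
                f"truth taxon for {pred.read_id!r} has no ancestor at {rank}"
            )
        if pred.is_unclassified:
            pred_label = None
        else:
            pred_label = t.project(pred.taxon, rank)
        if pred_label is None:
            if unclassified == "drop":
                continue
            pred_label = UNCLASSIFIED
        pairs.append((true_label, pred_label))
    taxa = sorted(
        {p for p, _ in pairs} | {q for _, q in pairs if q != UNCLASSIFIED}
    )
    labels: list[object] = taxa + [UNCLASSIFIED]
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for true_label, pred_label in pairs:
        counts[idx[true_label], idx[pred_label]] += 1
    return ConfusionMatrix(labels, counts)


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient of a confusion matrix.

    A zero denominator (a degenerate single-class margin) returns 0 by
    convention.
    """
    s = cm.s
    if s == 0:
        raise EmptyMatrixError("confusion matrix holds no counts")
    t_k = cm.t_k.astype(float)
    p_k = cm.p_k.astype(float)
    c = float(cm.c)
    s = float(s)
    num = c * s - float(p_k @ t_k)
    den = math.sqrt(s * s - float(p_k @ p_k)) * math.sqrt(
        s * s - float(t_k @ t_k)
    )
    return num / den if den > 0 else 0.0


def precision_recall(cm: ConfusionMatrix) -> tuple[float, float]:
    """Read-level micro precision and recall.

    precision = correct / classified reads (the unclassified column is
    excluded from the denominator); recall = correct / all reads. Both are
    0 when their denominator is 0, so recall = precision * classified
    fraction holds as an identity.
    """
    s = cm.s
    if s == 0:
        raise EmptyMatrixError("confusion matrix holds no counts")
    unclass_col = cm.labels.index(UNCLASSIFIED) if UNCLASSIFIED in cm.labels else None
    n_unclassified = int(cm.p_k[unclass_col]) if unclass_col is not None else 0
    classified = s - n_unclassified
    correct = cm.c
    precision = correct / classified if classified else 0.0
    recall = correct / s
    return precision, recall


def unseen_fp_rate(
    truth: Mapping[str, int],
    preds: Sequence[Prediction],
    reference_taxa: Mapping[str, Iterable[int]],
    t: Taxonomy,
    rank: str,
) -> float:
    """Species-level false-positive rate on reads from taxa absent at
    ``rank`` in the reference.

    Selects reads whose true taxon, projected to ``rank``, lies outside
    ``reference_taxa[rank]``, and returns the fraction of them that
    nonetheless received a species-level prediction.
    """
    ref = set(reference_taxa[rank])
    if not ref:
        raise NoUnseenReadsError(f"empty reference set at rank {rank}")
    selected = 0
    fp = 0
    for pred in preds:
        if pred.read_id not in truth:
            raise MissingTruthError(f"no ground truth for {pred.read_id!r}")
        true_at_rank = t.project(truth[pred.read_id], rank)
        if true_at_rank is None or true_at_rank in ref:
            continue
        selected += 1
        if not pred.is_unclassified and pred.rank == "species":
            fp += 1
    if selected == 0:
        raise NoUnseenReadsError(
            f"no read has an unseen true taxon at rank {rank}"
        )
    return fp / selected


def rank_report(
    truth: Mapping[str, int],
    preds: Sequence[Prediction],
    t: Taxonomy,
    ranks: Sequence[str] = ("species", "genus", "family", "order",
                            "class", "phylum"),
    unclassified: str = "count",
) -> pd.DataFrame:
    """Per-rank summary table: reads, classified reads, MCC, precision,
    recall and unclassified fraction."""
    rows = []
    for rank in ranks:
        cm = confusion_at_rank(truth, preds, t, rank,
                               unclassified=unclassified)
        prec, rec = precision_recall(cm)
        unclass_col = cm.labels.index(UNCLASSIFIED)
        n_unclassified = int(cm.p_k[unclass_col])
        rows.append({
            "rank": rank,
            "n_reads": cm.s,
            "n_classified": cm.s - n_unclassified,
            "mcc": mcc(cm),
            "precision": prec,
            "recall": rec,
            "unclassified_fraction": (
                n_unclassified / cm.s if cm.s else 0.0
            ),
        })
    return pd.DataFrame(rows)


def write_rank_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
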