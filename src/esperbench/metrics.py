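"""Classification metrics computed from per-case prediction tables.

The five reported metrics are macro AUROC, balanced accuracy, and
macro-averaged precision, recall and F1.  Macro AUROC is one-vs-rest: each
class is scored against the rest with the rank-based (Mann-Whitney) statistic
using midranks, so ties receive half credit and any strictly increasing
transform of the scores leaves the value unchanged; the per-class areas are
then averaged without class weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .records import Metric, PerformanceScore, ValidationError

__all__ = ["PredictionTable", "macro_auroc", "classification_report"]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-6


@dataclass(frozen=True)
class PredictionTable:
    """Per-case true labels and class probabilities for one model.

    ``true_label`` holds integer class indices in [0, K); ``probabilities``
    is an (n_cases, K) array whose rows sum to one within 1e-6.
    """

    case_ids: tuple[str, ...]
    true_label: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.true_label, dtype=int)
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "true_label", y)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 2 or p.shape[1] < 2:
            raise ValidationError("probabilities must be (n_cases, K) with K >= 2")
        if len(self.case_ids) != p.shape[0] or y.shape[0] != p.shape[0]:
            raise ValidationError("case_ids, labels and probabilities disagree in length")
        if p.shape[0] == 0:
            raise ValidationError("prediction table is empty")
        if np.any(p < 0):
            raise ValidationError("probabilities must be >= 0")
        sums = p.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _PROB_TOL)
        if bad.size:
            raise ValidationError(
                f"probabilities of case {self.case_ids[bad[0]]!r} sum to "
                f"{sums[bad[0]]:.8f}, not 1"
            )
        if np.any((y < 0) | (y >= p.shape[1])):
            raise ValidationError("true_label outside [0, K)")

    @property
    def n_cases(self) -> int:
        return self.probabilities.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[1]

    def subset(self, indices: np.ndarray) -> "PredictionTable":
        """Row subset/resample (used by the bootstrap)."""
        idx = np.asarray(indices, dtype=int)
        return PredictionTable(
            tuple(self.case_ids[i] for i in idx),
            self.true_label[idx],
            self.probabilities[idx],
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PredictionTable":
        """Read columns ``case_id, true_label, prob_0 .. prob_{K-1}``."""
        df = pd.read_csv(path)
        prob_cols = sorted(
            (c for c in df.columns if c.startswith("prob_")),
            key=lambda c: int(c.split("_", 1)[1]),
        )
        if not prob_cols:
            raise ValidationError(f"no prob_* columns in {path}")
        return cls(
            tuple(str(c) for c in df["case_id"]),
            df["true_label"].to_numpy(dtype=int),
            df[prob_cols].to_numpy(dtype=float),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"case_id": self.case_ids, "true_label": self.true_label}
        )
        for k in range(self.n_classes):
            df[f"prob_{k}"] = self.probabilities[:, k]
        df.to_csv(path, index=False)


def _binary_auroc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based AUROC with midrank tie handling (Mann-Whitney U / n1*n0)."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = rankdata(scores)  # midranks
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def macro_auroc(preds: PredictionTable) -> PerformanceScore:
    """Unweighted mean of one-vs-rest AUROCs over the classes present.

    Every class that occurs in ``true_label`` must have at least one positive
    and one negative case, otherwise its area is undefined.
    """
    y, p = preds.true_label, preds.probabilities
    present = np.unique(y)
    if np.unique(y).size < 2:
        raise ValidationError(
            f"AUROC undefined: only class {present[0]} present in labels"
        )
    aucs = []
    for k in present:
        positive = y == k
        if positive.all() or not positive.any():
            raise ValidationError(
                f"class {k} has no positives or no negatives; AUROC undefined"
            )
        aucs.append(_binary_auroc(p[:, k], positive))
    return PerformanceScore(Metric.AUROC, float(np.mean(aucs)))


def confusion_matrix(preds: PredictionTable) -> np.ndarray:
    """K x K matrix, rows = true class, columns = argmax-predicted class.

    Argmax ties resolve to the lowest class index.
    """
    y_pred = np.argmax(preds.probabilities, axis=1)
    k = preds.n_classes
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (preds.true_label, y_pred), 1)
    return cm


def classification_report(preds: PredictionTable) -> dict[Metric, PerformanceScore]:
    """Balanced accuracy plus macro precision/recall/F1 from argmax decisions.

    Balanced accuracy averages per-class recall over classes that actually
    occur.  Macro precision/recall/F1 average over the same classes; a class
    that is never predicted contributes precision 0 (logged as a warning).
    """
    cm = confusion_matrix(preds)
    present = np.flatnonzero(cm.sum(axis=1) > 0)
    tp = np.diag(cm).astype(float)
    true_counts = cm.sum(axis=1).astype(float)
    pred_counts = cm.sum(axis=0).astype(float)

    recalls = tp[present] / true_counts[present]
    precisions = np.zeros(present.size)
    for j, k in enumerate(present):
        if pred_counts[k] == 0:
            logger.warning(
                "class %d never predicted; its precision is reported as 0", k
            )
            precisions[j] = 0.0
        else:
            precisions[j] = tp[k] / pred_counts[k]
    denom = precisions + recalls
    f1 = np.where(denom > 0, 2 * precisions * recalls / np.where(denom > 0, denom, 1), 0.0)

    return {
        Metric.BALANCED_ACCURACY: PerformanceScore(
            Metric.BALANCED_ACCURACY, float(recalls.mean())
        ),
        Metric.PRECISION: PerformanceScore(Metric.PRECISION, float(precisions.mean())),
        Metric.RECALL: PerformanceScore(Metric.RECALL, float(recalls.mean())),
        Metric.F1: PerformanceScore(Metric.F1, float(f1.mean())),
    }


def all_metrics(preds: PredictionTable) -> dict[Metric, PerformanceScore]:
    """AUROC plus the argmax-based report, keyed by metric."""
    out = {Metric.AUROC: macro_auroc(preds)}
    out.update(classification_report(preds))
    return out
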