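"""Classification and regression metrics for depression assessment.

Classification metrics are confusion-matrix based: accuracy, precision,
recall, F1 and Cohen's kappa. One convention deserves emphasis: in this
screening setting the *positive* class defaults to "normal" (healthy
control, label 0) — a true positive is a control correctly identified as a
control. Pass ``positive_label=1`` for the clinical convention (positive =
depressed).

Regression metrics (MSE, RMSE, MAE, MEDAE) are always reported on the
original PHQ-9 scale (0-27), after any label denormalization:

    MSE   = (1/n) sum (y_i - yhat_i)^2
    RMSE  = sqrt(MSE)
    MAE   = (1/n) sum |y_i - yhat_i|
    MEDAE = median(|y_i - yhat_i|)

MEDAE is robust to outlier trials; MAE <= RMSE always (Jensen), while
MEDAE can exceed or undercut MAE depending on the error distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import SubjectRecord

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "classification_metrics",
    "kappa",
    "regression_metrics",
    "subject_level_report",
]

logger = logging.getLogger(__name__)


class ContractError(ValueError):
    pass


class UndefinedKappaError(ValueError):
    """Chance agreement is 1 (both sides constant): kappa is undefined."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts under a chosen positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ContractError("confusion counts must be non-negative")
        if self.total < 1:
            raise ContractError("confusion counts must cover at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def swapped(self) -> "ConfusionCounts":
        """The same predictions with the opposite positive class."""
        return ConfusionCounts(tp=self.tn, fn=self.fp, tn=self.tp, fp=self.fn)


@dataclass
class MetricReport:
    """All classification and/or regression scores of one evaluation."""

    accuracy: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    kappa: Optional[float] = None
    mse: Optional[float] = None
    rmse: Optional[float] = None
    mae: Optional[float] = None
    medae: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, float]:
        return {k: v for k, v in self.__dict__.items()
                if k != "flags" and v is not None}


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int],
                     positive_label: int = 0) -> ConfusionCounts:
    """Tally binary confusion counts.

    ``positive_label`` names the class counted as positive; the default (0,
    the healthy controls) matches the screening convention used throughout
    this package.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size < 1:
        raise ContractError(f"label vectors must be equal-length 1-D, got {yt.shape} vs {yp.shape}")
    labels = set(np.unique(yt)) | set(np.unique(yp))
    if not labels <= {0, 1}:
        raise ContractError(f"labels must be binary 0/1, found {sorted(labels)}")
    pos = positive_label
    return ConfusionCounts(
        tp=int(np.sum((yt == pos) & (yp == pos))),
        fn=int(np.sum((yt == pos) & (yp != pos))),
        tn=int(np.sum((yt != pos) & (yp != pos))),
        fp=int(np.sum((yt != pos) & (yp == pos))),
    )


def _safe_div(num: float, den: float, name: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(name)
        logger.warning("%s has zero denominator; reporting flagged 0", name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, precision, recall and F1 from confusion counts.

    Degenerate denominators yield a flagged 0 (listed in ``report.flags``)
    rather than an exception, so pooled cross-validation reports never
    abort on a pathological fold.
    """
    flags: List[str] = []
    acc = (c.tp + c.tn) / c.total
    prec = _safe_div(c.tp, c.tp + c.fp, "precision", flags)
    rec = _safe_div(c.tp, c.tp + c.fn, "recall", flags)
    f1 = _safe_div(2 * prec * rec, prec + rec, "f1", flags)
    return MetricReport(accuracy=acc, precision=prec, recall=rec, f1=f1, flags=flags)


def kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa: agreement beyond chance.

    ``kappa = (P_a - P_e) / (1 - P_e)`` where ``P_a`` is the observed
    agreement (= accuracy) and ``P_e`` the chance agreement implied by the
    marginal class frequencies of truth and prediction.
    """
    n = c.total
    pa = (c.tp + c.tn) / n
    pe = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / n ** 2
    if pe == 1.0:
        raise UndefinedKappaError(
            "chance agreement is 1 (both label vectors constant); kappa undefined"
        )
    return (pa - pe) / (1 - pe)


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> MetricReport:
    """MSE, RMSE, MAE and MEDAE on the (denormalized) PHQ-9 scale."""
    yt = np.asarray(y_true, dtype=np.float64)
    yp = np.asarray(y_pred, dtype=np.float64)
    if yt.shape != yp.shape or yt.ndim != 1 or yt.size < 1:
        raise ContractError(f"equal-length 1-D vectors required, got {yt.shape} vs {yp.shape}")
    err = yt - yp
    mse = float(np.mean(err ** 2))
    return MetricReport(
        mse=mse,
        rmse=math.sqrt(mse),
        mae=float(np.mean(np.abs(err))),
        medae=float(np.median(np.abs(err))),
    )


def subject_level_report(folds: Iterable, records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-subject regression errors from leave-one-subject-out folds.

    Each row compares one held-out subject's trial predictions against that
    subject's single true PHQ-9 score. ``folds`` is an iterable of objects
    with ``held_out_subject``, ``trial_predictions`` and ``trial_truth``
    attributes.
    """
    by_id = {r.subject_id: r for r in records}
    rows = []
    for fold in folds:
        sid = fold.held_out_subject
        if sid not in by_id:
            raise ContractError(f"fold subject {sid} missing from the metadata records")
        rec = by_id[sid]
        preds = np.asarray(fold.trial_predictions, dtype=np.float64)
        truth = np.full_like(preds, float(rec.phq9))
        m = regression_metrics(truth, preds)
        rows.append({
            "subject_id": sid, "group": rec.group.value, "phq9": rec.phq9,
            "n_trials": preds.size, "mean_prediction": float(preds.mean()),
            "rmse": m.rmse, "mae": m.mae, "medae": m.medae,
        })
    return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
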