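"""Label normalization, cue-triplet pairing, optimization and LOSOCV.

Regression targets (PHQ-9 scores, 0-27) are min-max normalized to [0, 1]
before training — ``y* = (y - ymin) / (ymax - ymin)`` — and predictions are
mapped back with the inverse affine transform at inference. Two fitting
strategies exist: ``train_minmax`` takes (ymin, ymax) from the *training*
subjects' score distribution (fitted per cross-validation fold, so held-out
labels never influence the mapping) and ``scale_bounds`` uses the fixed
questionnaire range (0, 27).

Leave-one-subject-out cross-validation (LOSOCV) holds out every trial of
exactly one subject per fold. The split is by subject, never by trial, so
the model cannot shortcut through subject identity; the validation set used
for early stopping is carved from the training subjects' trials only.

Optimization: Adam, mini-batches, at most ``epochs`` epochs; the weights
retained are those of the epoch with the lowest validation loss, and
training stops early once validation loss has not improved for ``patience``
consecutive epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _nn
from .data_io import (CueTripletBatch, EpochSet, SubjectRecord, ValidationError,
                      concatenate_triplets)
from .evaluation import (MetricReport, classification_metrics, confusion_counts,
                         kappa, regression_metrics, subject_level_report)
from .model import MCEEGNet, MCEEGNetConfig, BranchConfig, build_model

__all__ = [
    "NormalizationParams",
    "TrainConfig",
    "FoldResult",
    "LOSOCVResult",
    "SubjectDataset",
    "fit_label_normalizer",
    "normalize_labels",
    "denormalize_predictions",
    "make_cue_triplets",
    "train_model",
    "run_losocv",
]

logger = logging.getLogger(__name__)


class ContractError(ValueError):
    pass


class DegenerateRangeError(ValueError):
    """All training scores identical; min-max normalization is undefined."""


class DegenerateFoldError(ValueError):
    """A fold's training set lacks one of the classes."""


@dataclass(frozen=True)
class NormalizationParams:
    """The (ymin, ymax) pair of the affine label map, on the PHQ-9 scale."""

    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not self.ymax > self.ymin:
            raise ContractError(f"ymax ({self.ymax}) must exceed ymin ({self.ymin})")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    val_fraction: float = 0.10
    seed: int = 0
    loss: str = "cross_entropy"   # cross_entropy | mse
    patience: Optional[int] = 5   # epochs without val improvement; None = run all

    def validate(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ContractError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.epochs < 1:
            raise ContractError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ContractError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss not in ("cross_entropy", "mse", "joint"):
            raise ContractError(f"unsupported loss {self.loss!r}")


@dataclass
class FoldResult:
    held_out_subject: int
    trial_predictions: np.ndarray
    trial_truth: np.ndarray
    history: Dict[str, List[float]]
    train_subjects: Tuple[int, ...] = ()
    normalizer: Optional[NormalizationParams] = None


@dataclass
class LOSOCVResult:
    folds: List[FoldResult]
    pooled: MetricReport
    per_subject: pd.DataFrame
    task: str
    subject_accuracy: Optional[float] = None  # majority-vote aggregation


@dataclass
class SubjectDataset:
    """Per-subject cue-triplet batches plus the metadata records."""

    records: List[SubjectRecord]
    batches: Dict[int, CueTripletBatch]

    def __post_init__(self) -> None:
        ids = {r.subject_id for r in self.records}
        if set(self.batches) != ids:
            raise ValidationError("records and batches cover different subject ids")

    @property
    def subject_ids(self) -> List[int]:
        return [r.subject_id for r in self.records]


# ---------------------------------------------------------------------------
# Label normalization
# ---------------------------------------------------------------------------

def fit_label_normalizer(train_records: Sequence[SubjectRecord],
                         strategy: str = "train_minmax") -> NormalizationParams:
    """Fit the (ymin, ymax) of the label map from training subjects only."""
    if strategy == "scale_bounds":
        return NormalizationParams(0.0, 27.0)
    if strategy != "train_minmax":
        raise ContractError(f"unknown normalizer strategy {strategy!r}")
    scores = [r.phq9 for r in train_records]
    if len(set(scores)) < 2:
        raise DegenerateRangeError(
            "all training scores identical; min-max undefined — "
            "use strategy='scale_bounds' for the fixed (0, 27) range"
        )
    return NormalizationParams(float(min(scores)), float(max(scores)))


def normalize_labels(y, p: NormalizationParams) -> np.ndarray:
    """Affine map to normalized space: ymin -> 0, ymax -> 1."""
    y = np.asarray(y, dtype=np.float64)
    out = (y - p.ymin) / (p.ymax - p.ymin)
    if np.any((out < 0) | (out > 1)):
        logger.warning("labels outside [ymin, ymax] map outside [0, 1]")
    return out


def denormalize_predictions(y_star, p: NormalizationParams) -> np.ndarray:
    """Inverse map back to the PHQ-9 scale: exact inverse of normalization."""
    return np.asarray(y_star, dtype=np.float64) * (p.ymax - p.ymin) + p.ymin


# ---------------------------------------------------------------------------
# Cue-triplet pairing
# ---------------------------------------------------------------------------

def make_cue_triplets(hcue: EpochSet, fcue: EpochSet, scue: EpochSet,
                      policy: str = "by_index", seed: int = 0,
                      record: Optional[SubjectRecord] = None) -> CueTripletBatch:
    """Pair per-cue trials into (happy, fear, sad) model-input triplets.

    ``by_index`` pairs the i-th trial of each cue; ``shuffled`` permutes the
    trials within each cue (under ``seed``) before pairing. The triplet
    count is the minimum per-cue trial count; excess trials are dropped.
    Labels are filled from ``record`` when given, else NaN.
    """
    trip = {"hcue": hcue, "fcue": fcue, "scue": scue}
    for name, es in trip.items():
        if es.cue.value != name:
            raise ValidationError(f"argument {name} carries cue {es.cue.value!r}")
        if es.n_trials == 0:
            raise ValidationError(f"{name} epoch set is empty")
    sids = {es.subject_id for es in trip.values()}
    if len(sids) != 1:
        raise ValidationError(f"epoch sets come from different subjects: {sorted(sids)}")
    sid = sids.pop()
    n = min(es.n_trials for es in trip.values())
    dropped = sum(es.n_trials for es in trip.values()) - 3 * n
    if dropped:
        logger.info("subject %d: dropped %d excess trials when pairing", sid, dropped)
    if policy == "by_index":
        idx = {k: np.arange(n) for k in trip}
    elif policy == "shuffled":
        rng = np.random.default_rng(seed)
        idx = {k: rng.permutation(es.n_trials)[:n] for k, es in trip.items()}
    else:
        raise ContractError(f"unknown pairing policy {policy!r}")
    if record is not None and record.subject_id != sid:
        raise ValidationError("record subject id does not match the epoch sets")
    label = record.label if record is not None else -1
    score = float(record.phq9) if record is not None else float("nan")
    return CueTripletBatch(
        x_happy=hcue.data[idx["hcue"]],
        x_fear=fcue.data[idx["fcue"]],
        x_sad=scue.data[idx["scue"]],
        labels_class=np.full(n, label, dtype=np.int64),
        labels_score=np.full(n, score, dtype=np.float64),
        subject_ids=np.full(n, sid, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def _split_validation(batch: CueTripletBatch, cfg: TrainConfig, stratify: bool,
                      rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    n = batch.n
    n_val = int(round(n * cfg.val_fraction))
    if n_val < 1 or n - n_val < 1:
        raise ContractError(
            f"validation split of {n} samples at fraction {cfg.val_fraction} "
            "leaves an empty set"
        )
    if stratify:
        val_idx: List[int] = []
        for cls in np.unique(batch.labels_class):
            members = np.flatnonzero(batch.labels_class == cls)
            k = max(1, int(round(members.size * cfg.val_fraction)))
            val_idx.extend(rng.permutation(members)[:k])
        val = np.sort(np.asarray(val_idx))
    else:
        val = np.sort(rng.permutation(n)[:n_val])
    train = np.setdiff1d(np.arange(n), val)
    return train, val


def _batch_loss(model: MCEEGNet, batch: CueTripletBatch, loss: str,
                train_mode: bool) -> Tuple[float, Optional[np.ndarray], Optional[np.ndarray]]:
    out = model.forward(batch, train_mode=train_mode)
    if loss == "cross_entropy":
        l, dlog = _nn.cross_entropy(out["class_probs"].astype(np.float64),
                                    batch.labels_class.astype(np.int64))
        return l, dlog, None
    if loss == "mse":
        l, dsc = _nn.mse_loss(out["scores"].astype(np.float64),
                              batch.labels_score.astype(np.float64))
        return l, None, dsc
    # joint: unweighted sum of the two head losses
    lc, dlog = _nn.cross_entropy(out["class_probs"].astype(np.float64),
                                 batch.labels_class.astype(np.int64))
    lr, dsc = _nn.mse_loss(out["scores"].astype(np.float64),
                           batch.labels_score.astype(np.float64))
    return lc + lr, dlog, dsc


def _eval_loss(model: MCEEGNet, batch: CueTripletBatch, loss: str,
               chunk: int = 256) -> float:
    total, n = 0.0, batch.n
    for a in range(0, n, chunk):
        sub = batch.subset(np.arange(a, min(a + chunk, n)))
        l, _, _ = _batch_loss(model, sub, loss, train_mode=False)
        total += l * sub.n
    return total / n


def train_model(model: MCEEGNet, train: CueTripletBatch, cfg: TrainConfig,
                ) -> Tuple[MCEEGNet, Dict[str, List[float]]]:
    """Mini-batch Adam training with best-validation-weight retention.

    Runs at most ``cfg.epochs`` epochs (fewer if validation loss plateaus
    for ``cfg.patience`` epochs) and restores the weights of the epoch with
    the minimum validation loss before returning. Fully deterministic under
    a fixed seed on one device.
    """
    cfg.validate()
    if train.n < 2:
        raise ContractError("need at least 2 training samples")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x7261)))
    stratify = cfg.loss != "mse"
    tr_idx, val_idx = _split_validation(train, cfg, stratify, rng)
    tr, val = train.subset(tr_idx), train.subset(val_idx)
    opt = _nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}
    best_loss, best_state, since_best = np.inf, model.state(), 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr.n)
        ep_loss, n_seen = 0.0, 0
        for a in range(0, tr.n, cfg.batch_size):
            mb = tr.subset(order[a:a + cfg.batch_size])
            l, dlog, dsc = _batch_loss(model, mb, cfg.loss, train_mode=True)
            opt.zero_grad()
            model.backward(dlogits=dlog, dscores=dsc)
            opt.step()
            ep_loss += l * mb.n
            n_seen += mb.n
        val_loss = _eval_loss(model, val, cfg.loss)
        history["train_loss"].append(ep_loss / n_seen)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss, best_state, since_best = val_loss, model.state(), 0
        else:
            since_best += 1
            if cfg.patience is not None and since_best >= cfg.patience:
                logger.info("early stop at epoch %d (no val improvement for %d epochs)",
                            epoch + 1, cfg.patience)
                break
    model.load_state(best_state)
    return model, history


# ---------------------------------------------------------------------------
# Leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------

def _fold_seed(base_seed: int, fold_index: int) -> int:
    return int(np.random.SeedSequence((base_seed, fold_index)).generate_state(1)[0] % (2 ** 31))


def run_losocv(dataset: SubjectDataset, cfg: TrainConfig,
               task: str = "classify",
               model_cfg: Optional[MCEEGNetConfig] = None,
               normalizer_strategy: str = "train_minmax") -> LOSOCVResult:
    """One fold per subject: train on the rest, predict the held-out trials.

    For regression the label normalizer is fitted on each fold's training
    subjects only, and held-out predictions are mapped back to the PHQ-9
    scale before pooling. Returns pooled trial-level metrics, a per-subject
    table, and (classification) a majority-vote subject-level accuracy.
    """
    cfg.validate()
    if task not in ("classify", "regress"):
        raise ContractError(f"unknown task {task!r}")
    ids = dataset.subject_ids
    if len(ids) < 3:
        raise ContractError("LOSOCV needs at least 3 subjects")
    by_id = {r.subject_id: r for r in dataset.records}
    if task == "classify" and len({r.group for r in dataset.records}) < 2:
        raise DegenerateFoldError("classification needs both groups in the cohort")

    if model_cfg is None:
        any_batch = next(iter(dataset.batches.values()))
        _, C, T = any_batch.x_happy.shape
        model_cfg = MCEEGNetConfig(branch=BranchConfig(n_channels=C, n_samples=T),
                                   mode=task)
    elif model_cfg.mode != "joint" and model_cfg.mode != task:
        model_cfg = replace(model_cfg, mode=task)
    folds: List[FoldResult] = []
    for k, held in enumerate(ids):
        train_ids = [s for s in ids if s != held]
        train_recs = [by_id[s] for s in train_ids]
        if task == "classify" and len({r.group for r in train_recs}) < 2:
            raise DegenerateFoldError(f"fold holding out subject {held}: "
                                      "training set lacks a class")
        train_batch = concatenate_triplets([dataset.batches[s] for s in train_ids])
        assert held not in set(train_batch.subject_ids), "subject leakage into training"
        norm = None
        if task == "regress":
            norm = fit_label_normalizer(train_recs, normalizer_strategy)
            train_batch = replace(
                train_batch,
                labels_score=normalize_labels(train_batch.labels_score, norm),
            )
        fold_cfg = replace(cfg,
                           seed=_fold_seed(cfg.seed, k),
                           loss="cross_entropy" if task == "classify" else "mse")
        model = build_model(model_cfg, seed=_fold_seed(cfg.seed, 10_000 + k))
        model, history = train_model(model, train_batch, fold_cfg)
        held_batch = dataset.batches[held]
        out = model.forward(held_batch, train_mode=False)
        if task == "classify":
            preds = np.argmax(out["class_probs"], axis=1)
            truth = held_batch.labels_class
        else:
            preds = denormalize_predictions(out["scores"], norm)
            truth = held_batch.labels_score
        logger.info("fold %d/%d (subject %d): %d held-out trials, %d epochs",
                    k + 1, len(ids), held, held_batch.n, len(history["val_loss"]))
        folds.append(FoldResult(held, np.asarray(preds), np.asarray(truth),
                                history, tuple(train_ids), norm))

    all_pred = np.concatenate([f.trial_predictions for f in folds])
    all_true = np.concatenate([f.trial_truth for f in folds])
    subject_acc = None
    if task == "classify":
        counts = confusion_counts(all_true.astype(int), all_pred.astype(int))
        pooled = classification_metrics(counts)
        pooled.kappa = kappa(counts)
        votes = [(by_id[f.held_out_subject].label,
                  int(np.round(f.trial_predictions.mean())))
                 for f in folds]
        subject_acc = float(np.mean([t == p for t, p in votes]))
        per_subject = pd.DataFrame({
            "subject_id": [f.held_out_subject for f in folds],
            "group": [by_id[f.held_out_subject].group.value for f in folds],
            "trial_accuracy": [float(np.mean(f.trial_predictions == f.trial_truth))
                               for f in folds],
        })
    else:
        pooled = regression_metrics(all_true, all_pred)
        per_subject = subject_level_report(folds, dataset.records)
    return LOSOCVResult(folds=folds, pooled=pooled, per_subject=per_subject,
                        task=task, subject_accuracy=subject_acc)
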