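"""Training loop and evaluation metrics.

Training minimizes the root-mean-square error between predicted and measured
solubility with Adam on the hand-derived gradients of :mod:`solugat.gat`.
Evaluation reports the regression coefficient of determination R^2 and, after
binarizing both predictions and labels at a 0.5 solubility threshold, the
standard classification metrics (accuracy, precision, recall, F1, AUC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .gat import (GATModelConfig, GATParams, backward_batch, forward_batch,
                  init_params)

logger = logging.getLogger(__name__)

SOLUBLE_THRESHOLD = 0.5


@dataclass
class SolubilityRecord:
    """One labeled protein: graph + node features + solubility in [0, 1]."""

    id: str
    sequence: str
    graph: object = None        # ProteinGraph or adjacency array
    features: object = None     # L x F ndarray
    solubility: float = float("nan")

    def __post_init__(self) -> None:
        s = float(self.solubility)
        if not math.isfinite(s):
            raise ValueError(f"record {self.id}: solubility is not finite")
        if not (0.0 <= s <= 1.0):
            logger.warning("record %s: solubility %.3f outside [0, 1]",
                           self.id, s)


@dataclass
class TrainConfig:
    """Optimization settings.

    The tuned full-scale defaults are learning rate 2e-6 with batch size 4;
    ``target_train_rmse`` allows an early exit once the training loss falls
    below a requested level (useful for capacity checks).
    """

    learning_rate: float = 2e-6
    batch_size: int = 4
    epochs: int = 300
    seed: int = 0
    optimizer: str = "adam"
    patience: int = 30
    weight_decay: float = 0.0
    lr_schedule: str = "constant"   # or "cosine" (decays to ~0 by the last epoch)
    target_train_rmse: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


@dataclass
class EvalReport:
    r2: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    n: int
    threshold: float = SOLUBLE_THRESHOLD
    precision_defined: bool = True
    recall_defined: bool = True

    def as_dict(self) -> dict:
        return {"r2": self.r2, "accuracy": self.accuracy,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "auc": self.auc, "n": self.n,
                "threshold": self.threshold}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse_loss(pred, truth) -> float:
    """Root-mean-square error."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.size < 1:
        raise ValueError(
            f"prediction and truth lengths differ ({pred.shape} vs {truth.shape})"
        )
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def evaluate_regression(pred, truth) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot.

    This is the model-selection form that penalizes biased predictors (it can
    be negative), not squared Pearson correlation.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if truth.size < 2:
        raise ValueError("R^2 needs at least two observations")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant truth")
    ss_res = float(np.sum((truth - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def classification_metrics(pred, truth,
                           threshold: float = SOLUBLE_THRESHOLD) -> EvalReport:
    """Binarize both vectors at ``threshold`` (>= threshold -> soluble) and
    evaluate Accuracy, Precision, Recall and F1 from the confusion counts.

    Undefined ratios (no predicted positives for precision, no true positives
    in the truth for recall) are reported as NaN with the matching
    ``*_defined`` flag cleared; F1 follows suit.  AUC is left NaN here (it
    needs continuous scores; see :func:`auc_score`).
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.size < 1:
        raise ValueError("prediction and truth lengths differ")
    p = pred >= threshold
    t = truth >= threshold
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    precision_defined = (tp + fp) > 0
    recall_defined = (tp + fn) > 0
    if not precision_defined:
        logger.warning("precision undefined: no predicted positives")
    precision = tp / (tp + fp) if precision_defined else float("nan")
    recall = tp / (tp + fn) if recall_defined else 0.0
    if precision_defined and recall_defined and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision_defined and recall_defined:
        f1 = 0.0
    else:
        f1 = float("nan")
    return EvalReport(r2=float("nan"), accuracy=accuracy, precision=precision,
                      recall=recall, f1=f1, auc=float("nan"), n=pred.size,
                      threshold=threshold, precision_defined=precision_defined,
                      recall_defined=recall_defined)


def auc_score(scores, labels, threshold: float = SOLUBLE_THRESHOLD) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2.

    ``labels`` may be continuous (binarized at ``threshold``) or already 0/1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    binary = labels >= threshold
    if binary.all() or not binary.any():
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(binary.astype(int), scores))


def evaluate(pred, truth, threshold: float = SOLUBLE_THRESHOLD) -> EvalReport:
    """Full report: R^2 plus thresholded classification metrics and AUC."""
    report = classification_metrics(pred, truth, threshold)
    report.r2 = evaluate_regression(pred, truth)
    binary = np.asarray(truth, dtype=np.float64) >= threshold
    if binary.any() and not binary.all():
        report.auc = auc_score(pred, truth, threshold)
    return report


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

def kfold_split(records, k: int = 5, seed: int = 0):
    """Shuffle records into k folds whose sizes differ by at most one.

    Deterministic given the seed; every record lands in exactly one fold.
    """
    records = list(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [[records[i] for i in test_idx]
            for _, test_idx in splitter.split(records)]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _Adam:
    """Adam with decoupled weight decay (decay skips the readout bias)."""

    def __init__(self, shapes: dict, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, values: dict, grads: dict, lr: float | None = None) -> dict:
        if lr is not None:
            self.lr = lr
        self.t += 1
        out = {}
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            new = values[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and k != "mlp/b":
                new = new - self.lr * self.wd * values[k]
            out[k] = new
        return out


def _write_back(params: GATParams, values: dict) -> None:
    for l, layer in enumerate(params.layers):
        layer.W = values[f"layer{l}/W"]
        layer.a_src = values[f"layer{l}/a_src"]
        layer.a_dst = values[f"layer{l}/a_dst"]
    params.w_mlp = values["mlp/w"]
    params.b_mlp = values["mlp/b"]


def predict(records, params: GATParams, config: GATModelConfig) -> np.ndarray:
    """Model predictions for a list of records (or (graph, H) pairs)."""
    batch = [_as_pair(r) for r in records]
    S, _, _ = forward_batch(batch, params, config)
    return S


def _as_pair(record):
    if isinstance(record, SolubilityRecord):
        return (record.graph, record.features)
    return record


def train(records, model_config: GATModelConfig, train_config: TrainConfig,
          val_records=None, params: GATParams | None = None):
    """Train by mini-batch Adam on the RMSE loss.

    Returns ``(params, history)`` where ``history`` maps ``train_rmse`` (and
    ``val_rmse`` when a validation set is given) to per-epoch values.  The
    best-so-far validation loss is tracked; training stops early after
    ``patience`` epochs without improvement (best parameters are returned),
    or once ``target_train_rmse`` is reached.  Single-threaded runs with the
    same seed and config reproduce the history exactly.
    """
    records = list(records)
    if not records:
        raise ValueError("no training records")
    widths = {np.asarray(r.features).shape[1] for r in records}
    if len(widths) != 1:
        raise ValueError(f"inconsistent feature widths in dataset: {widths}")
    if params is None:
        params = init_params(model_config, seed=train_config.seed)
    history: dict[str, list[float]] = {"train_rmse": []}
    if val_records is not None:
        history["val_rmse"] = []
    if train_config.epochs == 0:
        return params, history

    values = params.as_dict()
    opt = _Adam({k: v.shape for k, v in values.items()},
                lr=train_config.learning_rate,
                weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    y_all = np.array([float(r.solubility) for r in records])
    pairs = [_as_pair(r) for r in records]

    best_val = math.inf
    best_params = None
    stall = 0
    for epoch in range(train_config.epochs):
        if train_config.lr_schedule == "cosine":
            frac = epoch / max(1, train_config.epochs)
            lr_epoch = train_config.learning_rate * 0.5 * (
                1.0 + math.cos(math.pi * frac))
        else:
            lr_epoch = train_config.learning_rate
        order = rng.permutation(len(records))
        for start in range(0, len(records), train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            batch = [pairs[i] for i in idx]
            y = y_all[idx]
            S, cache, _ = forward_batch(batch, params, model_config,
                                        want_cache=True)
            resid = S - y
            rmse = float(np.sqrt(np.mean(resid ** 2)))
            if not math.isfinite(rmse):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; aborting"
                )
            if rmse > 1e-12:
                dS = resid / (len(idx) * rmse)
                grads = backward_batch(cache, dS)
                values = opt.step(values, grads, lr=lr_epoch)
                _write_back(params, values)
        train_rmse = rmse_loss(predict(pairs, params, model_config), y_all)
        history["train_rmse"].append(train_rmse)
        if val_records is not None:
            y_val = np.array([float(r.solubility) for r in val_records])
            val_rmse = rmse_loss(predict(val_records, params, model_config),
                                 y_val)
            history["val_rmse"].append(val_rmse)
            if val_rmse < best_val - 1e-12:
                best_val = val_rmse
                best_params = params.copy()
                stall = 0
            else:
                stall += 1
                if stall >= train_config.patience:
                    logger.info("early stop at epoch %d (best val RMSE %.4f)",
                                epoch, best_val)
                    return best_params, history
        if (train_config.target_train_rmse is not None
                and train_rmse < train_config.target_train_rmse):
            logger.info("target train RMSE reached at epoch %d", epoch)
            break
    if val_records is not None and best_params is not None:
        return best_params, history
    return params, history


def grid_search(records, model_config: GATModelConfig,
                train_config: TrainConfig, grid: dict,
                k: int = 5, seed: int = 0):
    """Reduced-scale hyperparameter search by k-fold cross-validation.

    ``grid`` maps parameter names (fields of either config, e.g.
    ``hidden_channels`` or ``learning_rate``) to candidate lists; the full
    Cartesian product is evaluated and results are returned sorted by mean
    CV R^2, best first.
    """
    from dataclasses import replace
    from itertools import product

    names = list(grid)
    results = []
    for combo in product(*(grid[n] for n in names)):
        setting = dict(zip(names, combo))
        mc = replace(model_config, **{k_: v for k_, v in setting.items()
                                      if hasattr(model_config, k_)})
        tc = replace(train_config, **{k_: v for k_, v in setting.items()
                                      if hasattr(train_config, k_)})
        _, mean_r2 = cross_validate(records, mc, tc, k=k, seed=seed)
        results.append({"params": setting, "mean_r2": mean_r2})
    return sorted(results, key=lambda r: -r["mean_r2"])


def cross_validate(records, model_config: GATModelConfig,
                   train_config: TrainConfig, k: int = 5, seed: int = 0):
    """k-fold cross-validation; returns per-fold EvalReports and mean R^2."""
    folds = kfold_split(records, k=k, seed=seed)
    reports = []
    for i, fold in enumerate(folds):
        fold_ids = {id(r) for r in fold}
        train_set = [r for r in records if id(r) not in fold_ids]
        params, _ = train(train_set, model_config, train_config)
        pred = predict(fold, params, model_config)
        truth = np.array([float(r.solubility) for r in fold])
        reports.append(evaluate(pred, truth))
    mean_r2 = float(np.mean([r.r2 for r in reports]))
    return reports, mean_r2
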