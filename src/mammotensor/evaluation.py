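"""Evaluation protocol: confusion matrices, accuracy/macro-F1, and
confidence intervals over repeated experiment runs.

Each experiment is repeated (10 times by default) with derived seeds; every
repetition re-draws the tensor sample from the extracted patches, re-splits
30/70, trains afresh and is scored on its held-out set. Aggregates are
reported as mean +/- a Student-t 95% confidence half-width over repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .rankr_fnn import (
    ModelDims,
    RankRFNNParams,
    TrainConfig,
    TrainingHistory,
    fit_arrays,
    predict,
)
from .sampling import sample_by_class, split_dataset, stack_samples, tensorize_patch

__all__ = [
    "RepetitionResult",
    "ExperimentReport",
    "confusion_matrix",
    "confusion_matrix_labels",
    "scores",
    "aggregate_repetitions",
    "run_repetitions",
]

logger = logging.getLogger(__name__)


def confusion_matrix_labels(
    truth: np.ndarray, pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """Confusion matrix from integer class labels (rows = truth)."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction lengths differ")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (truth, pred), 1)
    return cm


def confusion_matrix(
    truth: Sequence[np.ndarray], predictions: Sequence[np.ndarray], C: int
) -> np.ndarray:
    """Confusion matrix from one-hot vectors; entry (r, c) counts samples
    with true class r predicted as c."""
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if truth.shape != predictions.shape:
        raise ValueError("truth and prediction shapes differ")
    if truth.ndim != 2 or truth.shape[1] != C:
        raise ValueError(f"expected one-hot vectors of length {C}")
    for name, arr in (("truth", truth), ("predictions", predictions)):
        if not ((arr.sum(axis=1) == 1).all() and np.isin(arr, (0, 1)).all()):
            raise ValueError(f"{name} entries must be one-hot")
    return confusion_matrix_labels(truth.argmax(axis=1), predictions.argmax(axis=1), C)


def scores(confusion: np.ndarray) -> tuple[float, float]:
    """(accuracy, macro F1) from a confusion matrix.

    accuracy = trace / total. Per-class F1 = 2PR / (P + R), defined as 0
    for a class with no predictions and no true positives; macro F1 is the
    unweighted class mean. A micro-averaged F1 (equal to accuracy in
    single-label classification) is available via ``average='micro'``.
    """
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = float(np.trace(cm) / total)
    tp = np.diag(cm)
    denom = cm.sum(axis=0) + cm.sum(axis=1)  # per-class 2TP + FP + FN
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * tp / denom, 0.0)
    return accuracy, float(f1.mean())


@dataclass
class RepetitionResult:
    accuracy: float
    f1: float
    confusion: np.ndarray
    history: TrainingHistory | None = None
    params: RankRFNNParams | None = None
    seed: int = 0


@dataclass
class ExperimentReport:
    """Per-repetition metrics plus Student-t aggregate summaries."""

    per_repetition: list[RepetitionResult]
    aggregate: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def aggregate_repetitions(
    reports: Sequence[RepetitionResult] | Sequence[float], confidence: float = 0.95
) -> dict[str, float]:
    """Mean and confidence half-width of accuracy and F1 over repetitions.

    The interval is mean +/- t_{1-(1-confidence)/2, n-1} * sd / sqrt(n)
    computed on the per-repetition values; means are also reported clipped
    to [0, 1] bounds implicitly (metrics already live there). Requires at
    least two repetitions.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 repetitions to form an interval")

    def halfwidth(vals: np.ndarray) -> float:
        sd = vals.std(ddof=1)
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, len(vals) - 1)
        return float(tcrit * sd / np.sqrt(len(vals)))

    if isinstance(reports[0], RepetitionResult):
        acc = np.array([r.accuracy for r in reports])
        f1 = np.array([r.f1 for r in reports])
    else:
        acc = np.asarray(reports, dtype=np.float64)
        f1 = acc
    return {
        "mean_accuracy": float(acc.mean()),
        "accuracy_ci95": halfwidth(acc),
        "mean_f1": float(f1.mean()),
        "f1_ci95": halfwidth(f1),
        "n_repetitions": len(reports),
    }


def run_repetitions(
    patches,
    dims_template: dict,
    train_cfg: TrainConfig,
    tws: int,
    tss: int,
    spc: int,
    train_fraction: float = 0.30,
    n_classes: int = 3,
) -> ExperimentReport:
    """Run the repeated-experiment protocol from a fixed set of patches.

    Patches are tensorized once; every repetition re-draws the
    samples-per-class selection and the 30/70 split with a seed derived
    from ``train_cfg.seed``, trains a fresh model, and is scored on its
    held-out 70%. A diverged repetition is recorded with its last finite
    checkpoint and does not abort the batch.
    """
    all_samples = []
    for pid, patch in enumerate(patches):
        all_samples.extend(tensorize_patch(patch, tws=tws, tss=tss, patch_id=pid))
    if not all_samples:
        raise ValueError("no tensor samples produced from the given patches")
    master = np.random.default_rng(train_cfg.seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=train_cfg.repetitions)
    results: list[RepetitionResult] = []
    for rep, seed in enumerate(rep_seeds):
        seed = int(seed)
        chosen = sample_by_class(all_samples, spc=spc, rng_seed=seed)
        ds = split_dataset(chosen, train_fraction=train_fraction, rng_seed=seed,
                           spc=spc, tws=tws, tss=tss)
        X_tr, T_tr = stack_samples([ds.samples[i] for i in ds.train_idx])
        X_te, T_te = stack_samples([ds.samples[i] for i in ds.test_idx])
        dims = ModelDims(s=tws, b=X_tr.shape[3], C=n_classes,
                         Q=dims_template.get("Q", 25), R=dims_template.get("R", 4))
        cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
        params, history = fit_arrays(X_tr, T_tr, dims, cfg, X_te, T_te)
        pred = predict(params, X_te)
        cm = confusion_matrix_labels(T_te.argmax(axis=1), pred.argmax(axis=1), n_classes)
        acc, f1 = scores(cm)
        logger.info("repetition %d/%d: accuracy=%.4f macro_f1=%.4f%s",
                    rep + 1, train_cfg.repetitions, acc, f1,
                    " (diverged)" if history.diverged else "")
        results.append(RepetitionResult(acc, f1, cm, history, params, seed))
    report = ExperimentReport(per_repetition=results)
    report.aggregate = aggregate_repetitions(results)
    return report
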