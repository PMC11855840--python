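"""Training, evaluation metrics, cross-validation, and ablation runs.

The seven evaluation metrics are accuracy, sensitivity (recall on the
active class), specificity, Matthews correlation coefficient, F1,
area under the precision-recall curve (PRC), and area under the ROC
curve (AUC).  Confusion counts use a fixed decision threshold of 0.5
on the sigmoid output; AUC and PRC are threshold sweeps (trapezoidal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .config import ModelConfig
from .data_io import DatasetSplit, MoleculeRecord, split_dataset
from .fusion_head_loss import fusion_loss
from .model import GSFLModel
from .nn import Adam

__all__ = [
    "MetricsReport",
    "EpochLog",
    "compute_metrics",
    "train",
    "evaluate",
    "cross_validate",
    "run_ablation",
    "multi_seed",
    "ABLATION_VARIANTS",
]


@dataclass
class MetricsReport:
    TP: int
    FP: int
    TN: int
    FN: int
    ACC: float
    SE: float
    SP: float
    MCC: float
    F1: float
    PRC: float
    AUC: float
    mcc_undefined: bool = False
    auc_undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "ACC": self.ACC, "SE": self.SE, "SP": self.SP, "MCC": self.MCC,
            "F1": self.F1, "PRC": self.PRC, "AUC": self.AUC,
        }

    METRIC_NAMES = ("ACC", "SE", "SP", "MCC", "F1", "PRC", "AUC")


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(labels: Sequence[int], scores: Sequence[float],
                    threshold: float = 0.5) -> MetricsReport:
    """Confusion counts at `threshold` plus the seven scalar metrics.

    With single-class labels, MCC and AUC/PRC are undefined; they are
    reported as 0.0 with the corresponding ``*_undefined`` flag set.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("scores must lie in [0,1]")
    pred = (scores >= threshold).astype(int)
    TP = int(((pred == 1) & (labels == 1)).sum())
    FP = int(((pred == 1) & (labels == 0)).sum())
    TN = int(((pred == 0) & (labels == 0)).sum())
    FN = int(((pred == 0) & (labels == 1)).sum())

    acc = _safe_div(TP + TN, TP + TN + FP + FN)
    se = _safe_div(TP, TP + FN)
    sp = _safe_div(TN, TN + FP)
    f1 = _safe_div(2 * TP, 2 * TP + FP + FN)

    mcc_den = math.sqrt(
        float(TP + FP) * float(TP + FN) * float(TN + FP) * float(TN + FN))
    mcc_undefined = mcc_den == 0.0
    mcc = 0.0 if mcc_undefined else (TP * TN - FP * FN) / mcc_den

    auc_undefined = len(np.unique(labels)) < 2
    if auc_undefined:
        auc_val, prc_val = 0.0, 0.0
    else:
        fpr, tpr, _ = roc_curve(labels, scores)
        auc_val = float(_trapezoid_auc(fpr, tpr))
        precision, recall, _ = precision_recall_curve(labels, scores)
        prc_val = float(_trapezoid_auc(recall, precision))

    return MetricsReport(TP=TP, FP=FP, TN=TN, FN=FN, ACC=acc, SE=se, SP=sp,
                         MCC=mcc, F1=f1, PRC=prc_val, AUC=auc_val,
                         mcc_undefined=mcc_undefined,
                         auc_undefined=auc_undefined)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class EpochLog:
    epoch: int
    loss: float
    bce: float
    contrastive: float
    train_acc: float
    val_acc: float


def evaluate(model: GSFLModel, records: Sequence[MoleculeRecord],
             threshold: float = 0.5) -> MetricsReport:
    scores = model.predict_proba(list(records))
    return compute_metrics([r.label for r in records], scores, threshold)


def _selection_key(rep: MetricsReport) -> tuple:
    # checkpoint selection: ACC first, ties broken by MCC then F1
    return (rep.ACC, rep.MCC, rep.F1)


def train(
    split: DatasetSplit,
    config: ModelConfig,
    *,
    stop_at_train_acc: float | None = None,
    callback: Callable[[EpochLog], None] | None = None,
) -> tuple[GSFLModel, list[EpochLog]]:
    """Train with Adam on BCE + α·contrastive; return the checkpoint with
    the best validation accuracy and the per-epoch log.

    A fixed ``config.seed`` makes the whole run reproducible: parameter
    init, batch order, and dropout all derive from it.  Training aborts
    on a non-finite loss and can stop early when validation accuracy
    has not improved for ``config.patience`` epochs, or when training
    accuracy reaches ``stop_at_train_acc`` (overfitting probes).
    """
    if not split.train:
        raise ValueError("empty training split")
    model = GSFLModel.build(config, split.train)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    train_records = list(split.train)
    logs: list[EpochLog] = []
    best_arrays: list[np.ndarray] | None = None
    best_key: tuple | None = None
    stale = 0
    n = len(train_records)

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        total = bce_total = con_total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = model.collate([train_records[i] for i in idx])
            logits, Z_s, Z_g = model(batch, train=True, rng=rng)
            use_con = model.loss_config.alpha > 0 and len(idx) >= 2
            loss, bce_v, con_v = fusion_loss(
                logits, batch.labels,
                Z_s if use_con else None, Z_g if use_con else None,
                model.loss_config,
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}")
            model.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
            bce_total += bce_v
            con_total += con_v

        train_rep = evaluate(model, train_records)
        if split.validation:
            val_rep = evaluate(model, split.validation)
        else:
            val_rep = train_rep
        log = EpochLog(epoch=epoch, loss=total, bce=bce_total,
                       contrastive=con_total, train_acc=train_rep.ACC,
                       val_acc=val_rep.ACC)
        logs.append(log)
        if callback is not None:
            callback(log)

        key = _selection_key(val_rep)
        if best_key is None or key > best_key:
            best_key = key
            best_arrays = [p.data.copy() for p in params]
            stale = 0
        else:
            stale += 1
        if stop_at_train_acc is not None and train_rep.ACC >= stop_at_train_acc:
            break
        if stale >= config.patience:
            break

    if best_arrays is not None and stop_at_train_acc is None:
        model.load_state_arrays(best_arrays)
    return model, logs


# ---------------------------------------------------------------------------
# cross-validation, ablation, multi-seed
# ---------------------------------------------------------------------------

def cross_validate(
    records: Sequence[MoleculeRecord],
    k: int = 10,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> dict:
    """Stratified k-fold CV: per-fold reports plus mean/SD per metric.

    Within each fold, a tenth of the training portion is held out
    (stratified) for checkpoint selection.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    records = list(records)
    labels = np.array([r.label for r in records])
    for c in (0, 1):
        if (labels == c).sum() < k:
            raise ValueError(f"class {c} has fewer than k={k} members")
    config = config or ModelConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[MetricsReport] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(records, labels)):
        train_pool = [records[i] for i in train_idx]
        test_fold = [records[i] for i in test_idx]
        inner = split_dataset(train_pool, ratios=(0.8, 0.1, 0.1),
                              seed=seed + fold)
        split = DatasetSplit(train=inner.train + inner.test,
                             validation=inner.validation, test=test_fold,
                             seed=seed + fold, ratios=(0.9, 0.1, 0.0))
        model, _ = train(split, config.replace(seed=seed + fold))
        fold_reports.append(evaluate(model, test_fold))
    summary = {
        name: {
            "mean": float(np.mean([getattr(r, name) for r in fold_reports])),
            "sd": float(np.std([getattr(r, name) for r in fold_reports])),
        }
        for name in MetricsReport.METRIC_NAMES
    }
    return {"folds": fold_reports, "summary": summary}


ABLATION_VARIANTS: dict[str, dict] = {
    "all": {},
    "without_fa": {"use_fa": False},
    "without_ha": {"use_ha": False},
    "without_fg_splitting": {"use_fg_splitting": False},
    "graph_only": {"use_sequence_branch": False, "use_ha": False,
                   "use_fg_splitting": False},
}


def run_ablation(
    records: Sequence[MoleculeRecord],
    config: ModelConfig | None = None,
    seed: int = 0,
) -> dict[str, MetricsReport]:
    """Train and evaluate the five ablation variants on one shared split."""
    config = config or ModelConfig()
    split = split_dataset(list(records), seed=seed)
    out: dict[str, MetricsReport] = {}
    for name, overrides in ABLATION_VARIANTS.items():
        variant_cfg = config.replace(seed=seed, **overrides)
        model, _ = train(split, variant_cfg)
        out[name] = evaluate(model, split.test)
    return out


def multi_seed(
    records: Sequence[MoleculeRecord],
    config: ModelConfig | None = None,
    seeds: Sequence[int] = tuple(range(10)),
) -> dict:
    """Repeat split+train+test over several seeds; mean ± SD per metric."""
    config = config or ModelConfig()
    reports = []
    for s in seeds:
        split = split_dataset(list(records), seed=s)
        model, _ = train(split, config.replace(seed=s))
        reports.append(evaluate(model, split.test))
    summary = {
        name: {
            "mean": float(np.mean([getattr(r, name) for r in reports])),
            "sd": float(np.std([getattr(r, name) for r in reports])),
        }
        for name in MetricsReport.METRIC_NAMES
    }
    return {"per_seed": reports, "summary": summary}
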