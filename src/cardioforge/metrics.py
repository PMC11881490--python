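"""Binary-classification metrics, AUC, Pearson correlation and the
Y-randomization protocol.

Metric definitions (all from the 2x2 confusion table):

    AC  = (TP + TN) / (TP + TN + FP + FN)
    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    F1  = TP / (TP + (FP + FN) / 2)
    CCR = (SN + SP) / 2
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

AC, SN, SP, F1, CCR and MCC are reported x100 (percent-style) to match the
conventional benchmark-table formatting.  Ratios with a zero denominator are
reported as NaN ("undefined"); MCC with any zero marginal is reported as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import pearsonr, rankdata

__all__ = [
    "ConfusionCounts",
    "confusion",
    "MetricReport",
    "classification_metrics",
    "ccr_from_rates",
    "roc_auc",
    "pearson",
    "y_randomization",
    "YRandomizationReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(predicted: Sequence[int], true: Sequence[int]) -> ConfusionCounts:
    pred = np.asarray(predicted).astype(bool)
    truth = np.asarray(true).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


@dataclass(frozen=True)
class MetricReport:
    ac: float
    sn: float
    sp: float
    f1: float
    ccr: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"AC": self.ac, "SN": self.sn, "SP": self.sp,
                "F1": self.f1, "CCR": self.ccr, "MCC": self.mcc}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """Evaluate all six confusion-table metrics, scaled x100."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    ac = _ratio(tp + tn, tp + tn + fp + fn)
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    f1 = _ratio(tp, tp + 0.5 * (fp + fn))
    ccr = (sn + sp) / 2.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricReport(ac=100 * ac, sn=100 * sn, sp=100 * sp,
                        f1=100 * f1, ccr=100 * ccr, mcc=100 * mcc)


def ccr_from_rates(sn: float, sp: float) -> float:
    """CCR = (SN + SP) / 2 on already-percent-scaled sensitivity/specificity."""
    return (sn + sp) / 2.0


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve; ties averaged."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("Pearson correlation requires n >= 2")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("Pearson correlation undefined for zero variance")
    return float(pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# Y-randomization: retrain on label-shuffled data; real structure should
# collapse to chance.

@dataclass(frozen=True)
class YRandomizationReport:
    true_metric: float
    permuted_metrics: tuple[float, ...]
    metric_name: str

    @property
    def permuted_mean(self) -> float:
        return float(np.mean(self.permuted_metrics))

    @property
    def permuted_max(self) -> float:
        return float(np.max(self.permuted_metrics))


def y_randomization(records, featurizer, config, recipe, n_permutations: int,
                    seed: int = 0) -> YRandomizationReport:
    """Train on true labels and on ``n_permutations`` label-shuffled copies.

    Reports the best-validation metric (accuracy for classification,
    Pearson r for regression) of the true-label model against the permuted
    distribution.  The permutation sequence is deterministic per seed.
    """
    from dataclasses import replace as _replace

    from .predictors import train_predictor

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    records = list(records)
    true_run = train_predictor(records, featurizer, config, recipe, seed=seed)
    permuted = []
    for k in range(n_permutations):
        perm = rng.permutation(len(records))
        if config.task == "classification":
            labels = [records[i].resolved_label() for i in perm]
            shuffled = [_replace(r, label=l, pic50=None)
                        for r, l in zip(records, labels)]
        else:
            pic50s = [records[i].pic50 for i in perm]
            shuffled = [_replace(r, pic50=p) for r, p in zip(records, pic50s)]
        run = train_predictor(shuffled, featurizer, config, recipe,
                              seed=seed + 1000 + k)
        permuted.append(run.best_metric)
    name = "val_accuracy" if config.task == "classification" else "val_pearson"
    return YRandomizationReport(true_metric=true_run.best_metric,
                                permuted_metrics=tuple(permuted), metric_name=name)
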