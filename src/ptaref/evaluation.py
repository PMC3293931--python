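"""Performance measurement: confusion-matrix metrics, cross-validated ROC
and region-overlap benchmarking.

Sensitivity, specificity and accuracy are reported as percentages (two
decimals match the conventional tabulation); the Matthews correlation
coefficient lies in [-1, 1] and is reported as 0 and flagged undefined when
any factor of its denominator vanishes.  The ROC is built from pooled
out-of-fold SVR scores of a stratified 10-fold cross validation, with AUC by
the trapezoid rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .duplex_finder import CandidateSite
from .errors import FoldError, UndefinedMetricError
from .svr_model import SVRConfig, TargetScorer


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise UndefinedMetricError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    Sn: float   # percent
    Sp: float   # percent
    Ac: float   # percent
    MCC: float
    mcc_defined: bool = True


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """Sn, Sp, Ac (percent) and MCC from a 2x2 confusion matrix.

    Sn = 100*TP/(TP+FN); Sp = 100*TN/(TN+FP); Ac = 100*(TP+TN)/total;
    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP)), reported as
    0 and flagged undefined when any denominator factor is zero.  Sn/Sp are
    NaN when their own denominator is empty.
    """
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise UndefinedMetricError("all confusion counts are zero")
    sn = 100.0 * c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else math.nan
    sp = 100.0 * c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else math.nan
    ac = 100.0 * (c.TP + c.TN) / total
    denom = ((c.TN + c.FN) * (c.TN + c.FP) * (c.TP + c.FN) * (c.TP + c.FP))
    if denom == 0:
        return Metrics(Sn=sn, Sp=sp, Ac=ac, MCC=0.0, mcc_defined=False)
    mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return Metrics(Sn=sn, Sp=sp, Ac=ac, MCC=mcc)


@dataclass(frozen=True)
class CVROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray   # pooled out-of-fold scores, original instance order
    labels: np.ndarray


def cv_roc(
    instances: np.ndarray,
    labels: Sequence[float],
    cfg: Optional[SVRConfig] = None,
    folds: int = 10,
    seed: int = 0,
) -> CVROCResult:
    """Stratified k-fold cross-validated ROC from pooled out-of-fold scores.

    ``labels`` are +1/-1 (anything >0 is treated as positive).  Deterministic
    given ``seed``; each class must have at least ``folds`` members.
    """
    if cfg is None:
        cfg = SVRConfig()
    X = np.asarray(instances, dtype=float)
    y = np.where(np.asarray(labels, dtype=float) > 0, 1.0, -1.0)
    n_pos, n_neg = int(np.sum(y > 0)), int(np.sum(y < 0))
    if n_pos < folds or n_neg < folds:
        raise FoldError(
            f"each class needs >= {folds} instances (have {n_pos} pos, {n_neg} neg)")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    for train_idx, test_idx in skf.split(X, y):
        pos = X[train_idx][y[train_idx] > 0]
        neg = X[train_idx][y[train_idx] < 0]
        results = TargetScorer(pos, neg, config=cfg).fit()
        pooled[test_idx] = results.decision_values(X[test_idx])
    fpr, tpr, _ = roc_curve(y, pooled)
    return CVROCResult(fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)),
                       scores=pooled, labels=y)


@dataclass(frozen=True)
class RegionBenchmark:
    tp_rate: float   # percent of validated regions hit
    fp_rate: float   # percent of predictions outside every validated region
    n_predictions: int
    n_regions: int
    n_fp: int
    n_regions_hit: int


def region_benchmark(
    predictions: Sequence[CandidateSite],
    validated_regions: Sequence[Tuple[str, int, int]],
    min_overlap: int = 1,
) -> RegionBenchmark:
    """Benchmark predictions against experimentally validated regions.

    A prediction overlapping (>= ``min_overlap`` nt) a validated region on
    the same transcript counts as a true positive; predictions falling
    outside every validated region are the negatives used for the
    false-positive rate.  TP rate = percent of validated regions hit.
    """
    hit_regions = set()
    n_fp = 0
    for p in predictions:
        is_tp = False
        for ri, (tid, start, end) in enumerate(validated_regions):
            if tid != p.transcript_id:
                continue
            overlap = min(p.end, end) - max(p.start, start)
            if overlap >= min_overlap:
                is_tp = True
                hit_regions.add(ri)
        if not is_tp:
            n_fp += 1
    n_pred, n_reg = len(predictions), len(validated_regions)
    return RegionBenchmark(
        tp_rate=100.0 * len(hit_regions) / n_reg if n_reg else math.nan,
        fp_rate=100.0 * n_fp / n_pred if n_pred else math.nan,
        n_predictions=n_pred, n_regions=n_reg,
        n_fp=n_fp, n_regions_hit=len(hit_regions),
    )


def metrics_to_tsv(metrics: Metrics, path: Union[str, Path]) -> None:
    pd.DataFrame([{
        "Sn": round(metrics.Sn, 2), "Sp": round(metrics.Sp, 2),
        "Ac": round(metrics.Ac, 2), "MCC": round(metrics.MCC, 4),
        "mcc_defined": metrics.mcc_defined,
    }]).to_csv(path, sep="\t", index=False)


def roc_to_tsv(result: CVROCResult, path: Union[str, Path]) -> None:
    pd.DataFrame({"fpr": result.fpr, "tpr": result.tpr}).to_csv(
        path, sep="\t", index=False)
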