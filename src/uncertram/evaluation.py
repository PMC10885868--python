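"""Test metrics and uncertainty-stratified evaluation.

Eight metrics are reported: precision, accuracy, AUPRC, AUROC, sensitivity,
specificity, F1 and the Matthews correlation coefficient, all computed from
the base branch's predictions against mean-aggregated labels.  Predictions
are additionally stratified by the image-level uncertainty D into a clean
stratum [0, 2) and an equivocal stratum [2, max]; the clean stratum carries
the interpretable signal since its labels are the most reliable.

Degenerate cases are flagged as NaN rather than silently coerced to 0:
AUROC/AUPRC and MCC when the evaluated sample contains a single class, and
MCC whenever a denominator factor vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "MetricsRecord",
    "StratifiedReport",
    "DEFAULT_BINS",
    "compute_metrics",
    "confusion_counts",
    "stratified_evaluate",
    "metrics_table",
]

METRIC_NAMES = ("precision", "accuracy", "auprc", "auroc", "sensitivity",
                "specificity", "f1", "mcc")


@dataclass
class MetricsRecord:
    precision: float
    accuracy: float
    auprc: float
    auroc: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_counts(y_true: np.ndarray,
                     y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den else float("nan")


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    y_score: np.ndarray) -> MetricsRecord:
    """The eight metrics from labels, hard predictions and positive-class
    scores.

    Threshold metrics come from the confusion counts; AUROC uses the
    rank statistic (mid-rank tie handling, equivalent to trapezoidal ROC
    integration) and AUPRC the average-precision step sum.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if not (len(y_true) == len(y_pred) == len(y_score)):
        raise ValueError("y_true, y_pred and y_score must share a length")
    tp, tn, fp, fn = confusion_counts(y_true, y_pred)
    precision = _safe_div(tp, tp + fp)
    accuracy = _safe_div(tp + tn, tp + tn + fp + fn)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    if math.isnan(precision) or math.isnan(sensitivity):
        f1 = float("nan")
    else:
        f1 = _safe_div(2 * sensitivity * precision, sensitivity + precision)
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (_safe_div(tp * tn - fp * fn, math.sqrt(denom)) if denom
           else float("nan"))
    if len(np.unique(y_true)) < 2:
        auroc = float("nan")
        auprc = float("nan")
    else:
        auroc = float(roc_auc_score(y_true, y_score))
        auprc = float(average_precision_score(y_true, y_score))
    return MetricsRecord(precision=precision, accuracy=accuracy, auprc=auprc,
                         auroc=auroc, sensitivity=sensitivity,
                         specificity=specificity, f1=f1, mcc=mcc,
                         tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertaintyBin:
    low: float
    high: float
    closed_top: bool = False
    name: str = ""

    def contains(self, d: float) -> bool:
        if self.closed_top:
            return self.low <= d <= self.high
        return self.low <= d < self.high


DEFAULT_BINS = (
    UncertaintyBin(0.0, 2.0, closed_top=False, name="clean"),
    UncertaintyBin(2.0, float("inf"), closed_top=True, name="equivocal"),
)


@dataclass
class StratifiedReport:
    bins: tuple[UncertaintyBin, ...]
    records: dict[str, MetricsRecord | None] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)


def _empty_record() -> MetricsRecord:
    nan = float("nan")
    return MetricsRecord(*([nan] * 8), tp=0, tn=0, fp=0, fn=0)


def stratified_evaluate(y_true: np.ndarray, y_pred: np.ndarray,
                        y_score: np.ndarray, D: np.ndarray,
                        bins: tuple[UncertaintyBin, ...] = DEFAULT_BINS,
                        ) -> StratifiedReport:
    """Evaluate per uncertainty stratum.

    Each case is assigned to the unique bin containing its D (the clean bin
    is right-open at 2, the top bin closed so no case is dropped); empty
    strata are reported with n = 0 and NaN metrics.
    """
    D = np.asarray(D, dtype=float)
    report = StratifiedReport(bins=tuple(bins))
    assigned = np.zeros(len(D), dtype=bool)
    for b in bins:
        mask = np.array([b.contains(d) for d in D]) & ~assigned
        assigned |= mask
        name = b.name or f"[{b.low},{b.high}{']' if b.closed_top else ')'}"
        report.sizes[name] = int(mask.sum())
        if mask.any():
            report.records[name] = compute_metrics(
                np.asarray(y_true)[mask], np.asarray(y_pred)[mask],
                np.asarray(y_score)[mask])
        else:
            report.records[name] = _empty_record()
    if not assigned.all():
        bad = D[~assigned]
        raise ValueError(f"uncertainty value {bad[0]} falls outside all bins")
    return report


def metrics_table(rows: dict[str, list[MetricsRecord]]) -> pd.DataFrame:
    """Mean +/- sd table across folds, one row per model variant."""
    out = []
    for variant, records in rows.items():
        row: dict[str, object] = {"model": variant}
        for name in METRIC_NAMES:
            vals = np.array([getattr(r, name) for r in records], dtype=float)
            row[name] = (f"{np.nanmean(vals):.3f} ± "
                         f"{np.nanstd(vals):.3f}")
        out.append(row)
    return pd.DataFrame(out)
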