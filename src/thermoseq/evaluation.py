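"""Confusion-matrix metrics, ROC/AUC and binned error analyses.

The seven scalar metrics for n_s = tp + tn + fp + fn samples:

    accuracy    = (tp + tn) / n_s
    precision   = tp / (tp + fp)
    recall      = tp / (tp + fn)
    specificity = tn / (tn + fp)
    BACC        = (recall + specificity) / 2
    F1          = 2 * precision * recall / (precision + recall)
    MCC         = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))

A metric whose denominator is zero is reported as 0 and flagged as
degenerate rather than raised on (the common MCC convention). MCC, a
correlation in [-1, 1], is robust to class imbalance and serves as the
primary criterion throughout; the others lie in [0, 1].

Binned analyses slice predictions by sequence length (equal-width bins over
the observed range, right-closed) and by the optimal growth temperature of
the source species, exposing where a classifier fails.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .io import Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "metrics",
    "roc_auc",
    "bin_by_length",
    "bin_by_ogt",
    "percent_improvement",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n_s < 1:
            raise ValueError("confusion table must contain at least one sample")

    @property
    def n_s(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    bacc: float
    f1: float
    mcc: float
    auc: float | None = None
    degenerate: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "bacc": self.bacc,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def confusion(labels, preds) -> ConfusionCounts:
    """Count the four label/prediction cells (positive class = 1)."""
    labels = np.asarray(labels, dtype=int)
    preds = np.asarray(preds, dtype=int)
    if labels.shape != preds.shape:
        raise ValueError(f"length mismatch: {labels.shape} labels vs {preds.shape} predictions")
    if labels.size < 1:
        raise ValueError("empty inputs")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (preds == 1))),
        tn=int(np.sum((labels == 0) & (preds == 0))),
        fp=int(np.sum((labels == 0) & (preds == 1))),
        fn=int(np.sum((labels == 1) & (preds == 0))),
    )


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """The seven confusion-matrix metrics; zero denominators → 0, flagged."""
    flags: list[str] = []
    accuracy = (c.tp + c.tn) / c.n_s
    precision = _safe_div(c.tp, c.tp + c.fp, "precision", flags)
    recall = _safe_div(c.tp, c.tp + c.fn, "recall", flags)
    specificity = _safe_div(c.tn, c.tn + c.fp, "specificity", flags)
    bacc = 0.5 * (recall + specificity)
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1", flags)
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _safe_div(c.tp * c.tn - c.fp * c.fn, mcc_den, "mcc", flags)
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        bacc=bacc,
        f1=f1,
        mcc=mcc,
        auc=auc,
        degenerate=tuple(flags),
    )


def roc_auc(labels, scores) -> tuple[pd.DataFrame, float]:
    """ROC curve over all score thresholds and the trapezoid-rule AUC.

    Tied scores are grouped into a single threshold step.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes in the labels")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return curve, auc


def _length_bin_edges(lengths: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = int(lengths.min()), int(lengths.max())
    return np.linspace(lo, hi, n_bins + 1)


def bin_by_length(ds: Dataset, preds, n_bins: int = 5) -> pd.DataFrame:
    """Per-length-bin confusion counts and metrics.

    Bins are equal-width over [min length, max length]; each bin is
    right-closed so integer boundaries fall in the lower bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(ds.labels, dtype=int)
    lengths = np.array([len(rec) for rec in ds])
    edges = _length_bin_edges(lengths, n_bins)
    # right-closed: a length equal to an internal edge joins the lower bin
    bins = np.digitize(lengths, edges[1:-1], right=True)
    rows = []
    for b in range(n_bins):
        sel = bins == b
        row = {
            "bin_low": edges[b],
            "bin_high": edges[b + 1],
            "n_thermo": int(np.sum(labels[sel] == 1)),
            "n_nonthermo": int(np.sum(labels[sel] == 0)),
        }
        if sel.any():
            c = confusion(labels[sel], preds[sel])
            row.update({"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn})
            row["mcc"] = metrics(c).mcc
        else:
            row.update({"tp": 0, "tn": 0, "fp": 0, "fn": 0, "mcc": 0.0})
        rows.append(row)
    return pd.DataFrame(rows)


def bin_by_ogt(ds: Dataset, preds, edges) -> pd.DataFrame:
    """Counts of species, proteins, tp and fn per OGT interval.

    ``edges`` are left-closed interval starts; the final interval is open
    above (e.g. [60, 70, 80, 90] → [60,70), [70,80), [80,90), 90+). Records
    without an OGT are excluded with a logged count.
    """
    preds = np.asarray(preds, dtype=int)
    have_ogt = [i for i, rec in enumerate(ds.records) if rec.ogt is not None]
    n_missing = len(ds) - len(have_ogt)
    if n_missing:
        logger.info("bin_by_ogt: excluded %d records without OGT", n_missing)
    edges = list(edges)
    rows = []
    for k, lo in enumerate(edges):
        hi = edges[k + 1] if k + 1 < len(edges) else math.inf
        sel = [i for i in have_ogt if lo <= ds.records[i].ogt < hi]
        species = {ds.records[i].species for i in sel}
        tp = sum(1 for i in sel if ds.records[i].label == 1 and preds[i] == 1)
        fn = sum(1 for i in sel if ds.records[i].label == 1 and preds[i] == 0)
        rows.append(
            {
                "ogt_low": lo,
                "ogt_high": hi,
                "n_species": len(species),
                "n_proteins": len(sel),
                "tp": tp,
                "fn": fn,
            }
        )
    return pd.DataFrame(rows)


def percent_improvement(new: float, baseline: float) -> float:
    """Relative improvement of ``new`` over ``baseline`` in percent."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return (new - baseline) / baseline * 100.0
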