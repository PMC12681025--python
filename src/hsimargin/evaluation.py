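"""Pixel-wise diagnostic metrics, ROC/AUC, classification maps, and cohort
summaries.

Every test pixel is one observation: a probability from the classifier and
a binary tumour/healthy truth label. A pixel counts as a positive call
when its probability is **greater than or equal to** the threshold (closed
lower bound, default 0.5). Classification outcomes are rendered as
four-colour maps: true negatives green, true positives blue, false
positives red, false negatives yellow.

For the half-split experiment metrics are pooled over all test pixels of
the cohort; for leave-one-out they are computed per fold and aggregated as
mean +/- sample (n-1) standard deviation. Metrics with an empty
denominator (e.g. sensitivity on a fold without tumour pixels) are flagged
absent rather than coerced to 0, and excluded from aggregation with a
logged note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsRecord:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    n_pixels: int
    n_positive: int
    unit: str = "pooled"  # or "per-fold"

    METRICS = ("accuracy", "sensitivity", "specificity", "auc")

    def as_dict(self) -> dict:
        return {
            **{m: getattr(self, m) for m in self.METRICS},
            "n_pixels": self.n_pixels,
            "n_positive": self.n_positive,
            "unit": self.unit,
        }


def confusion_at_threshold(
    prob_map: np.ndarray,
    truth: np.ndarray,
    region: np.ndarray | None = None,
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Tally pixel calls (prob >= threshold) against binary truth in a region."""
    prob_map = np.asarray(prob_map, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if prob_map.shape != truth.shape:
        raise ValueError("probability map and truth mask shapes differ")
    if region is None:
        region = ~np.isnan(prob_map)
    if not region.any():
        raise ValueError("empty evaluation region")
    p = prob_map[region]
    t = truth[region]
    if np.isnan(p).any():
        raise ValueError("region contains unevaluated (NaN) probabilities")
    call = p >= threshold
    return ConfusionCounts(
        tp=int(np.sum(call & t)),
        tn=int(np.sum(~call & ~t)),
        fp=int(np.sum(call & ~t)),
        fn=int(np.sum(~call & t)),
    )


def metrics_from_confusion(c: ConfusionCounts, unit: str = "pooled") -> MetricsRecord:
    """Accuracy/sensitivity/specificity from counts; undefined -> None."""
    def ratio(num, den):
        return num / den if den > 0 else None

    return MetricsRecord(
        accuracy=ratio(c.tp + c.tn, c.n),
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        auc=None,
        n_pixels=c.n,
        n_positive=c.tp + c.fn,
        unit=unit,
    )


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self):
        if not (self.fpr[0] == 0 and self.tpr[0] == 0):
            raise ValueError("ROC must start at (0, 0)")
        if not (self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC must end at (1, 1)")


def roc_curve(probs: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over all decision thresholds (one per unique probability)."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _skm.roc_curve(labels, np.asarray(probs, dtype=float),
                                   drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def auc(curve: ROCCurve) -> float:
    """Area under the ROC by the trapezoidal rule.

    Equals the Mann-Whitney concordance probability (ties counted 1/2).
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_threshold(curve: ROCCurve) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1."""
    j = curve.tpr - curve.fpr
    t = curve.thresholds[int(np.argmax(j))]
    return float(min(t, 1.0))  # sklearn's leading threshold is inf


@dataclass(frozen=True)
class ClassificationMapSpec:
    """Four-colour coding of pixel outcomes (RGB triples) and the threshold."""

    threshold: float = 0.5
    tn_colour: tuple[int, int, int] = (0, 160, 60)     # green
    tp_colour: tuple[int, int, int] = (30, 70, 220)    # blue
    fp_colour: tuple[int, int, int] = (220, 40, 40)    # red
    fn_colour: tuple[int, int, int] = (250, 220, 40)   # yellow
    background: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        colours = {self.tn_colour, self.tp_colour, self.fp_colour, self.fn_colour}
        if len(colours) != 4:
            raise ValueError("the four outcome colours must be distinct")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


def render_classification_map(
    prob_map: np.ndarray,
    truth: np.ndarray,
    spec: ClassificationMapSpec | None = None,
) -> np.ndarray:
    """RGB image colouring each evaluated pixel by its confusion class.

    Colour counts equal the confusion counts at the same threshold;
    unevaluated (NaN) pixels take the background colour.
    """
    spec = spec or ClassificationMapSpec()
    prob_map = np.asarray(prob_map, dtype=float)
    truth = np.asarray(truth).astype(bool)
    region = ~np.isnan(prob_map)
    call = np.zeros_like(truth)
    call[region] = prob_map[region] >= spec.threshold
    out = np.empty(prob_map.shape + (3,), dtype=np.uint8)
    out[...] = spec.background
    out[region & call & truth] = spec.tp_colour
    out[region & ~call & ~truth] = spec.tn_colour
    out[region & call & ~truth] = spec.fp_colour
    out[region & ~call & truth] = spec.fn_colour
    return out


@dataclass
class FoldSummary:
    records: list[MetricsRecord]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)


def aggregate_folds(records: list[MetricsRecord]) -> FoldSummary:
    """Mean and sample (ddof=1) SD per metric over folds.

    Folds where a metric is absent (undefined denominator) are excluded
    from that metric's aggregation with a logged note.
    """
    if len(records) < 2:
        raise ValueError("fold aggregation needs >= 2 folds")
    summary = FoldSummary(records=list(records))
    for m in MetricsRecord.METRICS:
        vals = [getattr(r, m) for r in records]
        present = [v for v in vals if v is not None]
        if len(present) < len(vals):
            logger.info(
                "metric %s absent in %d/%d folds; excluded from aggregation",
                m, len(vals) - len(present), len(vals),
            )
        if present:
            summary.mean[m] = float(np.mean(present))
            summary.sd[m] = float(np.std(present, ddof=1)) if len(present) > 1 else 0.0
    return summary


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def load_cohort_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged cohort table (or a CSV with the same columns)."""
    if path is None:
        src = resources.files("hsimargin.data").joinpath("table1_cohort.csv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    required = {"lesion_id", "size_mm", "subclinical_extension"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    return table


def cohort_summary(table: pd.DataFrame) -> dict:
    """Direct tallies over the cohort table rows.

    Medians are recomputed from the rows (they may differ from any
    separately published summary figures; the recomputed value is what is
    reported here).
    """
    if table.empty:
        raise ValueError("cohort table is empty")
    for i, row in table.iterrows():
        if pd.isna(row["size_mm"]) or row["subclinical_extension"] not in ("Yes", "No"):
            raise ValueError(f"malformed cohort row {row['lesion_id']!r} (index {i})")
    sizes = table["size_mm"].astype(float)
    out = {
        "n_lesions": int(len(table)),
        "n_subclinical_positive": int((table["subclinical_extension"] == "Yes").sum()),
        "size_min_mm": float(sizes.min()),
        "size_max_mm": float(sizes.max()),
        "size_median_mm": float(sizes.median()),
    }
    if "age_years" in table.columns:
        ages = table["age_years"].astype(float)
        out.update(
            age_median_years=float(ages.median()),
            age_min_years=float(ages.min()),
            age_max_years=float(ages.max()),
        )
    return out
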