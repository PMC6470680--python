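"""Confusion-matrix metrics, the four-stage selection funnel, and the
goodness index of the collapsed regular-vs-irregular model.

Per-class metrics follow the one-vs-rest reading of the 3x3 confusion
matrix: recall R = TP/(TP+FN), precision P = TP/(TP+FP), F1 the harmonic
mean of the two; the overall accuracy A is the trace over the total, and
with balanced classes the unweighted mean of the per-class recalls equals A.
Undefined precision (a class never predicted) is reported as 0 with a
warning so that downstream selection is conservative.

The selection funnel keeps, in order: mean A >= 0.80; per-class mean recall
>= 0.80 for all three conditions; overall mean precision >= 0.80; per-class
mean precision >= 0.80.  Comparisons are made on values rounded to two
decimals (the convention under which published metric tables reproduce their
own pass/fail pattern).

For funnel survivors the 3x3 matrix is collapsed to 2x2 by merging the two
fault classes into "irregular", and the goodness index

    G = sqrt((1 - TPR)^2 + (1 - TNR)^2)

is the Euclidean distance of the classifier from the perfect corner of ROC
space (TPR: irregular detected as irregular; TNR: regular as regular).
G = 0 is perfect, sqrt(0.5) ~= 0.70 is chance; categories: optimum
G <= 0.25, good 0.25 < G <= 0.70, random at the chance point, bad above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .synthdata import CONDITIONS

FUNNEL_STAGES = ("accuracy", "min_recall", "overall_precision", "min_precision")
CHANCE_G = math.sqrt(0.5)

METRIC_COLUMNS = (
    ["A"]
    + [f"R_{c}" for c in CONDITIONS]
    + ["P_overall"]
    + [f"P_{c}" for c in CONDITIONS]
    + ["F1_overall"]
    + [f"F1_{c}" for c in CONDITIONS]
)


@dataclass
class MetricsReport:
    accuracy: float
    recall: np.ndarray  # per class, CONDITIONS order
    precision: np.ndarray
    f1: np.ndarray
    precision_overall: float
    f1_overall: float

    def as_dict(self) -> dict[str, float]:
        out = {"A": self.accuracy}
        for i, cond in enumerate(CONDITIONS):
            out[f"R_{cond}"] = float(self.recall[i])
        out["P_overall"] = self.precision_overall
        for i, cond in enumerate(CONDITIONS):
            out[f"P_{cond}"] = float(self.precision[i])
        out["F1_overall"] = self.f1_overall
        for i, cond in enumerate(CONDITIONS):
            out[f"F1_{cond}"] = float(self.f1[i])
        return out


def confusion_matrix(true_labels, predicted_labels, labels=CONDITIONS) -> np.ndarray:
    """Cell (i, j) counts true class i predicted as class j."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise InputError("true and predicted label arrays differ in length")
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    cm = np.zeros((k, k), dtype=float)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise InputError(f"label outside {labels}: {t!r}/{p!r}")
        cm[index[t], index[p]] += 1
    return cm


def compute_metrics(cm) -> MetricsReport:
    """A, per-class R/P/F1 and their unweighted means from a 3x3 matrix."""
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise InputError("confusion matrix must be square")
    total = cm.sum()
    if total <= 0:
        raise InputError("confusion matrix is empty")
    k = cm.shape[0]
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp

    recall = np.zeros(k)
    precision = np.zeros(k)
    f1 = np.zeros(k)
    for i in range(k):
        recall[i] = tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] > 0 else 0.0
        if tp[i] + fp[i] > 0:
            precision[i] = tp[i] / (tp[i] + fp[i])
        else:
            warnings.warn(
                f"class {i} never predicted; precision reported as 0", stacklevel=2
            )
            precision[i] = 0.0
        denom = recall[i] + precision[i]
        f1[i] = 2 * recall[i] * precision[i] / denom if denom > 0 else 0.0

    return MetricsReport(
        accuracy=float(tp.sum() / total),
        recall=recall,
        precision=precision,
        f1=f1,
        precision_overall=float(precision.mean()),
        f1_overall=float(f1.mean()),
    )


def records_to_frame(records) -> pd.DataFrame:
    """One row of metrics per ResultRecord (per athlete, per model)."""
    rows = []
    for rec in records:
        row = {
            "athlete_id": rec.athlete_id,
            "name": rec.name,
            "classifier": rec.classifier,
            "segment": rec.segment,
            "combo": rec.combo,
        }
        row.update(compute_metrics(rec.cm).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate(records_or_frame) -> pd.DataFrame:
    """Mean and sample SD of every metric across athletes, per model name."""
    frame = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else records_to_frame(records_or_frame)
    )
    n_athletes = frame["athlete_id"].nunique()
    if n_athletes < 2:
        warnings.warn("single athlete: standard deviations reported as 0", stacklevel=2)
    grouped = frame.groupby("name", sort=True)
    means = grouped[list(METRIC_COLUMNS)].mean()
    sds = grouped[list(METRIC_COLUMNS)].std(ddof=1).fillna(0.0)
    sds.columns = [f"{c}_sd" for c in sds.columns]
    meta = grouped[["classifier", "segment", "combo"]].first()
    return pd.concat([meta, means, sds], axis=1)


def selection_funnel(
    aggregated: pd.DataFrame, thresholds: tuple[float, float, float, float] = (0.80,) * 4
) -> pd.DataFrame:
    """Apply the cascaded accuracy/recall/precision criteria.

    Expects the layout produced by :func:`aggregate` (or any table with
    columns ``A``, ``R_<cond>``, ``P_overall``, ``P_<cond>``).  Returns a
    copy with ``stage_reached`` ("rejected@k" or "survivor"), ``survivor``,
    and the failed metric/value.  Values are rounded to two decimals before
    comparison.
    """
    required = ["A"] + [f"R_{c}" for c in CONDITIONS] + ["P_overall"] + [
        f"P_{c}" for c in CONDITIONS
    ]
    missing = [c for c in required if c not in aggregated.columns]
    if missing:
        raise InputError(f"aggregated table lacks metric column(s): {missing}")

    out = aggregated.copy()
    rounded = out[required].round(2)
    stage = pd.Series("survivor", index=out.index, dtype=object)
    reason_metric = pd.Series("", index=out.index, dtype=object)
    reason_value = pd.Series(np.nan, index=out.index, dtype=float)

    recall_cols = [f"R_{c}" for c in CONDITIONS]
    precision_cols = [f"P_{c}" for c in CONDITIONS]
    checks = (
        ("rejected@1", rounded["A"], "A", thresholds[0]),
        ("rejected@2", rounded[recall_cols].min(axis=1), "min_recall", thresholds[1]),
        ("rejected@3", rounded["P_overall"], "P_overall", thresholds[2]),
        (
            "rejected@4",
            rounded[precision_cols].min(axis=1),
            "min_precision",
            thresholds[3],
        ),
    )
    for label, values, metric, threshold in checks:
        active = stage == "survivor"
        if values[active].isna().any():
            bad = values[active].index[values[active].isna()].tolist()
            raise InputError(f"missing {metric} values for candidate model(s) {bad}")
        failed = active & (values < threshold)
        stage[failed] = label
        reason_metric[failed] = metric
        reason_value[failed] = values[failed]

    out["stage_reached"] = stage
    out["survivor"] = stage == "survivor"
    out["reason_metric"] = reason_metric
    out["reason_value"] = reason_value
    return out


def collapse_binary(cm) -> np.ndarray:
    """Merge the two fault classes into "irregular": 3x3 -> 2x2."""
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (3, 3):
        raise InputError("expected a 3x3 confusion matrix")
    return np.array(
        [
            [cm[0, 0], cm[0, 1:].sum()],
            [cm[1:, 0].sum(), cm[1:, 1:].sum()],
        ]
    )


def goodness_from_rates(tp_rate: float, tn_rate: float) -> tuple[float, str]:
    """Goodness index and category from true-positive/true-negative *rates*."""
    g = math.sqrt((1.0 - tp_rate) ** 2 + (1.0 - tn_rate) ** 2)
    if g <= 0.25:
        category = "optimum"
    elif abs(g - CHANCE_G) < 5e-3:
        category = "random"
    elif g <= CHANCE_G:
        category = "good"
    else:
        category = "bad"
    return g, category


def goodness_index(cm2) -> tuple[float, str]:
    """Goodness index of a 2x2 matrix (positive class: irregular)."""
    cm2 = np.asarray(cm2, dtype=float)
    if cm2.shape != (2, 2):
        raise InputError("expected a 2x2 confusion matrix")
    regular_total = cm2[0].sum()
    irregular_total = cm2[1].sum()
    if regular_total <= 0 or irregular_total <= 0:
        raise InputError("both classes must be present to compute G")
    tn_rate = cm2[0, 0] / regular_total
    tp_rate = cm2[1, 1] / irregular_total
    return goodness_from_rates(tp_rate, tn_rate)


def binary_report(records, names=None) -> pd.DataFrame:
    """Accuracy and goodness index of the simplified (2-class) models,
    pooling the confusion matrices of all athletes."""
    pooled: dict[str, np.ndarray] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for rec in records:
        if names is not None and rec.name not in names:
            continue
        pooled[rec.name] = pooled.get(rec.name, 0) + np.asarray(rec.cm, dtype=float)
        meta[rec.name] = (rec.classifier, rec.segment, rec.combo)
    rows = []
    for name in sorted(pooled):
        cm2 = collapse_binary(pooled[name])
        g, category = goodness_index(cm2)
        rows.append(
            {
                "name": name,
                "classifier": meta[name][0],
                "segment": meta[name][1],
                "combo": meta[name][2],
                "accuracy": float(np.trace(cm2) / cm2.sum()),
                "G": g,
                "category": category,
            }
        )
    return pd.DataFrame(rows).set_index("name") if rows else pd.DataFrame()
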