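"""Benchmarking a per-minute recognizer confidence stream against label sources.

Each recognizer class is evaluated one-vs-rest against three possible
truth sources — thigh-only, verbal-only, and consensus labels — via ROC
curves, Youden-J-optimal confidence thresholds, and rank-based AUC.
Minutes lacking a label under a source are dropped for that source only,
so the three sources evaluate on different minute sets; n is reported per
cell.  AUC is computed on raw confidences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .activity_scheme import EXCLUDED, Activity, api_label_set

LABEL_SOURCES = ("thigh", "verbal", "consensus")

#: classes evaluated one-vs-rest (TILTING/UNKNOWN carry no posture semantics)
EVALUABLE_CLASSES = ("STILL", "IN_VEHICLE", "ON_FOOT", "WALKING", "RUNNING", "ON_BICYCLE")

API_CSV_COLUMNS = (
    "participant_id",
    "minute_start",
    "still",
    "in_vehicle",
    "on_foot",
    "walking",
    "running",
    "on_bicycle",
    "tilting",
    "unknown",
)


@dataclass
class EvalCurve:
    api_class: str
    label_source: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    youden_threshold: float
    youden_j: float
    auc: float
    n_pos: int
    n_neg: int


def binarize_truth(
    frames: pd.DataFrame, api_class: str, label_source: str
) -> pd.Series:
    """Per-minute binary truth for one recognizer class under one source.

    Minutes without a label under the source are omitted.  Truth is 1 when
    the source's label (any member of the set, for verbal) belongs to the
    class's mapped leaf set.
    """
    mapped = api_label_set(api_class)
    if not mapped:
        raise ValueError(f"{api_class} maps to no leaves and is not evaluable")
    if label_source == "thigh":
        sub = frames[(frames["thigh_label"] != EXCLUDED) & frames["worn"]]
        truth = sub["thigh_label"].map(lambda lab: Activity(lab) in mapped)
    elif label_source == "verbal":
        sub = frames[frames["worn"] & frames["verbal_labels"].map(bool)]
        truth = sub["verbal_labels"].map(lambda s: bool(s & mapped))
    elif label_source == "consensus":
        sub = frames[frames["consensus_label"] != EXCLUDED]
        truth = sub["consensus_label"].map(lambda lab: Activity(lab) in mapped)
    else:
        raise ValueError(f"unknown label source: {label_source!r}")
    return truth.astype(int)


def roc(confidences: np.ndarray, truth: np.ndarray) -> tuple:
    """Grouped-threshold ROC sweep; returns (fpr, tpr, thresholds).

    Thresholds are the distinct confidence values in descending order
    (an initial sentinel above the maximum yields the (0, 0) endpoint);
    prediction is positive when confidence >= threshold.
    """
    truth = np.asarray(truth)
    if truth.min() == truth.max():
        cls = "positive" if truth.max() == 1 else "negative"
        raise ValueError(f"single-class truth (all {cls}); ROC undefined")
    fpr, tpr, thr = roc_curve(
        truth, np.asarray(confidences, dtype=float), drop_intermediate=False
    )
    return fpr, tpr, thr


def youden_optimal(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray) -> tuple:
    """(threshold, J) maximizing J = TPR - FPR; ties go to the highest
    threshold (the most conservative detector)."""
    j = np.asarray(tpr) - np.asarray(fpr)
    finite = np.isfinite(thresholds)
    if not finite.any():
        return float("nan"), 0.0
    idx_f = np.flatnonzero(finite)
    j_max = j[idx_f].max()
    # thresholds are descending: the first index within numerical tolerance
    # of the maximum is the highest tying threshold
    best = idx_f[np.flatnonzero(j[idx_f] >= j_max - 1e-12)[0]]
    return float(thresholds[best]), float(j[best])


def auc(confidences: np.ndarray, truth: np.ndarray) -> float:
    """Rank-statistic AUC with tie correction (= trapezoid area of the
    grouped ROC)."""
    truth = np.asarray(truth)
    if truth.min() == truth.max():
        raise ValueError("single-class truth; AUC undefined")
    return float(roc_auc_score(truth, np.asarray(confidences, dtype=float)))


def evaluate(
    frames: pd.DataFrame, api_class: str, label_source: str
) -> Optional[EvalCurve]:
    """Full one-vs-rest evaluation of one class under one label source.

    Returns None when the cell is not evaluable (single-class truth or no
    overlapping confidence data).
    """
    truth = binarize_truth(frames, api_class, label_source)
    conf = frames.loc[truth.index, "api_confidences"].map(
        lambda c: c.get(api_class) if isinstance(c, dict) else None
    )
    ok = conf.notna()
    truth, conf = truth[ok], conf[ok].astype(float)
    if len(truth) == 0 or truth.min() == truth.max():
        return None
    fpr, tpr, thr = roc(conf.to_numpy(), truth.to_numpy())
    y_thr, j = youden_optimal(fpr, tpr, thr)
    return EvalCurve(
        api_class=api_class,
        label_source=label_source,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        youden_threshold=y_thr,
        youden_j=j,
        auc=auc(conf.to_numpy(), truth.to_numpy()),
        n_pos=int(truth.sum()),
        n_neg=int((1 - truth).sum()),
    )


def compare_sources(
    frames: pd.DataFrame,
    api_classes: Sequence[str] = EVALUABLE_CLASSES,
    label_sources: Sequence[str] = LABEL_SOURCES,
) -> pd.DataFrame:
    """AUC grid: one row per recognizer class, columns per label source.

    Non-evaluable cells hold NaN; n_pos/n_neg columns record the minute
    counts each cell was computed on.
    """
    rows = []
    for cls in api_classes:
        row: dict = {"api_class": cls}
        for source in label_sources:
            curve = evaluate(frames, cls, source)
            if curve is None:
                row[source] = np.nan
                row[f"{source}_n_pos"] = 0
                row[f"{source}_n_neg"] = 0
            else:
                row[source] = curve.auc
                row[f"{source}_n_pos"] = curve.n_pos
                row[f"{source}_n_neg"] = curve.n_neg
        rows.append(row)
    return pd.DataFrame(rows).set_index("api_class")


def error_crosstab(
    frames: pd.DataFrame,
    api_classes: Sequence[str] = ("IN_VEHICLE", "STILL"),
    thresholds: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Detected/not-detected counts per consensus class for chosen classes.

    Predictions are thresholded at the supplied confidence thresholds (by
    default the Youden-optimal threshold of each class evaluated against
    consensus labels).  Rows are consensus classes; columns are
    ``<class>_detected`` / ``<class>_not_detected`` minute counts over
    consensus-labeled minutes with confidences present.
    """
    sub = frames[frames["consensus_label"] != EXCLUDED].copy()
    sub = sub[sub["api_confidences"].map(lambda c: isinstance(c, dict))]
    activities = [a.value for a in Activity]
    out = pd.DataFrame(
        0,
        index=activities,
        columns=[f"{c}_{s}" for c in api_classes for s in ("detected", "not_detected")],
        dtype=int,
    )
    out.index.name = "consensus_label"
    if sub.empty:
        return out
    for cls in api_classes:
        if thresholds is not None and cls in thresholds:
            thr = float(thresholds[cls])
        else:
            curve = evaluate(frames, cls, "consensus")
            if curve is None:
                continue
            thr = curve.youden_threshold
        conf = sub["api_confidences"].map(lambda c: float(c.get(cls, 0.0)))
        detected = conf >= thr
        for act in activities:
            rows = sub["consensus_label"] == act
            out.loc[act, f"{cls}_detected"] = int((rows & detected).sum())
            out.loc[act, f"{cls}_not_detected"] = int((rows & ~detected).sum())
    return out


def read_api_csv(path: str) -> pd.DataFrame:
    """Read the confidence CSV into a frame-joinable table.

    Returns participant_id, minute_start and an ``api_confidences`` dict
    column keyed by upper-case recognizer class names.
    """
    df = pd.read_csv(path, parse_dates=["minute_start"])
    class_cols = [c for c in API_CSV_COLUMNS[2:] if c in df.columns]
    conf = [
        {c.upper(): float(v) for c, v in zip(class_cols, row)}
        for row in df[class_cols].to_numpy()
    ]
    return pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "minute_start": df["minute_start"],
            "api_confidences": conf,
        }
    )


def attach_confidences(frames: pd.DataFrame, api: pd.DataFrame) -> pd.DataFrame:
    """Left-join recognizer confidences onto the minute frames."""
    return frames.merge(
        api[["participant_id", "minute_start", "api_confidences"]],
        on=["participant_id", "minute_start"],
        how="left",
    )
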