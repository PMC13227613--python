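"""Triangulation of thigh epoch labels with verbal minute label sets.

A minute receives a consensus label only when the smartwatch was worn, the
thigh sensor produced a valid epoch label, and that label is a member of
the verbal report's label set for the minute — composite reports
contribute only when they contain the sensor's label.  The module also
produces the accounting artifacts: per-participant and per-activity
shrinkage tables, and the singleton-only thigh-vs-verbal confusion matrix.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._util import percent
from .activity_scheme import EXCLUDED, Activity

ACTIVITY_ORDER = [a.value for a in Activity]


def triangulate(
    thigh: pd.DataFrame,
    verbal: pd.DataFrame,
    wear_mask: pd.DataFrame,
) -> pd.DataFrame:
    """Build the per-minute frame ledger with consensus labels.

    Parameters
    ----------
    thigh
        Labeled epochs: participant_id, minute_start, label.
    verbal
        Minute label sets: participant_id, minute_start, labels (frozenset).
    wear_mask
        participant_id, minute_start, worn (0/1).

    Returns
    -------
    DataFrame with participant_id, minute_start, worn, thigh_label,
    verbal_labels, consensus_label.  The grid is the union of thigh and
    wear-mask minutes; minutes absent from the mask count as unworn.
    """
    for name, df in (("thigh", thigh), ("verbal", verbal), ("wear_mask", wear_mask)):
        if df.duplicated(["participant_id", "minute_start"]).any():
            raise ValueError(f"duplicate participant/minute keys in {name} input")

    t = thigh[["participant_id", "minute_start", "label"]].rename(
        columns={"label": "thigh_label"}
    )
    w = wear_mask[["participant_id", "minute_start", "worn"]]
    frames = t.merge(w, on=["participant_id", "minute_start"], how="outer")
    frames["worn"] = frames["worn"].fillna(0).astype(bool)
    frames["thigh_label"] = frames["thigh_label"].fillna(EXCLUDED)

    v = verbal[["participant_id", "minute_start", "labels"]].rename(
        columns={"labels": "verbal_labels"}
    )
    frames = frames.merge(v, on=["participant_id", "minute_start"], how="left")
    empty = frozenset()
    frames["verbal_labels"] = frames["verbal_labels"].map(
        lambda s: s if isinstance(s, frozenset) else empty
    )

    thigh_lab = frames["thigh_label"].to_numpy()
    worn = frames["worn"].to_numpy()
    vsets = frames["verbal_labels"].to_numpy()
    consensus = np.full(len(frames), EXCLUDED, dtype=object)
    for i in range(len(frames)):
        lab = thigh_lab[i]
        if worn[i] and lab != EXCLUDED and Activity(lab) in vsets[i]:
            consensus[i] = lab
    frames["consensus_label"] = consensus
    return frames.sort_values(["participant_id", "minute_start"]).reset_index(drop=True)


@dataclass
class ShrinkageReport:
    """Stage counts and retention ratios, per participant and per activity.

    ``per_participant`` columns: thigh_min (all thigh epochs), imu_min
    (worn minutes), verbal_min (worn minutes with verbal labels),
    consensus_min, agreement_pct (= consensus/verbal), retention_pct
    (= consensus/imu).  ``per_activity`` columns: thigh_min,
    thigh_labeled_imu_min (worn minutes the thigh labeled with the
    activity), verbal_labeled_imu_min, consensus_min, retention_pct
    (= consensus/thigh-labeled IMU).  Percentages are half-up integers;
    full-precision ratios are kept in the ``*_frac`` columns.
    """

    per_participant: pd.DataFrame
    per_activity: pd.DataFrame
    totals: dict

    @classmethod
    def from_frames(cls, frames: pd.DataFrame) -> "ShrinkageReport":
        worn = frames["worn"]
        thigh_valid = frames["thigh_label"] != EXCLUDED
        verbal_any = frames["verbal_labels"].map(bool)
        cons_valid = frames["consensus_label"] != EXCLUDED

        g = frames.assign(
            thigh_min=1,
            imu_min=worn.astype(int),
            verbal_min=(worn & verbal_any).astype(int),
            consensus_min=cons_valid.astype(int),
        ).groupby("participant_id")[["thigh_min", "imu_min", "verbal_min", "consensus_min"]]
        per_participant = g.sum()

        rows = {}
        for act in ACTIVITY_ORDER:
            is_thigh = frames["thigh_label"] == act
            rows[act] = {
                "thigh_min": int(is_thigh.sum()),
                "thigh_labeled_imu_min": int((is_thigh & worn).sum()),
                "verbal_labeled_imu_min": int(
                    (worn & frames["verbal_labels"].map(lambda s: Activity(act) in s)).sum()
                ),
                "consensus_min": int((frames["consensus_label"] == act).sum()),
            }
        per_activity = pd.DataFrame.from_dict(rows, orient="index")
        per_activity.index.name = "activity"
        return cls.from_counts(per_participant, per_activity)

    @classmethod
    def from_counts(
        cls, per_participant: pd.DataFrame, per_activity: pd.DataFrame
    ) -> "ShrinkageReport":
        """Finish a report from raw stage counts (pipeline output or a
        printed-table fixture)."""
        pp = per_participant.copy()
        pa = per_activity.copy()

        def _ratio(df, num, den, name):
            frac = df[num] / df[den].where(df[den] != 0)
            df[name + "_frac"] = frac
            df[name + "_pct"] = frac.map(
                lambda f: percent(f, 1.0) if pd.notna(f) else np.nan
            )

        _ratio(pp, "consensus_min", "verbal_min", "agreement")
        _ratio(pp, "consensus_min", "imu_min", "retention")
        _ratio(pa, "consensus_min", "thigh_labeled_imu_min", "retention")

        tot_pp = pp[["thigh_min", "imu_min", "verbal_min", "consensus_min"]].sum()
        totals = {k: int(v) for k, v in tot_pp.items()}
        _pct = lambda num, den: percent(num, den) if den else np.nan
        totals["agreement_pct"] = _pct(totals["consensus_min"], totals["verbal_min"])
        totals["retention_pct"] = _pct(totals["consensus_min"], totals["imu_min"])
        # alternative denominator: thigh-labeled IMU minutes summed by activity
        denom_labeled = int(pa["thigh_labeled_imu_min"].sum())
        totals["thigh_labeled_imu_min"] = denom_labeled
        if denom_labeled:
            totals["retention_vs_labeled_pct"] = percent(
                int(pa["consensus_min"].sum()), denom_labeled
            )
        return cls(per_participant=pp, per_activity=pa, totals=totals)


def shrinkage(frames: pd.DataFrame) -> ShrinkageReport:
    if frames.empty or frames["participant_id"].nunique() == 0:
        raise ValueError("shrinkage of an empty cohort")
    return ShrinkageReport.from_frames(frames)


@dataclass
class ConfusionMatrix:
    """Thigh (rows) vs verbal (columns) minute counts with row shares."""

    counts: pd.DataFrame
    proportions: pd.DataFrame

    @property
    def empty(self) -> bool:
        return int(self.counts.to_numpy().sum()) == 0


def confusion(frames: pd.DataFrame, singleton_only: bool = True) -> ConfusionMatrix:
    """Minute-count confusion matrix between thigh and verbal labels.

    Only minutes with a valid thigh label, the smartwatch worn, and (by
    default) a singleton verbal label set are counted; rows are normalized
    by thigh totals.
    """
    mask = (frames["thigh_label"] != EXCLUDED) & frames["worn"]
    sizes = frames["verbal_labels"].map(len)
    mask &= (sizes == 1) if singleton_only else (sizes >= 1)
    sub = frames[mask]

    counts = pd.DataFrame(0, index=ACTIVITY_ORDER, columns=ACTIVITY_ORDER, dtype=int)
    for t_lab, vset in zip(sub["thigh_label"], sub["verbal_labels"]):
        for v in vset:
            counts.loc[t_lab, v.value] += 1
    row_sums = counts.sum(axis=1)
    proportions = counts.div(row_sums.where(row_sums > 0), axis=0)
    return ConfusionMatrix(counts=counts, proportions=proportions)


def render_tables(
    report: ShrinkageReport,
    matrix: Optional[ConfusionMatrix],
    outdir: str,
    metadata: Optional[dict] = None,
) -> dict:
    """Write the shrinkage tables, confusion matrix, and a JSON summary."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "table5": os.path.join(outdir, "table5.csv"),
        "table6": os.path.join(outdir, "table6.csv"),
        "confusion": os.path.join(outdir, "confusion.csv"),
        "summary": os.path.join(outdir, "summary.json"),
    }
    report.per_participant.to_csv(paths["table5"])
    report.per_activity.to_csv(paths["table6"])
    if matrix is not None and not matrix.empty:
        matrix.counts.to_csv(paths["confusion"])
    else:
        with open(paths["confusion"], "w") as fh:
            fh.write("# no data\n")
    summary = {
        "totals": report.totals,
        "per_participant": json.loads(report.per_participant.to_json(orient="index")),
        "per_activity": json.loads(report.per_activity.to_json(orient="index")),
        "notes": {
            "agreement_definition": "consensus minutes / verbally labeled worn minutes",
            "tilting_unknown": "recognizer TILTING/UNKNOWN minutes carry no posture "
            "semantics and are excluded from all evaluations",
        },
    }
    if metadata:
        summary["metadata"] = metadata
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return paths
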