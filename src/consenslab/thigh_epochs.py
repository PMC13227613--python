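"""Per-minute thigh-sensor epoch labeling.

The thigh sensor exports one row per participant-minute with the seconds
spent in each of its own classes.  Three leaves of the activity scheme are
derived by aggregation/subtraction (lying, sitting not in transport,
standing); the epoch label is the unique leaf present for strictly more
than 30 seconds; minutes without such a majority are excluded.  A winning
stepping epoch is refined into an intensity sub-label using personalized
cadence thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .activity_scheme import EXCLUDED, Activity
from .cadence import CadenceThresholds

log = logging.getLogger(__name__)

#: columns of the epoch CSV holding raw per-class seconds
RAW_SECOND_COLUMNS = (
    "sedentary_s",
    "sitting_transport_s",
    "lying_primary_s",
    "lying_secondary_s",
    "upright_s",
    "stepping_s",
    "cycling_s",
)

EPOCH_CSV_COLUMNS = (
    "participant_id",
    "minute_start",
    *RAW_SECOND_COLUMNS,
    "steps",
    "met",
)

#: default epoch-majority boundary in seconds; strictly "exceeding"
MAJORITY_SECONDS = 30.0

#: derived-duration keys competing for the epoch label, paired with leaves
_COMPETING = (
    ("lying", Activity.LYING),
    ("sitting_not_in_transport", Activity.SITTING_NOT_IN_TRANSPORT),
    ("sitting_in_transport", Activity.SITTING_IN_TRANSPORT),
    ("standing", Activity.STANDING),
    ("stepping", None),  # refined by cadence
    ("cycling", Activity.CYCLING),
)

_CLAMP_TOLERANCE_S = 1.0


@dataclass
class EpochLabel:
    participant_id: str
    minute_start: pd.Timestamp
    label: Activity | str  # leaf or EXCLUDED
    basis_seconds: float


def derive_durations(seconds: Mapping[str, float]) -> dict[str, float]:
    """Augment a raw second composition with the derived leaf durations.

    lying = lying_primary + lying_secondary;
    sitting_not_in_transport = sedentary - sitting_in_transport;
    standing = upright - stepping - cycling.

    Small negative results of the subtractions (within 1 s, rounding noise)
    are clamped to zero with a warning; larger ones mark the record invalid.
    """
    get = lambda k: float(seconds.get(k, 0.0))
    out = {
        "lying": get("lying_primary_s") + get("lying_secondary_s"),
        "sitting_in_transport": get("sitting_transport_s"),
        "stepping": get("stepping_s"),
        "cycling": get("cycling_s"),
    }
    snt = get("sedentary_s") - get("sitting_transport_s")
    standing = get("upright_s") - get("stepping_s") - get("cycling_s")
    for key, value in (("sitting_not_in_transport", snt), ("standing", standing)):
        if value < -_CLAMP_TOLERANCE_S:
            raise ValueError(
                f"derived duration {key} = {value:.2f} s is negative beyond "
                f"rounding tolerance; record is invalid"
            )
        if value < 0:
            log.warning("clamping %s from %.3f s to 0", key, value)
            value = 0.0
        out[key] = value
    return out


def classify_stepping_intensity(
    steps: float, thresholds: CadenceThresholds
) -> Activity:
    """Stepping intensity sub-label from the minute's cadence.

    Boundaries are inclusive on the higher-intensity side: ``steps >= theta``
    goes to the higher class.  With no vigorous threshold, everything at or
    above theta_lm is moderate.
    """
    if steps < 0:
        raise ValueError(f"negative step count: {steps}")
    if steps < thresholds.theta_lm:
        return Activity.LOW_STEPPING
    if thresholds.theta_mv is None or steps < thresholds.theta_mv:
        return Activity.MODERATE_STEPPING
    return Activity.VIGOROUS_STEPPING


def assign_epoch_label(
    seconds: Mapping[str, float],
    steps: float = 0.0,
    thresholds: Optional[CadenceThresholds] = None,
    majority_s: float = MAJORITY_SECONDS,
) -> tuple[Activity | str, float]:
    """Label one epoch from its raw second composition.

    Returns ``(label, basis_seconds)``; the label is the unique leaf whose
    derived duration strictly exceeds ``majority_s``, or the excluded
    sentinel when none does.  A stepping win requires cadence thresholds.
    """
    derived = derive_durations(seconds)
    winners = [
        (key, leaf, derived[key]) for key, leaf in _COMPETING if derived[key] > majority_s
    ]
    if not winners:
        return EXCLUDED, 0.0
    if len(winners) > 1:  # impossible within a 60 s epoch
        raise RuntimeError(f"multiple majority durations in one epoch: {winners}")
    key, leaf, basis = winners[0]
    if key == "stepping":
        if thresholds is None:
            raise ValueError(
                "stepping epoch requires cadence thresholds to refine intensity"
            )
        leaf = classify_stepping_intensity(steps, thresholds)
    return leaf, basis


def label_epochs(
    epochs: pd.DataFrame,
    thresholds: Mapping[str, CadenceThresholds],
    majority_s: float = MAJORITY_SECONDS,
) -> pd.DataFrame:
    """Vectorized epoch labeling of a full epoch table.

    Parameters
    ----------
    epochs
        Table in the epoch CSV schema (see :data:`EPOCH_CSV_COLUMNS`).
    thresholds
        Per-participant cadence thresholds, keyed by participant id.

    Returns
    -------
    DataFrame with columns participant_id, minute_start, label,
    basis_seconds.
    """
    df = epochs
    sec = {c: df[c].to_numpy(dtype=float) for c in RAW_SECOND_COLUMNS if c in df}
    for c in RAW_SECOND_COLUMNS:
        sec.setdefault(c, np.zeros(len(df)))

    lying = sec["lying_primary_s"] + sec["lying_secondary_s"]
    snt = sec["sedentary_s"] - sec["sitting_transport_s"]
    standing = sec["upright_s"] - sec["stepping_s"] - sec["cycling_s"]
    for name, arr in (("sitting_not_in_transport", snt), ("standing", standing)):
        bad = arr < -_CLAMP_TOLERANCE_S
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} epochs have negative derived {name} beyond tolerance"
            )
        np.clip(arr, 0.0, None, out=arr)

    durations = np.column_stack(
        [lying, snt, sec["sitting_transport_s"], standing, sec["stepping_s"], sec["cycling_s"]]
    )
    exceeds = durations > majority_s
    n_win = exceeds.sum(axis=1)
    if (n_win > 1).any():
        raise RuntimeError("multiple majority durations in a single epoch")

    winner = np.where(n_win == 1, exceeds.argmax(axis=1), -1)
    basis = np.where(winner >= 0, durations[np.arange(len(df)), winner], 0.0)

    leaf_by_idx = np.array(
        [
            Activity.LYING.value,
            Activity.SITTING_NOT_IN_TRANSPORT.value,
            Activity.SITTING_IN_TRANSPORT.value,
            Activity.STANDING.value,
            "stepping",
            Activity.CYCLING.value,
        ]
    )
    labels = np.where(winner >= 0, leaf_by_idx[winner], EXCLUDED)

    stepping_mask = labels == "stepping"
    if stepping_mask.any():
        steps = df["steps"].to_numpy(dtype=float)
        pids = df["participant_id"].to_numpy()
        refined = np.empty(stepping_mask.sum(), dtype=object)
        for i, (pid, s) in enumerate(zip(pids[stepping_mask], steps[stepping_mask])):
            try:
                thr = thresholds[pid]
            except KeyError:
                raise KeyError(f"no cadence thresholds for participant {pid!r}") from None
            refined[i] = classify_stepping_intensity(s, thr).value
        labels = labels.astype(object)
        labels[stepping_mask] = refined

    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "minute_start": pd.to_datetime(df["minute_start"]).dt.floor("min"),
            "label": labels,
            "basis_seconds": basis,
        }
    )


def exclusion_rate(labels: Iterable[str] | pd.Series) -> float:
    """Fraction of excluded (no >30 s majority) epochs."""
    arr = pd.Series(list(labels) if not isinstance(labels, pd.Series) else labels)
    if len(arr) == 0:
        raise ValueError("exclusion_rate of an empty collection")
    return float((arr.astype(str) == EXCLUDED).mean())


def read_epoch_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["minute_start"])
    missing = set(EPOCH_CSV_COLUMNS) - {"met"} - set(df.columns)
    if missing:
        raise ValueError(f"epoch CSV missing columns: {sorted(missing)}")
    return df


def write_labeled_csv(labels: pd.DataFrame, path: str) -> None:
    labels.to_csv(path, index=False)
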