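"""Loaders for the packaged reference tables (study-report fixtures).

These small CSV/JSON resources encode the published accounting tables of
the reference deployment — per-participant and per-activity stage counts,
the time-cue style counts, and the event-expansion/exclusion counts — in
the exact schemas the pipeline's own reports use, so the same ratio code
runs on both.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .consensus import ShrinkageReport


def _read_csv(name: str, **kwargs) -> pd.DataFrame:
    src = resources.files("consenslab.data").joinpath(name)
    with resources.as_file(src) as p:
        return pd.read_csv(p, **kwargs)


def load_participant_counts() -> pd.DataFrame:
    """Per-participant stage counts (minutes per stage + entry counts)."""
    return _read_csv("shrinkage_participants.csv", index_col="participant_id")


def load_activity_counts() -> pd.DataFrame:
    """Per-activity stage counts."""
    return _read_csv("shrinkage_activities.csv", index_col="activity")


def load_style_counts() -> pd.Series:
    """Counts of the ten time-cue styles."""
    df = _read_csv("time_cue_styles.csv")
    return df.set_index("style")["count"]


def load_event_accounting() -> dict:
    """Entry/event expansion and exclusion counts."""
    raw = resources.files("consenslab.data").joinpath("event_accounting.json").read_text()
    return json.loads(raw)


def reference_shrinkage_report() -> ShrinkageReport:
    """ShrinkageReport built from the fixture stage counts.

    Runs the same ratio/rounding code the pipeline applies to its own
    counts.
    """
    pp = load_participant_counts()[
        ["thigh_min", "imu_min", "verbal_min", "consensus_min"]
    ]
    pa = load_activity_counts()
    return ShrinkageReport.from_counts(pp, pa)
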