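"""Verbal self-report processing: interval reconstruction and minute projection.

Structured annotations of verbal activity reports arrive as entries, each
holding one or more activity events.  Every event carries a label set
(empty = undefined), a time-cue style, and whatever cue fields the style
provides.  The seven complete styles (C1-C7) are reconstructed into
half-open intervals; the incomplete styles (I1-I3) cannot be and are
excluded.  Retained events are projected onto the shared minute grid.

Time-cue styles:

========  ==========================================================
C1        end = report time, start = end - stated duration
C2        start = previous report time, end = report time
C3        ongoing at the report; a short configurable window is used
C4        start and end stated explicitly
C5        start/end resolved across reports (supplied pre-resolved)
C6        start stated, end = report time
C7        start = report time, end = start + stated duration
I1-I3     insufficient cues; excluded
========  ==========================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import MINUTE, floor_minute
from .activity_scheme import Activity

log = logging.getLogger(__name__)

COMPLETE_STYLES = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")
INCOMPLETE_STYLES = ("I1", "I2", "I3")
CUE_STYLES = COMPLETE_STYLES + INCOMPLETE_STYLES

DEFAULT_C3_WINDOW_MIN = 1
DEFAULT_COVERAGE_S = 30.0


@dataclass
class ActivityEvent:
    """One verbally reported activity event."""

    participant_id: str
    report_time: pd.Timestamp
    labels: frozenset  # of Activity; empty => undefined
    cue_style: str
    stated_start: Optional[pd.Timestamp] = None
    stated_end: Optional[pd.Timestamp] = None
    stated_duration_min: Optional[float] = None
    raw_text: Optional[str] = None
    interval: Optional[tuple] = None  # reconstructed [start, end) or None

    @property
    def event_class(self) -> str:
        if not self.labels:
            return "undefined"
        return "singleton" if len(self.labels) == 1 else "composite"


@dataclass
class VerbalEntry:
    """One voice recording; holds >= 1 sequential activity events."""

    participant_id: str
    report_time: pd.Timestamp
    events: list = field(default_factory=list)
    raw_text: Optional[str] = None


@dataclass
class ExpansionTally:
    entries_total: int = 0
    entries_expanded: int = 0
    events_added: int = 0

    @property
    def events_total(self) -> int:
        """entries - expanded entries + events the expansions produced."""
        return self.entries_total - self.entries_expanded + self.events_added


@dataclass
class ExclusionTally:
    retained: int = 0
    no_time: int = 0
    no_label: int = 0
    both: int = 0
    not_worn: int = 0
    truncated: int = 0  # retained but clipped to worn minutes

    @property
    def excluded(self) -> int:
        return self.no_time + self.no_label + self.both + self.not_worn

    @property
    def total(self) -> int:
        return self.retained + self.excluded


def reconstruct_interval(
    event: ActivityEvent,
    prev_report_time: Optional[pd.Timestamp] = None,
    c3_window_min: float = DEFAULT_C3_WINDOW_MIN,
) -> Optional[tuple]:
    """Reconstruct the half-open [start, end) interval for one event.

    Returns None (the excluded sentinel) for I-styles, for missing required
    cue fields, and for degenerate intervals (end <= start).
    """
    style = event.cue_style
    if style not in CUE_STYLES:
        raise ValueError(f"unknown time-cue style: {style!r}")
    if style in INCOMPLETE_STYLES:
        return None

    rt = pd.Timestamp(event.report_time)
    dur = (
        pd.Timedelta(minutes=float(event.stated_duration_min))
        if event.stated_duration_min is not None
        else None
    )

    if style == "C1":
        if dur is None:
            log.warning("C1 event without stated duration; excluded")
            return None
        start, end = rt - dur, rt
    elif style == "C2":
        if prev_report_time is None:
            log.warning("C2 event without a previous report; excluded")
            return None
        start, end = pd.Timestamp(prev_report_time), rt
    elif style == "C3":
        start, end = rt, rt + pd.Timedelta(minutes=c3_window_min)
    elif style in ("C4", "C5"):
        if event.stated_start is None or event.stated_end is None:
            log.warning("%s event missing resolved start/end; excluded", style)
            return None
        start, end = pd.Timestamp(event.stated_start), pd.Timestamp(event.stated_end)
    elif style == "C6":
        if event.stated_start is None:
            log.warning("C6 event without stated start; excluded")
            return None
        start, end = pd.Timestamp(event.stated_start), rt
    else:  # C7
        if dur is None:
            log.warning("C7 event without stated duration; excluded")
            return None
        start, end = rt, rt + dur

    if end <= start:
        log.warning(
            "degenerate interval for %s event at %s; excluded", style, event.report_time
        )
        return None
    return (start, end)


def reconstruct_all(
    entries: Sequence[VerbalEntry],
    c3_window_min: float = DEFAULT_C3_WINDOW_MIN,
) -> None:
    """Reconstruct intervals for every event in report-time order, in place.

    The previous report time used by C2 events is the report time of the
    participant's preceding entry.
    """
    by_pid: dict[str, list[VerbalEntry]] = {}
    for entry in entries:
        by_pid.setdefault(entry.participant_id, []).append(entry)
    for pid, group in by_pid.items():
        group.sort(key=lambda e: pd.Timestamp(e.report_time))
        prev = None
        for entry in group:
            for ev in entry.events:
                ev.interval = reconstruct_interval(ev, prev, c3_window_min)
            prev = pd.Timestamp(entry.report_time)


def expand_entries(
    entries: Iterable[VerbalEntry],
) -> tuple[list[ActivityEvent], ExpansionTally]:
    """Flatten entries to events; series entries split into their events."""
    tally = ExpansionTally()
    events: list[ActivityEvent] = []
    for entry in entries:
        tally.entries_total += 1
        if len(entry.events) == 0:
            raise ValueError("entry with no events")
        if len(entry.events) > 1:
            tally.entries_expanded += 1
            tally.events_added += len(entry.events)
        events.extend(entry.events)
    return events, tally


def apply_exclusions(
    events: Iterable[ActivityEvent],
    wear_mask: Optional[pd.DataFrame] = None,
    coverage_s: float = DEFAULT_COVERAGE_S,
) -> tuple[list[ActivityEvent], ExclusionTally]:
    """Drop events lacking time or labels, and events wholly unworn.

    Reasons are mutually exclusive: ``no_time`` (no reconstructable
    interval), ``no_label`` (undefined), ``both``, and ``not_worn`` (none of
    the event's covered minutes has the smartwatch worn).  Events straddling
    a worn/unworn boundary are retained and counted as truncated; the
    unworn minutes are dropped at projection time.
    """
    worn_lookup = _worn_lookup(wear_mask) if wear_mask is not None else None
    tally = ExclusionTally()
    retained: list[ActivityEvent] = []
    for ev in events:
        has_time = ev.interval is not None
        has_label = bool(ev.labels)
        if not has_time and not has_label:
            tally.both += 1
            continue
        if not has_time:
            tally.no_time += 1
            continue
        if not has_label:
            tally.no_label += 1
            continue
        if worn_lookup is not None:
            minutes = _covered_minutes(ev.interval, coverage_s)
            worn = [m for m in minutes if worn_lookup.get((ev.participant_id, m), False)]
            if minutes and not worn:
                tally.not_worn += 1
                continue
            if len(worn) < len(minutes):
                tally.truncated += 1
        tally.retained += 1
        retained.append(ev)
    return retained, tally


def project_to_minutes(
    events: Iterable[ActivityEvent],
    coverage_s: float = DEFAULT_COVERAGE_S,
    wear_mask: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Project retained events onto the minute grid.

    A minute receives an event's label set when the event overlaps it by at
    least ``coverage_s`` seconds (default 30, mirroring the epoch rule).
    Overlapping events union their label sets.  Minutes with the smartwatch
    unworn are dropped when a wear mask is given.

    Returns a DataFrame with participant_id, minute_start, labels
    (frozenset of Activity) and n_events.
    """
    worn_lookup = _worn_lookup(wear_mask) if wear_mask is not None else None
    acc: dict[tuple, set] = {}
    nev: dict[tuple, int] = {}
    for ev in events:
        if ev.interval is None or not ev.labels:
            continue
        for m in _covered_minutes(ev.interval, coverage_s):
            key = (ev.participant_id, m)
            if worn_lookup is not None and not worn_lookup.get(key, False):
                continue
            acc.setdefault(key, set()).update(ev.labels)
            nev[key] = nev.get(key, 0) + 1
    rows = [
        {
            "participant_id": pid,
            "minute_start": minute,
            "labels": frozenset(labels),
            "n_events": nev[(pid, minute)],
        }
        for (pid, minute), labels in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["participant_id", "minute_start", "labels", "n_events"])


def _covered_minutes(interval: tuple, coverage_s: float) -> list:
    """Grid minutes the interval overlaps by >= coverage_s seconds."""
    start, end = interval
    out = []
    m = floor_minute(start)
    while m < end:
        overlap = (min(end, m + MINUTE) - max(start, m)).total_seconds()
        if overlap >= coverage_s:
            out.append(m)
        m += MINUTE
    return out


def _worn_lookup(wear_mask: pd.DataFrame) -> dict:
    minutes = pd.to_datetime(wear_mask["minute_start"])
    return {
        (pid, m): bool(w)
        for pid, m, w in zip(wear_mask["participant_id"], minutes, wear_mask["worn"])
    }


# --- file formats -----------------------------------------------------------

EVENT_CSV_COLUMNS = (
    "participant_id",
    "report_time",
    "event_index",
    "labels",
    "cue_style",
    "stated_start",
    "stated_end",
    "stated_duration_min",
    "raw_text",
)


def read_events_csv(path: str) -> list[VerbalEntry]:
    """Parse the events CSV into entries (grouped by participant + report)."""
    df = pd.read_csv(path, dtype={"labels": "string", "raw_text": "string"})
    for col in ("report_time", "stated_start", "stated_end"):
        df[col] = pd.to_datetime(df[col])
    entries: dict[tuple, VerbalEntry] = {}
    for row in df.itertuples(index=False):
        key = (row.participant_id, row.report_time)
        entry = entries.get(key)
        if entry is None:
            entry = VerbalEntry(
                participant_id=str(row.participant_id), report_time=row.report_time
            )
            entries[key] = entry
        raw_labels = "" if pd.isna(row.labels) else str(row.labels)
        labels = frozenset(Activity(name) for name in raw_labels.split("|") if name)
        entry.events.append(
            ActivityEvent(
                participant_id=str(row.participant_id),
                report_time=row.report_time,
                labels=labels,
                cue_style=str(row.cue_style),
                stated_start=None if pd.isna(row.stated_start) else row.stated_start,
                stated_end=None if pd.isna(row.stated_end) else row.stated_end,
                stated_duration_min=(
                    None if pd.isna(row.stated_duration_min) else float(row.stated_duration_min)
                ),
                raw_text=None if pd.isna(row.raw_text) else str(row.raw_text),
            )
        )
    return list(entries.values())


def entries_to_csv(entries: Sequence[VerbalEntry], path: str) -> None:
    rows = []
    for entry in entries:
        for i, ev in enumerate(entry.events):
            rows.append(
                {
                    "participant_id": ev.participant_id,
                    "report_time": ev.report_time,
                    "event_index": i,
                    "labels": "|".join(sorted(a.value for a in ev.labels)),
                    "cue_style": ev.cue_style,
                    "stated_start": ev.stated_start,
                    "stated_end": ev.stated_end,
                    "stated_duration_min": ev.stated_duration_min,
                    "raw_text": ev.raw_text,
                }
            )
    pd.DataFrame(rows, columns=EVENT_CSV_COLUMNS).to_csv(path, index=False)


def write_minutes_csv(minutes: pd.DataFrame, path: str) -> None:
    out = minutes.copy()
    out["labels"] = out["labels"].map(
        lambda s: "|".join(sorted(a.value for a in s))
    )
    out.to_csv(path, index=False)


def read_minutes_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["minute_start"])
    df["labels"] = df["labels"].map(
        lambda s: frozenset(Activity(name) for name in str(s).split("|") if name)
    )
    return df
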