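"""Synthetic multi-source cohort generator.

Produces the four input streams the pipeline consumes — thigh-sensor epoch
tables, verbal-report entries, recognizer confidence streams, and a
smartwatch wear mask — from a shared ground-truth activity timeline, with
the statistical structure the analysis assumes: a semi-Markov day
structure with an overnight lying block, minute alternation between
classes (driving the excluded-epoch rate), posture-confusion channels,
intensity-dependent verbal under-reporting with the full time-cue style
mix, recall noise, and recognizer error modes (motorized-tool vehicle
false positives, idle-vehicle misses, cycling with a still wrist).

Everything is deterministic under ``(config, seed)``; one global seed
feeds per-participant substreams via spawned seed sequences, so adding
participants never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._util import MINUTE
from .activity_scheme import Activity, api_label_set
from .verbal_events import ActivityEvent, VerbalEntry, entries_to_csv

_A = Activity  # shorthand

#: fractions of the ten time-cue styles among reported events (reference
#: deployment counts over 1357 events)
_STYLE_COUNTS = {
    "C1": 440, "C2": 297, "C3": 259, "C4": 87, "C5": 69,
    "C6": 59, "C7": 47, "I1": 52, "I2": 33, "I3": 14,
}
DEFAULT_STYLE_PROBS = {s: c / 1357 for s, c in _STYLE_COUNTS.items()}

DEFAULT_DWELL_MEAN = {
    _A.LYING: 45.0,
    _A.SITTING_NOT_IN_TRANSPORT: 40.0,
    _A.SITTING_IN_TRANSPORT: 16.0,
    _A.STANDING: 10.0,
    _A.LOW_STEPPING: 8.0,
    _A.MODERATE_STEPPING: 22.0,
    _A.VIGOROUS_STEPPING: 16.0,
    _A.CYCLING: 25.0,
}

DEFAULT_CLASS_WEIGHTS = {
    _A.LYING: 0.02,
    _A.SITTING_NOT_IN_TRANSPORT: 0.37,
    _A.SITTING_IN_TRANSPORT: 0.07,
    _A.STANDING: 0.25,
    _A.LOW_STEPPING: 0.19,
    _A.MODERATE_STEPPING: 0.06,
    _A.VIGOROUS_STEPPING: 0.02,
    _A.CYCLING: 0.02,
}

#: probability an episode overlapping worn time is verbally reported;
#: calibrated so low-intensity activities are under-reported and
#: high-intensity ones over-reported, as the study observed
DEFAULT_REPORT_COVERAGE = {
    _A.LYING: 0.30,
    _A.SITTING_NOT_IN_TRANSPORT: 0.45,
    _A.SITTING_IN_TRANSPORT: 0.60,
    _A.STANDING: 0.30,
    _A.LOW_STEPPING: 0.25,
    _A.MODERATE_STEPPING: 0.80,
    _A.VIGOROUS_STEPPING: 0.95,
    _A.CYCLING: 0.95,
}


@dataclass
class ApiNoise:
    """Recognizer confidence model: class-conditional draws + error modes."""

    tp_mean: float = 82.0
    tp_sd: float = 10.0
    bg_mean: float = 12.0
    bg_sd: float = 9.0
    #: rate at which true Standing minutes get a vehicle-like confidence
    #: (motorized tools vibrate like vehicles)
    motorized_tool_invehicle: float = 0.03
    #: rate at which true transport minutes lose their vehicle confidence
    #: (stopped or idling vehicle)
    idle_vehicle_miss: float = 0.30
    #: rate at which true Cycling minutes look still at the wrist
    cycling_wrist_still: float = 0.10


@dataclass
class CohortConfig:
    n_participants: int = 13
    n_days: int = 7
    start_date: str = "2023-05-01"
    #: wake / bed, minutes from midnight; outside is the overnight lying block
    day_start_min: int = 7 * 60
    day_end_min: int = 22 * 60
    #: smartwatch worn window (~10.3 h/day), start jittered per day
    watch_wear_start_min: int = 8 * 60
    watch_wear_minutes: int = 620
    watch_wear_jitter_min: int = 30

    dwell_mean: dict = field(default_factory=lambda: dict(DEFAULT_DWELL_MEAN))
    dwell_shape: float = 2.0
    class_weights: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))

    #: minute alternation channels on the thigh stream: a two-way split
    #: between the minute's class and a neighbor, and a three-way split
    #: whose excluded-epoch probability is 1/4 (uniform Dirichlet)
    alternation_two_way: float = 0.16
    alternation_three_way: float = 0.052

    #: thigh posture-confusion channels (per-minute rates)
    stool_sitting_as_standing: float = 0.05
    cycling_as_stepping: float = 0.30

    #: verbal label confusion channels (per-event rates), "From>To"
    verbal_confusion: dict = field(
        default_factory=lambda: {
            "Lying>SittingNotInTransport": 0.30,
            "Standing>SittingNotInTransport": 0.25,
        }
    )

    report_coverage: dict = field(default_factory=lambda: dict(DEFAULT_REPORT_COVERAGE))
    style_probs: dict = field(default_factory=lambda: dict(DEFAULT_STYLE_PROBS))
    recall_noise_sd_min: float = 4.0
    report_delay_max_min: float = 3.0
    composite_prob: float = 0.15
    series_prob: float = 0.08
    undefined_prob: float = 0.05

    #: per-participant cadence mixture (low/moderate/vigorous components)
    cadence_means: tuple = (70.0, 110.0, 150.0)
    cadence_sds: tuple = (8.0, 8.0, 8.0)
    cadence_mean_jitter_sd: float = 0.0

    api: ApiNoise = field(default_factory=ApiNoise)

    def __post_init__(self) -> None:
        total = sum(self.style_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"style_probs must sum to 1, got {total}")
        for name, p in self.style_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"style probability {name} out of [0,1]")
        if any(m <= 0 for m in self.dwell_mean.values()):
            raise ValueError("dwell means must be positive")
        if not (
            self.cadence_means[0] < self.cadence_means[1] < self.cadence_means[2]
        ):
            raise ValueError("cadence component means must be ordered low < mod < vig")

    @classmethod
    def zero_noise(cls, **overrides) -> "CohortConfig":
        """A noise-free full-coverage world: the pipeline must recover truth
        exactly on worn minutes."""
        base = dict(
            alternation_two_way=0.0,
            alternation_three_way=0.0,
            stool_sitting_as_standing=0.0,
            cycling_as_stepping=0.0,
            verbal_confusion={},
            report_coverage={a: 1.0 for a in Activity},
            style_probs={"C4": 1.0},
            recall_noise_sd_min=0.0,
            report_delay_max_min=0.0,
            composite_prob=0.0,
            series_prob=0.0,
            undefined_prob=0.0,
            cadence_sds=(0.5, 0.5, 0.5),
            cadence_mean_jitter_sd=0.0,
            api=ApiNoise(
                tp_mean=95.0,
                tp_sd=1.0,
                bg_mean=5.0,
                bg_sd=1.0,
                motorized_tool_invehicle=0.0,
                idle_vehicle_miss=0.0,
                cycling_wrist_still=0.0,
            ),
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dwell_mean"] = {k.value: v for k, v in self.dwell_mean.items()}
        d["class_weights"] = {k.value: v for k, v in self.class_weights.items()}
        d["report_coverage"] = {k.value: v for k, v in self.report_coverage.items()}
        return d


@dataclass
class CohortBundle:
    config: CohortConfig
    seed: int
    truth: pd.DataFrame  # participant_id, minute_start, true_label
    episodes: pd.DataFrame  # participant_id, start, end, label
    wear: pd.DataFrame  # participant_id, minute_start, worn
    thigh: pd.DataFrame  # epoch CSV schema
    entries: list  # of VerbalEntry
    api: pd.DataFrame  # participant_id, minute_start, api_confidences
    book: dict  # generator bookkeeping (oracle values for tests)

    def provenance(self) -> dict:
        return {
            "generator": "consenslab.cohort",
            "version": 1,
            "seed": self.seed,
            "config": self.config.to_dict(),
        }

    def write(self, outdir: str) -> dict:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "thigh": os.path.join(outdir, "thigh_epochs.csv"),
            "events": os.path.join(outdir, "verbal_events.csv"),
            "api": os.path.join(outdir, "api_confidences.csv"),
            "wear": os.path.join(outdir, "wear_mask.csv"),
            "truth": os.path.join(outdir, "truth.csv"),
            "provenance": os.path.join(outdir, "provenance.json"),
        }
        self.thigh.to_csv(paths["thigh"], index=False)
        entries_to_csv(self.entries, paths["events"])
        api_wide = self.api.copy()
        for cls in (
            "STILL",
            "IN_VEHICLE",
            "ON_FOOT",
            "WALKING",
            "RUNNING",
            "ON_BICYCLE",
            "TILTING",
            "UNKNOWN",
        ):
            api_wide[cls.lower()] = [
                round(c.get(cls, 0.0), 4) for c in api_wide["api_confidences"]
            ]
        api_wide.drop(columns=["api_confidences"]).to_csv(paths["api"], index=False)
        self.wear.assign(worn=self.wear["worn"].astype(int)).to_csv(
            paths["wear"], index=False
        )
        self.truth.to_csv(paths["truth"], index=False)
        with open(paths["provenance"], "w") as fh:
            json.dump(self.provenance(), fh, indent=2)
        return paths


def _pid(i: int) -> str:
    return f"S{i + 1:02d}"


# --------------------------------------------------------------------------
# truth timeline


def simulate_truth(
    config: CohortConfig, rng: np.random.Generator, participant_id: str
) -> pd.DataFrame:
    """Semi-Markov episode list for one participant over the study horizon.

    Nights (bed to wake) are single lying episodes; daytime episodes draw a
    class from ``class_weights`` (never repeating the current class) and a
    gamma dwell time.
    """
    weights = config.class_weights
    if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
        raise ValueError("invalid class weights")
    classes = list(weights)
    probs = np.array([weights[c] for c in classes], dtype=float)
    probs /= probs.sum()

    base = pd.Timestamp(config.start_date)
    episodes = []
    t = base  # horizon start: midnight of day 0
    current: Optional[Activity] = None
    for day in range(config.n_days):
        wake = base + pd.Timedelta(days=day, minutes=config.day_start_min)
        bed = base + pd.Timedelta(days=day, minutes=config.day_end_min)
        episodes.append((t, wake, _A.LYING))
        current = _A.LYING
        t = wake
        while t < bed:
            p = probs.copy()
            if current in classes:
                p[classes.index(current)] = 0.0
                if p.sum() > 0:
                    p /= p.sum()
                else:  # degenerate chain: allow self-transition
                    p = probs.copy()
            nxt = classes[rng.choice(len(classes), p=p)]
            shape = config.dwell_shape
            dwell = rng.gamma(shape, config.dwell_mean[nxt] / shape)
            dwell_min = max(1, int(round(dwell)))
            end = min(t + pd.Timedelta(minutes=dwell_min), bed)
            episodes.append((t, end, nxt))
            current = nxt
            t = end
    horizon_end = base + pd.Timedelta(days=config.n_days)
    if t < horizon_end:
        episodes.append((t, horizon_end, _A.LYING))

    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "start": [e[0] for e in episodes],
            "end": [e[1] for e in episodes],
            "label": [e[2].value for e in episodes],
        }
    )


def _episodes_to_minutes(episodes: pd.DataFrame) -> pd.DataFrame:
    pids, minutes, labels = [], [], []
    for row in episodes.itertuples(index=False):
        n = int((row.end - row.start) / MINUTE)
        rng_minutes = pd.date_range(row.start, periods=n, freq="min")
        pids.extend([row.participant_id] * n)
        minutes.append(rng_minutes)
        labels.extend([row.label] * n)
    return pd.DataFrame(
        {
            "participant_id": pids,
            "minute_start": np.concatenate([m.to_numpy() for m in minutes]),
            "true_label": labels,
        }
    )


def _wear_windows(
    config: CohortConfig, rng: np.random.Generator, participant_id: str
) -> list[tuple]:
    base = pd.Timestamp(config.start_date)
    windows = []
    for day in range(config.n_days):
        jitter = (
            rng.integers(-config.watch_wear_jitter_min, config.watch_wear_jitter_min + 1)
            if config.watch_wear_jitter_min
            else 0
        )
        start = base + pd.Timedelta(days=day, minutes=config.watch_wear_start_min + int(jitter))
        end = start + pd.Timedelta(minutes=config.watch_wear_minutes)
        windows.append((start, min(end, base + pd.Timedelta(days=day + 1))))
    return windows


# --------------------------------------------------------------------------
# thigh observation

_STEPPING_SET = {_A.LOW_STEPPING.value, _A.MODERATE_STEPPING.value, _A.VIGOROUS_STEPPING.value}
_STEP_COMPONENT = {
    _A.LOW_STEPPING.value: 0,
    _A.MODERATE_STEPPING.value: 1,
    _A.VIGOROUS_STEPPING.value: 2,
}
_MET_BY_CLASS = {
    _A.LYING.value: 1.0,
    _A.SITTING_NOT_IN_TRANSPORT.value: 1.2,
    _A.SITTING_IN_TRANSPORT.value: 1.3,
    _A.STANDING.value: 1.6,
    _A.LOW_STEPPING.value: 2.3,
    _A.MODERATE_STEPPING.value: 3.5,
    _A.VIGOROUS_STEPPING.value: 5.2,  # built-in estimate underestimates vigorous
    _A.CYCLING.value: 4.5,
}


def observe_thigh(
    truth_minutes: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    cadence_means: np.ndarray,
    cadence_sds: np.ndarray,
) -> tuple[pd.DataFrame, dict]:
    """Thigh-sensor epoch table for one participant's truth minutes.

    Applies per-minute posture-confusion channels, then the alternation
    channels (two-way uniform split; three-way uniform-Dirichlet split with
    analytic exclusion probability 1/4), then composes the raw per-class
    second columns and cadence-based step counts.
    """
    n = len(truth_minutes)
    observed = truth_minutes["true_label"].to_numpy().copy()

    book = {"n_two_way": 0, "n_three_way": 0, "n_stool": 0, "n_cycling_stepping": 0}

    # posture confusion channels
    if config.stool_sitting_as_standing > 0:
        mask = observed == _A.SITTING_NOT_IN_TRANSPORT.value
        flip = mask & (rng.random(n) < config.stool_sitting_as_standing)
        observed[flip] = _A.STANDING.value
        book["n_stool"] = int(flip.sum())
    cyc_component = np.full(n, -1)
    if config.cycling_as_stepping > 0:
        mask = observed == _A.CYCLING.value
        flip = mask & (rng.random(n) < config.cycling_as_stepping)
        # pedaling counted as steps: moderate or vigorous cadence
        comp = np.where(rng.random(n) < 0.5, 1, 2)
        observed[flip] = np.where(
            comp[flip] == 1, _A.MODERATE_STEPPING.value, _A.VIGOROUS_STEPPING.value
        )
        cyc_component[flip] = comp[flip]
        book["n_cycling_stepping"] = int(flip.sum())

    # alternation channels -> (class, seconds) composition per minute
    u = rng.random(n)
    two_way = u < config.alternation_two_way
    three_way = (u >= config.alternation_two_way) & (
        u < config.alternation_two_way + config.alternation_three_way
    )
    book["n_two_way"] = int(two_way.sum())
    book["n_three_way"] = int(three_way.sum())

    sec_cols = {
        c: np.zeros(n)
        for c in (
            "sedentary_s",
            "sitting_transport_s",
            "lying_primary_s",
            "lying_secondary_s",
            "upright_s",
            "stepping_s",
            "cycling_s",
        )
    }
    step_seconds_by_comp = [np.zeros(n), np.zeros(n), np.zeros(n)]

    def _add(cls: str, idx, seconds) -> None:
        if cls == _A.LYING.value:
            sec_cols["lying_primary_s"][idx] += seconds
        elif cls == _A.SITTING_NOT_IN_TRANSPORT.value:
            sec_cols["sedentary_s"][idx] += seconds
        elif cls == _A.SITTING_IN_TRANSPORT.value:
            sec_cols["sedentary_s"][idx] += seconds
            sec_cols["sitting_transport_s"][idx] += seconds
        elif cls == _A.STANDING.value:
            sec_cols["upright_s"][idx] += seconds
        elif cls in _STEPPING_SET:
            sec_cols["upright_s"][idx] += seconds
            sec_cols["stepping_s"][idx] += seconds
            step_seconds_by_comp[_STEP_COMPONENT[cls]][idx] += seconds
        elif cls == _A.CYCLING.value:
            sec_cols["upright_s"][idx] += seconds
            sec_cols["cycling_s"][idx] += seconds
        else:  # pragma: no cover
            raise ValueError(f"unknown class {cls}")

    plain = ~(two_way | three_way)
    for cls in np.unique(observed[plain]):
        idx = np.flatnonzero(plain & (observed == cls))
        _add(cls, idx, 60.0)

    # neighbor class for splits: previous minute's class, else a fixed alternative
    prev = np.roll(observed, 1)
    prev[0] = observed[0]
    for i in np.flatnonzero(two_way | three_way):
        cur = observed[i]
        partner = prev[i]
        if partner == cur:
            partner = (
                _A.STANDING.value
                if cur != _A.STANDING.value
                else _A.SITTING_NOT_IN_TRANSPORT.value
            )
        if two_way[i]:
            frac = rng.random()
            _add(cur, i, 60.0 * frac)
            _add(partner, i, 60.0 * (1.0 - frac))
        else:
            third = _A.STANDING.value
            if third in (cur, partner):
                third = _A.SITTING_NOT_IN_TRANSPORT.value
            if third in (cur, partner):
                third = _A.LOW_STEPPING.value
            parts = rng.dirichlet(np.ones(3)) * 60.0
            for cls, seconds in zip((cur, partner, third), parts):
                _add(cls, i, seconds)

    # cadence draws: one cadence per minute from the dominant stepping component
    steps = np.zeros(n)
    stepping_s = sec_cols["stepping_s"]
    has_steps = stepping_s > 0
    if has_steps.any():
        comp_sec = np.column_stack(step_seconds_by_comp)
        comp = comp_sec.argmax(axis=1)
        # cycling-as-stepping minutes keep the component chosen above
        use_cyc = cyc_component >= 0
        comp[use_cyc] = cyc_component[use_cyc]
        cadence = rng.normal(cadence_means[comp], cadence_sds[comp])
        cadence = np.clip(cadence, 0.0, None)
        steps = np.where(has_steps, np.round(cadence * stepping_s / 60.0), 0.0)

    met = np.array([_MET_BY_CLASS[c] for c in observed]) + rng.normal(0, 0.1, n)

    out = pd.DataFrame(
        {
            "participant_id": truth_minutes["participant_id"].to_numpy(),
            "minute_start": truth_minutes["minute_start"].to_numpy(),
            **{k: np.round(v, 3) for k, v in sec_cols.items()},
            "steps": steps.astype(int),
            "met": np.round(np.clip(met, 0.9, None), 2),
        }
    )
    return out, book


# --------------------------------------------------------------------------
# verbal observation


def observe_verbal(
    episodes: pd.DataFrame,
    wear_windows: list,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[list, dict]:
    """Verbal entries for one participant.

    Each truth episode overlapping worn time is reported with its class's
    coverage probability; reported events get a time-cue style from the
    configured mix, recall noise on stated fields, optional label
    confusion/undefined/composite channels, and are occasionally bundled
    into series entries with explicit transition times.
    """
    styles = list(config.style_probs)
    style_p = np.array([config.style_probs[s] for s in styles])
    style_p = style_p / style_p.sum()

    confusion = {
        tuple(key.split(">")): rate for key, rate in config.verbal_confusion.items()
    }

    book = {
        "n_episodes": 0,
        "n_reported": 0,
        "n_series_entries": 0,
        "n_series_events": 0,
        "n_undefined": 0,
        "n_composite": 0,
        "n_confused": {},
        "style_counts": {s: 0 for s in styles},
    }

    def _clip(start, end):
        best = None
        for w0, w1 in wear_windows:
            lo, hi = max(start, w0), min(end, w1)
            if lo < hi and (best is None or hi - lo > best[1] - best[0]):
                best = (lo, hi)
        return best

    noise = lambda: (
        rng.normal(0.0, config.recall_noise_sd_min) if config.recall_noise_sd_min else 0.0
    )
    delay = lambda: (
        rng.uniform(0.0, config.report_delay_max_min) if config.report_delay_max_min else 0.0
    )

    def _minute(ts) -> pd.Timestamp:
        return pd.Timestamp(ts).round("min")

    reported: list[dict] = []  # {start, end, labels, undefined}
    rows = list(episodes.itertuples(index=False))
    i = 0
    while i < len(rows):
        row = rows[i]
        i += 1
        label = Activity(row.label)
        book["n_episodes"] += 1
        clip = _clip(row.start, row.end)
        if clip is None:
            continue
        if rng.random() >= config.report_coverage.get(label, 1.0):
            continue

        labels = {label}
        if label.value in (k[0] for k in confusion):
            for (src, dst), rate in confusion.items():
                if src == label.value and rng.random() < rate:
                    labels = {Activity(dst)}
                    book["n_confused"][f"{src}>{dst}"] = (
                        book["n_confused"].get(f"{src}>{dst}", 0) + 1
                    )
                    break

        start, end = clip
        merged_next = False
        if config.composite_prob and i < len(rows) and rng.random() < config.composite_prob:
            nxt = rows[i]
            nclip = _clip(nxt.start, nxt.end)
            if nclip is not None and nclip[0] == end:
                labels.add(Activity(nxt.label))
                end = nclip[1]
                book["n_episodes"] += 1
                book["n_composite"] += 1
                merged_next = True
                i += 1

        undefined = bool(config.undefined_prob) and rng.random() < config.undefined_prob
        if undefined:
            labels = set()
            book["n_undefined"] += 1
        reported.append(
            {"start": start, "end": end, "labels": frozenset(labels), "series": False}
        )
        book["n_reported"] += 1

        # series entry: bundle the following episode as a second event with
        # explicit transition times
        if (
            not merged_next
            and config.series_prob
            and i < len(rows)
            and rng.random() < config.series_prob
        ):
            nxt = rows[i]
            nclip = _clip(nxt.start, nxt.end)
            if nclip is not None and nclip[0] == end:
                reported[-1]["series"] = True
                reported.append(
                    {
                        "start": nclip[0],
                        "end": nclip[1],
                        "labels": frozenset({Activity(nxt.label)}),
                        "series": "tail",
                    }
                )
                book["n_reported"] += 1
                i += 1

    # build events with styles and cue fields
    pid = episodes["participant_id"].iloc[0] if len(episodes) else "?"
    entries: list[VerbalEntry] = []
    used_report_times: set = set()

    def _unique_report_time(ts: pd.Timestamp) -> pd.Timestamp:
        ts = _minute(ts)
        while ts in used_report_times:
            ts += MINUTE
        used_report_times.add(ts)
        return ts

    j = 0
    while j < len(reported):
        rec = reported[j]
        if rec["series"] is True:  # head of a two-event series entry (C4 cues)
            tail = reported[j + 1]
            rt = _unique_report_time(tail["end"] + pd.Timedelta(minutes=delay()))
            entry = VerbalEntry(participant_id=pid, report_time=rt)
            for r in (rec, tail):
                entry.events.append(
                    ActivityEvent(
                        participant_id=pid,
                        report_time=rt,
                        labels=r["labels"],
                        cue_style="C4",
                        stated_start=_minute(r["start"] + pd.Timedelta(minutes=noise())),
                        stated_end=_minute(r["end"] + pd.Timedelta(minutes=noise())),
                    )
                )
                # forced C4 cues; not a draw from style_probs, so not tallied
            book["n_series_entries"] += 1
            book["n_series_events"] += 2
            entries.append(entry)
            j += 2
            continue

        style = styles[rng.choice(len(styles), p=style_p)]
        book["style_counts"][style] += 1
        start, end = rec["start"], rec["end"]
        dur = (end - start).total_seconds() / 60.0
        ev = ActivityEvent(
            participant_id=pid,
            report_time=end,  # placeholder, set below
            labels=rec["labels"],
            cue_style=style,
        )
        if style == "C1":
            rt = end + pd.Timedelta(minutes=delay())
            ev.stated_duration_min = max(1.0, round(dur + noise()))
        elif style == "C2":
            rt = end + pd.Timedelta(minutes=delay())
        elif style == "C3":
            offset = rng.uniform(0.0, max(dur - 1.0, 0.0))
            rt = start + pd.Timedelta(minutes=float(np.floor(offset)))
        elif style in ("C4", "C5"):
            rt = end + pd.Timedelta(minutes=delay())
            ev.stated_start = _minute(start + pd.Timedelta(minutes=noise()))
            ev.stated_end = _minute(end + pd.Timedelta(minutes=noise()))
        elif style == "C6":
            rt = end + pd.Timedelta(minutes=delay())
            ev.stated_start = _minute(start + pd.Timedelta(minutes=noise()))
        elif style == "C7":
            rt = start
            ev.stated_duration_min = max(1.0, round(dur + noise()))
        elif style == "I2":
            rt = start
        else:  # I1, I3
            rt = end + pd.Timedelta(minutes=delay())
        rt = _unique_report_time(rt)
        ev.report_time = rt
        entries.append(VerbalEntry(participant_id=pid, report_time=rt, events=[ev]))
        j += 1

    entries.sort(key=lambda e: e.report_time)
    return entries, book


# --------------------------------------------------------------------------
# recognizer observation

_API_CLASSES = ("STILL", "IN_VEHICLE", "ON_FOOT", "WALKING", "RUNNING", "ON_BICYCLE", "TILTING", "UNKNOWN")


def observe_api(
    truth_minutes: pd.DataFrame,
    worn: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Recognizer confidence stream for one participant's worn minutes.

    Confidence per class is drawn high when the true label belongs to the
    class's mapped leaf set and low otherwise, independently of the label
    sources' error channels; the configured special error modes then
    overwrite the affected minutes.
    """
    sub = truth_minutes[worn]
    n = len(sub)
    truth = sub["true_label"].to_numpy()
    noise = config.api

    def _tp(size):
        return np.clip(rng.normal(noise.tp_mean, noise.tp_sd, size), 0.0, 100.0)

    def _bg(size):
        return np.clip(rng.normal(noise.bg_mean, noise.bg_sd, size), 0.0, 100.0)

    conf = {}
    for cls in _API_CLASSES:
        mapped = {a.value for a in api_label_set(cls)}
        member = np.isin(truth, list(mapped)) if mapped else np.zeros(n, dtype=bool)
        values = _bg(n)
        values[member] = _tp(int(member.sum()))
        conf[cls] = values

    book = {"n_motorized": 0, "n_idle_miss": 0, "n_wrist_still": 0}
    if noise.motorized_tool_invehicle > 0:
        hit = (truth == _A.STANDING.value) & (rng.random(n) < noise.motorized_tool_invehicle)
        conf["IN_VEHICLE"][hit] = _tp(int(hit.sum()))
        book["n_motorized"] = int(hit.sum())
    if noise.idle_vehicle_miss > 0:
        hit = (truth == _A.SITTING_IN_TRANSPORT.value) & (
            rng.random(n) < noise.idle_vehicle_miss
        )
        conf["IN_VEHICLE"][hit] = _bg(int(hit.sum()))
        book["n_idle_miss"] = int(hit.sum())
    if noise.cycling_wrist_still > 0:
        hit = (truth == _A.CYCLING.value) & (rng.random(n) < noise.cycling_wrist_still)
        conf["STILL"][hit] = _tp(int(hit.sum()))
        conf["ON_BICYCLE"][hit] = _bg(int(hit.sum()))
        book["n_wrist_still"] = int(hit.sum())

    records = [
        {cls: float(conf[cls][i]) for cls in _API_CLASSES} for i in range(n)
    ]
    return (
        pd.DataFrame(
            {
                "participant_id": sub["participant_id"].to_numpy(),
                "minute_start": sub["minute_start"].to_numpy(),
                "api_confidences": records,
            }
        ),
        book,
    )


# --------------------------------------------------------------------------
# orchestration


def generate(config: Optional[CohortConfig] = None, seed: int = 0) -> CohortBundle:
    """Generate a full cohort bundle, deterministic under (config, seed)."""
    config = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    participant_seeds = root.spawn(config.n_participants)

    all_truth, all_eps, all_wear, all_thigh, all_api = [], [], [], [], []
    entries: list[VerbalEntry] = []
    book: dict = {
        "thigh": {},
        "verbal": {},
        "api": {},
        "cadence_valleys": {},
        "wear_minutes": 0,
    }

    for i, pseed in enumerate(participant_seeds):
        pid = _pid(i)
        s_truth, s_thigh, s_verbal, s_api, s_profile = (
            np.random.default_rng(c) for c in pseed.spawn(5)
        )

        means = np.asarray(config.cadence_means, dtype=float)
        if config.cadence_mean_jitter_sd:
            means = means + s_profile.normal(0, config.cadence_mean_jitter_sd, 3)
            means.sort()
        sds = np.asarray(config.cadence_sds, dtype=float)
        book["cadence_valleys"][pid] = (
            float((means[0] + means[1]) / 2),
            float((means[1] + means[2]) / 2),
        )

        episodes = simulate_truth(config, s_truth, pid)
        truth_minutes = _episodes_to_minutes(episodes)
        windows = _wear_windows(config, s_truth, pid)
        minutes = pd.to_datetime(truth_minutes["minute_start"])
        worn = np.zeros(len(truth_minutes), dtype=bool)
        for w0, w1 in windows:
            worn |= ((minutes >= w0) & (minutes < w1)).to_numpy()
        book["wear_minutes"] += int(worn.sum())

        thigh, tb = observe_thigh(truth_minutes, config, s_thigh, means, sds)
        p_entries, vb = observe_verbal(episodes, windows, config, s_verbal)
        api, ab = observe_api(truth_minutes, worn, config, s_api)

        book["thigh"][pid] = tb
        book["verbal"][pid] = vb
        book["api"][pid] = ab

        all_truth.append(truth_minutes)
        all_eps.append(episodes)
        all_wear.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "minute_start": truth_minutes["minute_start"],
                    "worn": worn,
                }
            )
        )
        all_thigh.append(thigh)
        all_api.append(api)
        entries.extend(p_entries)

    return CohortBundle(
        config=config,
        seed=seed,
        truth=pd.concat(all_truth, ignore_index=True),
        episodes=pd.concat(all_eps, ignore_index=True),
        wear=pd.concat(all_wear, ignore_index=True),
        thigh=pd.concat(all_thigh, ignore_index=True),
        entries=entries,
        api=pd.concat(all_api, ignore_index=True),
        book=book,
    )
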