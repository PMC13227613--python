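"""End-to-end driver: raw streams -> consensus frames -> benchmark tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from . import benchmark, cadence, consensus, thigh_epochs, verbal_events
from .cohort import CohortBundle

DEFAULT_FALLBACK_THRESHOLDS = cadence.CadenceThresholds(90.0, 130.0)


@dataclass
class PipelineResult:
    frames: pd.DataFrame
    labeled_epochs: pd.DataFrame
    verbal_minutes: pd.DataFrame
    expansion: verbal_events.ExpansionTally
    exclusions: verbal_events.ExclusionTally
    thresholds: dict


def estimate_cohort_thresholds(
    thigh: pd.DataFrame,
    fallback: cadence.CadenceThresholds = DEFAULT_FALLBACK_THRESHOLDS,
    min_prominence: float = cadence.DEFAULT_MIN_PROMINENCE,
) -> dict[str, cadence.CadenceThresholds]:
    """Per-participant cadence thresholds from full-minute stepping epochs.

    Participants whose cadence distribution is indeterminate (fewer than
    two density peaks) fall back to the supplied thresholds.
    """
    out: dict[str, cadence.CadenceThresholds] = {}
    stepping = thigh[thigh["stepping_s"] > 50]
    for pid, grp in stepping.groupby("participant_id"):
        try:
            profile = cadence.build_distribution(str(pid), grp["steps"].astype(float))
            cadence.estimate_thresholds(profile, min_prominence=min_prominence)
            out[str(pid)] = profile.thresholds
        except ValueError:
            out[str(pid)] = fallback
    for pid in thigh["participant_id"].unique():
        out.setdefault(str(pid), fallback)
    return out


def run_pipeline(
    bundle: CohortBundle,
    thresholds: Optional[Mapping[str, cadence.CadenceThresholds] | str] = None,
    c3_window_min: float = verbal_events.DEFAULT_C3_WINDOW_MIN,
    coverage_s: float = verbal_events.DEFAULT_COVERAGE_S,
) -> PipelineResult:
    """Run the full labeling pipeline on a cohort bundle.

    ``thresholds`` may be a per-participant mapping, the string
    ``"generator"`` (use the generating mixture's valleys — useful when the
    estimator should stay out of the comparison), or None to estimate them
    from the thigh stream.
    """
    if thresholds == "generator":
        thr = {
            pid: cadence.CadenceThresholds(v[0], v[1])
            for pid, v in bundle.book["cadence_valleys"].items()
        }
    elif thresholds is None:
        thr = estimate_cohort_thresholds(bundle.thigh)
    else:
        thr = dict(thresholds)

    labeled = thigh_epochs.label_epochs(bundle.thigh, thr)

    entries = bundle.entries
    verbal_events.reconstruct_all(entries, c3_window_min=c3_window_min)
    events, expansion = verbal_events.expand_entries(entries)
    wear = bundle.wear.copy()
    retained, exclusions = verbal_events.apply_exclusions(
        events, wear, coverage_s=coverage_s
    )
    minutes = verbal_events.project_to_minutes(
        retained, coverage_s=coverage_s, wear_mask=wear
    )

    frames = consensus.triangulate(labeled, minutes, wear)
    frames = benchmark.attach_confidences(frames, bundle.api)
    return PipelineResult(
        frames=frames,
        labeled_epochs=labeled,
        verbal_minutes=minutes,
        expansion=expansion,
        exclusions=exclusions,
        thresholds=thr,
    )
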