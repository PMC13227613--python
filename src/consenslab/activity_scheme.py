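"""Hierarchical activity taxonomy and source-to-scheme mapping tables.

The taxonomy has eight leaf activities grouped under three postural
branches (sedentary, upright, cycling).  Two external label sources are
mapped onto it: the thigh-worn sensor's export classes and a wrist
recognizer's eight classes.  Mapping tables ship as a JSON resource so
they are auditable and can be overridden from a config file.
"""

from __future__ import annotations

import enum
import json
from importlib import resources
from typing import FrozenSet, Mapping

__all__ = [
    "Activity",
    "Branch",
    "EXCLUDED",
    "API_CLASSES",
    "THIGH_CLASSES",
    "MetCategoryBounds",
    "load_mappings",
    "api_label_set",
    "thigh_label_set",
    "met_category",
]


class Branch(str, enum.Enum):
    SEDENTARY = "Sedentary"
    UPRIGHT = "Upright"
    CYCLING = "Cycling"


class Activity(str, enum.Enum):
    """Leaf activity labels of the hierarchical scheme."""

    LYING = "Lying"
    SITTING_NOT_IN_TRANSPORT = "SittingNotInTransport"
    SITTING_IN_TRANSPORT = "SittingInTransport"
    STANDING = "Standing"
    LOW_STEPPING = "LowStepping"
    MODERATE_STEPPING = "ModerateStepping"
    VIGOROUS_STEPPING = "VigorousStepping"
    CYCLING = "Cycling"

    @property
    def parent(self) -> Branch:
        return _PARENTS[self]

    def __str__(self) -> str:  # CSV-friendly
        return self.value


_PARENTS: Mapping[Activity, Branch] = {
    Activity.LYING: Branch.SEDENTARY,
    Activity.SITTING_NOT_IN_TRANSPORT: Branch.SEDENTARY,
    Activity.SITTING_IN_TRANSPORT: Branch.SEDENTARY,
    Activity.STANDING: Branch.UPRIGHT,
    Activity.LOW_STEPPING: Branch.UPRIGHT,
    Activity.MODERATE_STEPPING: Branch.UPRIGHT,
    Activity.VIGOROUS_STEPPING: Branch.UPRIGHT,
    Activity.CYCLING: Branch.CYCLING,
}

#: Distinguished non-label value for dropped epochs/events.  Never counted
#: in any statistic.
EXCLUDED = "excluded"

STEPPING = frozenset(
    {Activity.LOW_STEPPING, Activity.MODERATE_STEPPING, Activity.VIGOROUS_STEPPING}
)

API_CLASSES = (
    "STILL",
    "IN_VEHICLE",
    "ON_FOOT",
    "WALKING",
    "RUNNING",
    "ON_BICYCLE",
    "TILTING",
    "UNKNOWN",
)

THIGH_CLASSES = (
    "sitting",
    "sitting-in-transport",
    "cycling",
    "upright",
    "stepping",
    "lying-primary",
    "lying-secondary",
    "sedentary",
)


def load_mappings(path: str | None = None) -> dict[str, dict[str, FrozenSet[Activity]]]:
    """Load the source-to-scheme mapping tables.

    Parameters
    ----------
    path
        Optional JSON file overriding the packaged tables.  The file must
        contain ``thigh`` and ``api`` objects mapping source class names to
        lists of leaf label names.
    """
    if path is None:
        raw = json.loads(
            resources.files("consenslab.data").joinpath("mappings.json").read_text()
        )
    else:
        with open(path) as fh:
            raw = json.load(fh)
    out: dict[str, dict[str, FrozenSet[Activity]]] = {}
    for source, entries in raw.items():
        out[source] = {
            cls: frozenset(Activity(name) for name in leaves)
            for cls, leaves in entries.items()
        }
    return out


_MAPPINGS = load_mappings()


def api_label_set(api_class: str) -> FrozenSet[Activity]:
    """Leaf label set a recognizer class maps onto (may be empty)."""
    try:
        return _MAPPINGS["api"][api_class]
    except KeyError:
        raise KeyError(f"unknown recognizer class: {api_class!r}") from None


def thigh_label_set(thigh_class: str) -> FrozenSet[Activity]:
    """Leaf label set a thigh-sensor export class maps onto."""
    try:
        return _MAPPINGS["thigh"][thigh_class]
    except KeyError:
        raise KeyError(f"unknown thigh-sensor class: {thigh_class!r}") from None


class MetCategoryBounds:
    """MET intensity category bounds (printed at two decimals)."""

    LIGHT_MAX = 2.99
    MODERATE_MIN = 3.00
    MODERATE_MAX = 5.99
    VIGOROUS_MIN = 6.00
    VIGOROUS_MAX = 8.99
    #: reference comparison line drawn in intensity plots
    VIGOROUS_LINE = 6.0


def met_category(met: float) -> str:
    """Intensity category for a MET value.

    Inputs are rounded to two decimals before comparison since the bounds
    are defined at two-decimal precision.  Returns one of ``light``,
    ``moderate``, ``vigorous`` or ``out_of_range``.
    """
    if met < 0:
        raise ValueError(f"MET value must be non-negative, got {met}")
    m = round(met, 2)
    if m <= MetCategoryBounds.LIGHT_MAX:
        return "light"
    if m <= MetCategoryBounds.MODERATE_MAX:
        return "moderate"
    if m <= MetCategoryBounds.VIGOROUS_MAX:
        return "vigorous"
    return "out_of_range"
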