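"""Personalized stepping-cadence distributions and intensity thresholds.

Builds a per-participant cadence histogram plus kernel density over
stepping minutes, detects the distribution's peaks, and places intensity
thresholds at the density valleys between adjacent peaks: two peaks give
the low/moderate threshold only, three give both the low/moderate and
moderate/vigorous thresholds.  Manual thresholds (e.g. set by visual
inspection) take precedence when supplied.  An exertion-audit helper
checks keyword-implied intensity in verbal reports against the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

DEFAULT_BIN_WIDTH = 2.0
DEFAULT_MIN_STEPS = 50.0
DEFAULT_MIN_PROMINENCE = 0.05  # fraction of the density maximum
_GRID_STEP = 0.5


@dataclass(frozen=True)
class CadenceThresholds:
    """Steps/min boundaries between stepping intensity classes."""

    theta_lm: float
    theta_mv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.theta_lm <= 0:
            raise ValueError("theta_lm must be positive")
        if self.theta_mv is not None and self.theta_mv <= self.theta_lm:
            raise ValueError("theta_mv must exceed theta_lm")


@dataclass
class CadenceProfile:
    """Cadence distribution for one participant's stepping minutes."""

    participant_id: str
    cadences: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    n_epochs: int
    theta_lm: Optional[float] = None
    theta_mv: Optional[float] = None
    indeterminate: bool = False
    peak_positions: list = field(default_factory=list)

    @property
    def thresholds(self) -> CadenceThresholds:
        if self.theta_lm is None:
            raise ValueError(
                f"profile for {self.participant_id} has no thresholds "
                f"({'indeterminate' if self.indeterminate else 'not estimated yet'}); "
                "supply manual thresholds or run estimate_thresholds"
            )
        return CadenceThresholds(self.theta_lm, self.theta_mv)


def build_distribution(
    participant_id: str,
    cadences: Iterable[float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_steps: float = DEFAULT_MIN_STEPS,
    bw_method: str | float = "silverman",
) -> CadenceProfile:
    """Histogram + kernel density of stepping cadence.

    Epochs with fewer than ``min_steps`` steps are excluded.  Histogram bins
    are ``bin_width`` steps/min wide starting at ``min_steps``; the density
    is a Gaussian KDE (Silverman bandwidth by default) evaluated on a fine
    grid over the filtered support.
    """
    arr = np.asarray(list(cadences), dtype=float)
    arr = arr[arr >= min_steps]
    if arr.size == 0:
        raise ValueError(
            f"no stepping epochs for {participant_id} after the "
            f">= {min_steps} steps/min filter"
        )
    hi = float(arr.max())
    edges = np.arange(min_steps, hi + bin_width, bin_width)
    if edges[-1] <= hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(arr, bins=edges)

    if arr.size > 1 and arr.std() > 0:
        kde = gaussian_kde(arr, bw_method=bw_method)
        grid = np.arange(min_steps, hi + _GRID_STEP, _GRID_STEP)
        density = kde(grid)
    else:  # degenerate: all mass at one cadence
        grid = np.array([arr[0]])
        density = np.array([1.0])

    return CadenceProfile(
        participant_id=participant_id,
        cadences=arr,
        bin_edges=edges,
        counts=counts,
        grid=grid,
        density=density,
        n_epochs=int(arr.size),
    )


def estimate_thresholds(
    profile: CadenceProfile,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> CadenceProfile:
    """Place thresholds at density valleys between detected peaks.

    Local maxima of the smoothed density with prominence at least
    ``min_prominence`` times the density maximum count as peaks; when more
    than three qualify, the three most prominent are kept.  Each threshold
    is the grid position of the density minimum strictly between two
    adjacent peaks (leftmost on ties).  One peak leaves the profile
    indeterminate; two peaks yield theta_lm only; three yield both.
    """
    dens = profile.density
    if dens.size < 3:
        profile.indeterminate = True
        return profile
    idx, props = find_peaks(dens, prominence=min_prominence * float(dens.max()))
    if idx.size > 3:
        keep = np.sort(np.argsort(props["prominences"])[-3:])
        idx = idx[keep]
    profile.peak_positions = [float(profile.grid[i]) for i in idx]

    if idx.size <= 1:
        profile.indeterminate = True
        profile.theta_lm = None
        profile.theta_mv = None
        return profile

    valleys = []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = dens[a : b + 1]
        valleys.append(float(profile.grid[a + int(np.argmin(seg))]))
    profile.theta_lm = valleys[0]
    profile.theta_mv = valleys[1] if len(valleys) > 1 else None
    profile.indeterminate = False
    return profile


def load_manual_thresholds(path: Optional[str] = None) -> dict[str, CadenceThresholds]:
    """Read a manual thresholds CSV (participant_id, theta_lm, theta_mv).

    With no path, the packaged reference thresholds (set by visual
    inspection of each participant's cadence distribution) are returned.
    """
    if path is None:
        src = resources.files("consenslab.data").joinpath("stepping_thresholds.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    out: dict[str, CadenceThresholds] = {}
    for row in df.itertuples(index=False):
        mv = None if pd.isna(row.theta_mv) else float(row.theta_mv)
        out[str(row.participant_id)] = CadenceThresholds(float(row.theta_lm), mv)
    return out


# --- exertion audit ---------------------------------------------------------

#: fixed keyword lexicon mapping exertion phrases to intensity classes
MODERATE_KEYWORDS = frozenset({"moderate", "moderately", "steady", "brisk", "medium"})
VIGOROUS_KEYWORDS = frozenset({"run", "ran", "running", "intense"})


@dataclass
class ExertionItem:
    participant_id: str
    phrase: str
    cadence_lo: float
    cadence_hi: float
    event_ref: object = None
    keyword_class: Optional[str] = None
    threshold_class: Optional[str] = None
    consistent: Optional[bool] = None


@dataclass
class ExertionAudit:
    items: list
    n_consistent: int
    n_checked: int

    @property
    def agreement(self) -> Optional[float]:
        """Fraction of audited items whose keyword class matches; None if empty."""
        return self.n_consistent / self.n_checked if self.n_checked else None


def _keyword_class(phrase: str) -> Optional[str]:
    words = {w.strip(".,!?;:\"'").lower() for w in phrase.split()}
    if words & VIGOROUS_KEYWORDS:
        return "vigorous"
    if words & MODERATE_KEYWORDS:
        return "moderate"
    return None


def exertion_audit(
    thresholds: CadenceThresholds, items: Sequence[ExertionItem]
) -> ExertionAudit:
    """Check keyword-implied intensity against threshold-implied intensity.

    The threshold class of each item is taken at the midpoint of its
    cadence range; items without a lexicon keyword are skipped.
    """
    checked = 0
    consistent = 0
    for item in items:
        if item.cadence_lo > item.cadence_hi:
            raise ValueError("cadence range min > max")
        item.keyword_class = _keyword_class(item.phrase)
        mid = 0.5 * (item.cadence_lo + item.cadence_hi)
        if mid < thresholds.theta_lm:
            item.threshold_class = "low"
        elif thresholds.theta_mv is None or mid < thresholds.theta_mv:
            item.threshold_class = "moderate"
        else:
            item.threshold_class = "vigorous"
        if item.keyword_class is None:
            item.consistent = None
            continue
        checked += 1
        item.consistent = item.keyword_class == item.threshold_class
        consistent += int(item.consistent)
    return ExertionAudit(items=list(items), n_consistent=consistent, n_checked=checked)


def plot_profile(profile: CadenceProfile, path: str) -> None:
    """Save a histogram + density plot for one profile (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    widths = np.diff(profile.bin_edges)
    ax.bar(
        profile.bin_edges[:-1],
        profile.counts / profile.counts.sum() / widths,
        width=widths,
        align="edge",
        alpha=0.5,
    )
    ax.plot(profile.grid, profile.density, lw=2)
    for theta, style in ((profile.theta_lm, "--"), (profile.theta_mv, ":")):
        if theta is not None:
            ax.axvline(theta, color="k", ls=style)
    ax.set_xlabel("cadence (steps/min)")
    ax.set_ylabel("density")
    ax.set_title(profile.participant_id)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
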