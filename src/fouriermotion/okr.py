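"""Optokinetic-response analysis: saccade detection and behavior sorting.

The optokinetic response (OKR) consists of slow pursuit eye rotations in the
perceived direction of whole-field motion, periodically reset by fast
saccades in the opposite direction.  Because the resetting saccades are far
faster than the pursuits, the direction of pursuit can be read off the
saccade directions alone: two consecutive saccades rotating left-to-right
imply pursuits to the left, two consecutive right-to-left saccades imply
pursuits to the right, and alternating saccades are spontaneous eye
rotations.

Sign convention: positive angle = clockwise in image coordinates, so a
``+1`` saccade rotates the eye from the animal's left toward its right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus import StimulusEpoch

__all__ = [
    "EyeTrace",
    "Saccade",
    "BehaviorSummary",
    "zero_baseline",
    "detect_saccades",
    "classify_epoch",
    "summarize_behavior",
]

#: Behavioral event categories relative to the stimulus.
CATEGORIES = ("stimulus_direction", "opposite_direction", "spontaneous")


@dataclass(frozen=True)
class EyeTrace:
    """Uniformly sampled orientation of both eyes against a fixed axis."""

    time: np.ndarray  # seconds
    angle_left: np.ndarray  # degrees
    angle_right: np.ndarray  # degrees

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        al = np.asarray(self.angle_left, dtype=float)
        ar = np.asarray(self.angle_right, dtype=float)
        for name, arr in (("time", t), ("angle_left", al), ("angle_right", ar)):
            if arr.ndim != 1 or arr.shape != t.shape:
                raise ValueError(f"{name} must be 1-D and match time's length")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "angle_left", al)
        object.__setattr__(self, "angle_right", ar)

    @property
    def dt(self) -> float:
        steps = np.diff(self.time)
        if len(steps) == 0:
            raise ValueError("trace has fewer than two samples")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace is not uniformly sampled")
        return float(steps[0])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "angle_left_deg": self.angle_left,
                "angle_right_deg": self.angle_right,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EyeTrace":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df["angle_left_deg"].to_numpy(),
            df["angle_right_deg"].to_numpy(),
        )


@dataclass(frozen=True)
class Saccade:
    """A rapid eye rotation event."""

    time: float  # seconds (midpoint of the fast phase)
    eye: str  # "left" | "right"
    direction: int  # +1 = left-to-right rotation (angle increasing)
    amplitude: float  # degrees, > 0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class BehaviorSummary:
    """Group-level behavior statistics per epoch type.

    ``percentages`` maps epoch type -> DataFrame (larva x category, percent);
    ``anova_p`` maps epoch type -> one-way ANOVA p-value across the three
    categories; ``pairwise`` maps epoch type -> DataFrame of pairwise
    comparisons (mean difference, 95% CI, p) computed when the ANOVA is
    significant.
    """

    percentages: Mapping[str, pd.DataFrame]
    anova_p: Mapping[str, float]
    anova_f: Mapping[str, float]
    pairwise: Mapping[str, pd.DataFrame | None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for etype, df in self.percentages.items():
            means = df.mean(axis=0)
            for cat in CATEGORIES:
                rows.append(
                    {
                        "epoch_type": etype,
                        "category": cat,
                        "mean_percent": means[cat],
                        "sd_percent": df[cat].std(ddof=1) if len(df) > 1 else 0.0,
                        "anova_p": self.anova_p[etype],
                    }
                )
        return pd.DataFrame(rows)


def zero_baseline(trace: EyeTrace) -> EyeTrace:
    """Subtract each eye's mean orientation (removes the larva's heading)."""
    if len(trace.time) < 2:
        raise ValueError("need at least two samples")
    return replace(
        trace,
        angle_left=trace.angle_left - trace.angle_left.mean(),
        angle_right=trace.angle_right - trace.angle_right.mean(),
    )


def _detect_one_eye(
    time: np.ndarray, angle: np.ndarray, eye: str, vel_threshold: float, refractory: float
) -> list[Saccade]:
    dt = time[1] - time[0]
    vel = np.diff(angle) / dt
    fast = np.abs(vel) > vel_threshold
    if not fast.any():
        return []
    # maximal runs of supra-threshold velocity samples
    edges = np.diff(fast.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if fast[0]:
        starts.insert(0, 0)
    if fast[-1]:
        ends.append(len(fast))
    runs = list(zip(starts, ends))
    # merge runs separated by less than the refractory interval
    merged = [runs[0]]
    for s, e in runs[1:]:
        if time[s] - time[merged[-1][1]] < refractory:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    saccades = []
    for s, e in merged:
        # run over velocity samples [s, e) corresponds to angle[s] .. angle[e]
        net = angle[e] - angle[s]
        if net == 0:
            continue
        saccades.append(
            Saccade(
                time=float(0.5 * (time[s] + time[e])),
                eye=eye,
                direction=1 if net > 0 else -1,
                amplitude=float(abs(net)),
            )
        )
    return saccades


def detect_saccades(
    trace: EyeTrace, vel_threshold: float = 100.0, refractory: float = 0.2
) -> list[Saccade]:
    """Detect saccades as maximal runs of supra-threshold angular velocity.

    A saccade's direction is the sign of the net angular displacement over
    the run; runs of one eye closer than ``refractory`` seconds are merged.
    Returns saccades of both eyes sorted by time.

    Parameters
    ----------
    vel_threshold : float
        Angular-velocity threshold in degrees/second (well above pursuit
        velocities, well below the fast resetting phase).
    refractory : float
        Minimum separation between distinct saccades of one eye, seconds.
    """
    if vel_threshold <= 0:
        raise ValueError("vel_threshold must be positive")
    trace.dt  # raises on non-uniform sampling
    out = _detect_one_eye(
        trace.time, trace.angle_left, "left", vel_threshold, refractory
    )
    out += _detect_one_eye(
        trace.time, trace.angle_right, "right", vel_threshold, refractory
    )
    return sorted(out, key=lambda s: s.time)


def classify_epoch(
    saccades: Sequence[Saccade], epoch: StimulusEpoch | None = None
) -> list[str]:
    """Sort the saccades of one epoch into behavioral events.

    Each consecutive pair of saccades (per eye, then pooled across eyes) is
    one behavioral event: two left-to-right saccades (+1, +1) mean the
    intervening pursuits ran right-to-left, so the event is ``pursuit_left``;
    two right-to-left saccades (-1, -1) give ``pursuit_right``; alternating
    directions are ``spontaneous``.  An epoch with fewer than two saccades
    (in every eye) yields a single spontaneous event.
    """
    if epoch is not None:
        lo, hi = epoch.onset, epoch.onset + epoch.duration
        saccades = [s for s in saccades if lo <= s.time < hi]
    events: list[tuple[float, str]] = []
    for eye in ("left", "right"):
        eye_s = [s for s in saccades if s.eye == eye]
        for a, b in zip(eye_s[:-1], eye_s[1:]):
            if a.direction == b.direction:
                label = "pursuit_left" if a.direction == 1 else "pursuit_right"
            else:
                label = "spontaneous"
            events.append((b.time, label))
    if not events:
        return ["spontaneous"]
    return [label for _, label in sorted(events)]


def _stimulus_relative(label: str, direction: str) -> str:
    """Map a pursuit label to a stimulus-relative category.

    For epochs without a stimulus direction ('none': black screens) the
    two pursuit categories are kept by a fixed convention (leftward pursuit
    fills the 'stimulus_direction' slot) so that the three-way split remains
    comparable across epoch types.
    """
    if label == "spontaneous":
        return "spontaneous"
    pursuit_dir = "left" if label == "pursuit_left" else "right"
    if direction == "none":
        return "stimulus_direction" if pursuit_dir == "left" else "opposite_direction"
    return "stimulus_direction" if pursuit_dir == direction else "opposite_direction"


def summarize_behavior(
    events: Iterable[tuple[str, str, str, str]],
    alpha: float = 0.05,
) -> BehaviorSummary:
    """Aggregate behavioral events into per-larva percentages and statistics.

    Parameters
    ----------
    events : iterable of (larva, epoch_type, label, stimulus_direction)
        One row per behavioral event.  ``label`` is a ``classify_epoch``
        output; ``epoch_type`` groups epochs for the summary (for example
        ``"moving:square"``); ``stimulus_direction`` is the direction of the
        epoch's stimulus or ``"none"``.

    Returns
    -------
    BehaviorSummary
        Per-larva percentages of stimulus-relative categories per epoch
        type, a one-way ANOVA across the three categories (observations =
        per-larva percentages), and pairwise comparisons with 95%
        confidence intervals when the ANOVA is significant at ``alpha``.
    """
    df = pd.DataFrame(
        events, columns=["larva", "epoch_type", "label", "direction"]
    )
    if df.empty:
        raise ValueError("no behavioral events supplied")
    df["category"] = [
        _stimulus_relative(lbl, d) for lbl, d in zip(df["label"], df["direction"])
    ]

    percentages: dict[str, pd.DataFrame] = {}
    anova_p: dict[str, float] = {}
    anova_f: dict[str, float] = {}
    pairwise: dict[str, pd.DataFrame | None] = {}
    for etype, sub in df.groupby("epoch_type"):
        counts = (
            sub.groupby(["larva", "category"]).size().unstack(fill_value=0)
        )
        for cat in CATEGORIES:
            if cat not in counts:
                counts[cat] = 0
        counts = counts[list(CATEGORIES)]
        pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
        percentages[etype] = pct
        if len(pct) < 2:
            warnings.warn(
                f"epoch type {etype!r} has fewer than 2 larvae; ANOVA skipped"
            )
            anova_p[etype] = np.nan
            anova_f[etype] = np.nan
            pairwise[etype] = None
            continue
        groups = [pct[cat].to_numpy() for cat in CATEGORIES]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                # constant groups with different means give F = inf, p = 0,
                # which is the right answer; silence scipy's precision note
                warnings.simplefilter("ignore", RuntimeWarning)
                f, p = stats.f_oneway(*groups)
        anova_p[etype] = float(p)
        anova_f[etype] = float(f)
        pairwise[etype] = _pairwise_ci(groups) if p < alpha else None
    return BehaviorSummary(percentages, anova_p, anova_f, pairwise)


def _pairwise_ci(groups: list[np.ndarray]) -> pd.DataFrame:
    """Pairwise Welch comparisons between categories with 95% CIs."""
    rows = []
    for i in range(len(CATEGORIES)):
        for j in range(i + 1, len(CATEGORIES)):
            a, b = groups[i], groups[j]
            diff = a.mean() - b.mean()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # constant groups
                res = stats.ttest_ind(a, b, equal_var=False)
            ci = res.confidence_interval(0.95)
            rows.append(
                {
                    "a": CATEGORIES[i],
                    "b": CATEGORIES[j],
                    "mean_diff": diff,
                    "ci_low": ci.low,
                    "ci_high": ci.high,
                    "p": float(res.pvalue),
                }
            )
    return pd.DataFrame(rows)
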