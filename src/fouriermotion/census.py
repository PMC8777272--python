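"""Stimulus-responsiveness scoring and the response-type census.

Each neuron is scored against each moving stimulus condition (square wave,
missing fundamental, third harmonic x left/right) by the difference between
its mean activity during that condition and its mean activity during the
black baseline, standardized across the population (z-score).  Neurons with
z < -1 for a condition are ineligible for it; the remaining neurons are
*responsive* to a condition when they show at least ``min_frames``
significant frames during the stimulation span in at least half of that
condition's repetitions.

The per-neuron booleans over the 6 moving conditions form a response
profile (2^6 = 64 possible patterns).  The census tallies each pattern as a
percentage of all recorded neurons per larva and region, keeps patterns
reaching at least 0.1% of a region's recorded neurons, compares regions per
pattern with the Wilcoxon rank-sum test, and controls the false discovery
rate with the Benjamini-Hochberg step-up rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stimulus import Protocol

__all__ = [
    "EpochIndex",
    "build_epoch_index",
    "score_responses",
    "is_responsive",
    "responsive_matrix",
    "profile_neurons",
    "split_static_moving",
    "census_compare",
    "spatial_report",
    "pattern_label",
    "MOVING_CONDITIONS",
]

#: Canonical order of the 6 moving conditions (bit 0 first in pattern ids).
MOVING_CONDITIONS: tuple[str, ...] = (
    "square:left",
    "square:right",
    "missing_fundamental:left",
    "missing_fundamental:right",
    "third_harmonic:left",
    "third_harmonic:right",
)

_SHORT = {
    "square": "Sq",
    "missing_fundamental": "MF",
    "third_harmonic": "3h",
}


def pattern_label(pattern: int, conditions=MOVING_CONDITIONS) -> str:
    """Human-readable name for a pattern id, e.g. ``SqL+MFR``."""
    parts = []
    for bit, cond in enumerate(conditions):
        if pattern >> bit & 1:
            name, direction = cond.split(":")
            parts.append(_SHORT.get(name, name) + direction[0].upper())
    return "+".join(parts) if parts else "none"


@dataclass(frozen=True)
class EpochIndex:
    """Frame spans of every epoch, grouped by condition and direction.

    ``spans`` maps ``(kind, condition, direction)`` to a list of half-open
    frame ranges ``(start, stop)``, one per repetition, in presentation
    order.  ``black`` is the span of the leading black epoch.
    """

    spans: dict[tuple[str, str | None, str], list[tuple[int, int]]]
    black: tuple[int, int]
    n_frames: int
    frame_rate: float

    def moving(self, condition_dir: str) -> list[tuple[int, int]]:
        cond, direction = condition_dir.split(":")
        return self.spans.get(("moving", cond, direction), [])

    def static(self, condition_dir: str) -> list[tuple[int, int]]:
        cond, direction = condition_dir.split(":")
        return self.spans.get(("static", cond, direction), [])

    def conditions(self, kind: str = "moving") -> list[str]:
        return sorted(
            f"{c}:{d}" for (k, c, d) in self.spans if k == kind
        )


def build_epoch_index(
    protocol: Protocol, frame_rate: float | None = None, n_frames: int | None = None
) -> EpochIndex:
    """Convert a protocol timeline into frame spans.

    Spans are ``floor(onset * rate) .. floor((onset + duration) * rate)``,
    half-open, so they tile the recording without overlap.
    """
    rate = protocol.frame_rate if frame_rate is None else frame_rate
    total = int(np.floor(protocol.total_duration * rate))
    if n_frames is not None:
        if abs(n_frames - total) > 1:
            raise ValueError(
                f"recording has {n_frames} frames but the protocol at {rate} Hz "
                f"spans {total}"
            )
        total = n_frames
    spans: dict[tuple[str, str | None, str], list[tuple[int, int]]] = {}
    black = None
    for ep in protocol.epochs:
        a = int(np.floor(ep.onset * rate))
        b = min(total, int(np.floor((ep.onset + ep.duration) * rate)))
        if ep.kind == "black" and black is None:
            black = (a, b)
            continue
        spans.setdefault((ep.kind, ep.condition, ep.direction), []).append((a, b))
    if black is None:
        raise ValueError("protocol has no leading black epoch")
    return EpochIndex(spans=spans, black=black, n_frames=total, frame_rate=rate)


def _span_mean(activity: np.ndarray, spans: list[tuple[int, int]]) -> np.ndarray:
    """Mean activity over the union of spans, per ROI (NaN-aware)."""
    chunks = [activity[a:b] for a, b in spans]
    stacked = np.concatenate(chunks, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stacked, axis=0)


def score_responses(
    activity: np.ndarray, index: EpochIndex, conditions=MOVING_CONDITIONS
) -> pd.DataFrame:
    """Population-standardized response score per ROI per condition.

    ``activity`` is (frames, ROIs); by default the significant-frame
    indicator (0/1), alternatively ΔF/F.  For each condition,
    ``delta = mean activity during the condition's moving spans - mean
    activity during black``, and ``z = (delta - mean over ROIs) / sd over
    ROIs``.  ROIs with z < -1 are marked ineligible for that condition.
    """
    activity = np.asarray(activity, dtype=float)
    black_mean = _span_mean(activity, [index.black])
    rows = []
    for cond in conditions:
        spans = index.moving(cond)
        if not spans:
            raise ValueError(f"no moving spans for condition {cond!r}")
        delta = _span_mean(activity, spans) - black_mean
        sd = np.nanstd(delta, ddof=0)
        if sd == 0:
            raise ValueError(f"degenerate population: zero delta spread for {cond!r}")
        z = (delta - np.nanmean(delta)) / sd
        for i in range(activity.shape[1]):
            rows.append(
                {
                    "roi": i,
                    "condition": cond,
                    "delta": delta[i],
                    "z": z[i],
                    "eligible": z[i] >= -1.0,
                }
            )
    return pd.DataFrame(rows)


def is_responsive(
    significant: np.ndarray,
    spans: list[tuple[int, int]],
    min_frames: int = 4,
    min_rep_frac: float = 0.5,
) -> np.ndarray | bool:
    """Responsiveness rule over the repetitions of one condition.

    True when an ROI shows at least ``min_frames`` significant frames
    within the span of a repetition, in at least
    ``ceil(min_rep_frac * n_reps)`` repetitions.

    ``significant`` is (frames,) or (frames, ROIs) boolean.
    """
    sig = np.asarray(significant)
    squeeze = sig.ndim == 1
    if squeeze:
        sig = sig[:, None]
    need_reps = ceil(min_rep_frac * len(spans))
    hits = np.zeros(sig.shape[1], dtype=int)
    for a, b in spans:
        hits += sig[a:b].sum(axis=0) >= min_frames
    out = hits >= need_reps
    return bool(out[0]) if squeeze else out


def responsive_matrix(
    significant: np.ndarray,
    index: EpochIndex,
    scores: pd.DataFrame | None = None,
    conditions=MOVING_CONDITIONS,
    min_frames: int = 4,
    min_rep_frac: float = 0.5,
    kind: str = "moving",
) -> np.ndarray:
    """(ROIs, conditions) boolean responsiveness, eligibility applied."""
    sig = np.asarray(significant)
    if sig.ndim == 1:
        sig = sig[:, None]
    out = np.zeros((sig.shape[1], len(conditions)), dtype=bool)
    for c, cond in enumerate(conditions):
        spans = index.static(cond) if kind == "static" else index.moving(cond)
        out[:, c] = is_responsive(sig, spans, min_frames, min_rep_frac)
        if scores is not None:
            elig = (
                scores[scores["condition"] == cond]
                .sort_values("roi")["eligible"]
                .to_numpy()
            )
            out[:, c] &= elig
    return out


def profile_neurons(responsive: np.ndarray, conditions=MOVING_CONDITIONS) -> pd.DataFrame:
    """Binary response profile and pattern id per ROI.

    Pattern ids encode condition ``c`` (in the order of ``conditions``) as
    bit ``c``; the all-zero pattern marks a non-responder.
    """
    responsive = np.asarray(responsive, dtype=bool)
    if responsive.ndim != 2 or responsive.shape[1] != len(conditions):
        raise ValueError("responsive must be (ROIs, conditions)")
    weights = 1 << np.arange(len(conditions))
    patterns = responsive @ weights
    df = pd.DataFrame(responsive, columns=list(conditions))
    df.insert(0, "roi", np.arange(len(df)))
    df["pattern"] = patterns
    df["label"] = [pattern_label(p, conditions) for p in patterns]
    df["responder"] = patterns > 0
    return df


def split_static_moving(
    significant: np.ndarray,
    index: EpochIndex,
    condition: str,
    min_frames: int = 4,
    min_rep_frac: float = 0.5,
) -> np.ndarray:
    """Sub-classify responders by the stimulus part driving them.

    Applies the responsiveness rule separately to the static and the moving
    spans of ``condition`` and combines into ``static_only``,
    ``moving_only``, ``both`` or ``neither`` per ROI.
    """
    sig = np.asarray(significant)
    if sig.ndim == 1:
        sig = sig[:, None]
    st = is_responsive(sig, index.static(condition), min_frames, min_rep_frac)
    mv = is_responsive(sig, index.moving(condition), min_frames, min_rep_frac)
    out = np.full(sig.shape[1], "neither", dtype=object)
    out[st & ~mv] = "static_only"
    out[~st & mv] = "moving_only"
    out[st & mv] = "both"
    return out


def census_compare(
    profiles: pd.DataFrame,
    floor_pct: float = 0.1,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Response-type census with a region comparison.

    Parameters
    ----------
    profiles : DataFrame
        One row per recorded neuron with columns ``larva``, ``region`` and
        ``pattern`` (the all-zero pattern counts in the denominator but is
        not itself a census row).
    floor_pct : float
        A pattern is retained when it reaches at least this percentage of a
        region's total recorded neurons (pooled across larvae) in either
        region.

    Returns
    -------
    DataFrame
        One row per retained pattern: per-region pooled percentage and
        per-larva median, Wilcoxon rank-sum p across larvae between regions
        (exact distribution for group sizes <= 10 without ties), and the
        Benjamini-Hochberg adjusted q across retained patterns.
    """
    required = {"larva", "region", "pattern"}
    if not required <= set(profiles.columns):
        raise ValueError(f"profiles needs columns {sorted(required)}")
    regions = sorted(profiles["region"].unique())
    if len(regions) > 2:
        raise ValueError("census comparison supports at most two regions")

    # per-larva percentages of all recorded neurons, for every pattern > 0
    totals = profiles.groupby(["region", "larva"]).size()
    counts = (
        profiles[profiles["pattern"] > 0]
        .groupby(["region", "larva", "pattern"])
        .size()
    )
    pct = (counts / totals * 100.0).rename("pct")

    pooled_tot = profiles.groupby("region").size()
    pooled_cnt = profiles[profiles["pattern"] > 0].groupby(["region", "pattern"]).size()
    pooled_pct = (pooled_cnt / pooled_tot * 100.0).unstack(0, fill_value=0.0)

    retained = pooled_pct.index[(pooled_pct >= floor_pct).any(axis=1)]
    rows = []
    for pattern in retained:
        row: dict = {"pattern": int(pattern), "label": pattern_label(int(pattern))}
        samples = {}
        for region in regions:
            larvae = totals.loc[region].index
            vals = np.array(
                [
                    pct.get((region, larva, pattern), 0.0)
                    for larva in larvae
                ]
            )
            samples[region] = vals
            row[f"pct_{region}"] = pooled_pct.loc[pattern].get(region, 0.0)
            row[f"median_{region}"] = float(np.median(vals))
        if len(regions) == 2 and all(len(v) >= 2 for v in samples.values()):
            row["p"] = _ranksum_p(samples[regions[0]], samples[regions[1]])
        else:
            if len(regions) == 2:
                warnings.warn("a region has fewer than 2 larvae; comparison skipped")
            row["p"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    have_p = out["p"].notna()
    out["q"] = np.nan
    if have_p.any():
        _, q, *_ = multipletests(out.loc[have_p, "p"], alpha=fdr_alpha, method="fdr_bh")
        out.loc[have_p, "q"] = q
    return out.sort_values("pattern").reset_index(drop=True)


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact null for small tie-free samples,
    normal approximation with tie correction otherwise."""
    exact = (
        len(a) <= 10
        and len(b) <= 10
        and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def spatial_report(
    profiles: pd.DataFrame,
    quadrants: pd.DataFrame,
    patterns: list[int] | None = None,
) -> pd.DataFrame:
    """Hemisphere (and rostro-caudal) composition of each pattern group.

    ``profiles`` must align row-wise with ``quadrants`` (one row per
    neuron).  Returns, per pattern, the percentage of its neurons in each
    hemisphere, and in the rostral/caudal halves when an ``axis`` column is
    present.  Empty groups are omitted.
    """
    if len(profiles) != len(quadrants):
        raise ValueError("profiles and quadrants must align row-wise")
    df = pd.concat(
        [profiles.reset_index(drop=True), quadrants.reset_index(drop=True)], axis=1
    )
    if patterns is None:
        patterns = sorted(p for p in df["pattern"].unique() if p > 0)
    rows = []
    for pattern in patterns:
        grp = df[df["pattern"] == pattern]
        if grp.empty:
            continue
        n = len(grp)
        row = {
            "pattern": int(pattern),
            "label": pattern_label(int(pattern)),
            "n": n,
            "pct_right": 100.0 * (grp["hemisphere"] == "right").mean(),
            "pct_left": 100.0 * (grp["hemisphere"] == "left").mean(),
        }
        if "axis" in grp.columns:
            row["pct_caudal"] = 100.0 * (grp["axis"] == "caudal").mean()
            row["pct_rostral"] = 100.0 * (grp["axis"] == "rostral").mean()
        rows.append(row)
    return pd.DataFrame(rows)
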