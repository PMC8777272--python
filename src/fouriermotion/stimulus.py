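"""Synthesis and animation of square-wave and missing-fundamental gratings.

A square wave of spatial period :math:`\\lambda` decomposes into its odd
harmonics with amplitudes falling off as :math:`1/k`:

.. math::

    s(x) = \\frac{4}{\\pi} \\sum_{k=1,3,5,\\dots} \\frac{1}{k}
           \\sin\\!\\left(k \\cdot \\frac{2\\pi x}{\\lambda}\\right)

Removing the fundamental (``k = 1``) term yields the *missing-fundamental*
(fluted square wave) stimulus: its strongest component is the third harmonic,
so when the pattern is advanced in jumps of a quarter of the fundamental
wavelength, the third harmonic advances by three quarters of its own
wavelength — indistinguishable from moving *backwards* by one quarter.  The
luminance-defined (Fourier) motion energy therefore moves opposite to the
edges and features of the pattern.

This module builds the three stimulus variants used in the experiments
(square wave, missing fundamental, and a square wave at the third-harmonic
spatial frequency), animates them in quarter-cycle jumps, measures the
apparent direction of their dominant Fourier component, and assembles the
presentation protocol (black baseline followed by randomly ordered
static/moving presentations).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GratingSpec",
    "LuminanceProfile",
    "FrameSeries",
    "StimulusEpoch",
    "Protocol",
    "synth_profile",
    "quarter_cycle_sequence",
    "frame_sequence",
    "apparent_motion_direction",
    "cross_correlation_direction",
    "warp_to_screen",
    "unwarp_from_screen",
    "build_protocol",
    "build_orthogonal_protocol",
    "michelson_contrast",
    "bar_width_of",
]

Mode = Literal["square", "missing_fundamental", "third_harmonic"]

#: Stimulus conditions in canonical order (used throughout the pipeline).
CONDITIONS: tuple[str, ...] = ("square", "missing_fundamental", "third_harmonic")


@dataclass(frozen=True)
class GratingSpec:
    """Parametric description of a 1-D periodic luminance grating.

    Parameters
    ----------
    bar_width : float
        Half-period of the square wave, in degrees of visual angle.  The
        spatial period is ``2 * bar_width``.
    velocity : float
        Drift velocity in degrees of visual angle per second.
    mode : {"square", "missing_fundamental", "third_harmonic"}
        ``square``: truncated odd-harmonic square wave.
        ``missing_fundamental``: same series with the fundamental removed.
        ``third_harmonic``: square wave of one third the bar width.
    lum_min, lum_max : float
        Luminance of the dark/bright screen levels, in lux.
    n_harmonics : int or None
        Number of odd harmonics retained in the synthesis.  ``None`` flags an
        ideal two-level square wave (infinite series).
    phase : float
        Phase offset in degrees of the fundamental period.
    """

    bar_width: float = 16.0
    velocity: float = 180.0
    mode: Mode = "square"
    lum_min: float = 8.0
    lum_max: float = 800.0
    n_harmonics: int | None = 15
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.bar_width <= 0:
            raise ValueError("bar_width must be positive")
        if not (self.lum_max > self.lum_min >= 0):
            raise ValueError("need lum_max > lum_min >= 0")
        if self.n_harmonics is not None and self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1 (or None for an ideal square wave)")
        if self.mode not in CONDITIONS:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def wavelength(self) -> float:
        """Spatial period of the fundamental, in degrees."""
        return 2.0 * self.bar_width


@dataclass(frozen=True)
class LuminanceProfile:
    """Luminance as a function of spatial position over one or more periods."""

    positions: np.ndarray  # degrees (or flat-plane mm after warping)
    luminance: np.ndarray  # lux

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        lum = np.asarray(self.luminance, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "luminance", lum)
        if pos.shape != lum.shape or pos.ndim != 1:
            raise ValueError("positions and luminance must be matching 1-D arrays")
        if not np.all(np.isfinite(lum)):
            raise ValueError("luminance must be finite")
        steps = np.diff(pos)
        if len(steps) and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("positions must form a uniform grid")


@dataclass(frozen=True)
class FrameSeries:
    """Ordered sequence of luminance profiles sharing one spatial grid."""

    profiles: tuple[LuminanceProfile, ...]
    step_fraction: float  # fraction of the fundamental wavelength per frame

    def __post_init__(self) -> None:
        if not 0 < self.step_fraction <= 1:
            raise ValueError("step_fraction must lie in (0, 1]")
        grids = {p.positions.tobytes() for p in self.profiles}
        if len(grids) > 1:
            raise ValueError("all profiles must share one spatial grid")

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, i: int) -> LuminanceProfile:
        return self.profiles[i]

    def as_array(self) -> np.ndarray:
        """Stack luminance rows into a (frames, positions) array."""
        return np.stack([p.luminance for p in self.profiles])


@dataclass(frozen=True)
class StimulusEpoch:
    """One contiguous segment of the presentation timeline."""

    kind: Literal["black", "static", "moving"]
    condition: str | None
    direction: Literal["left", "right", "up", "down", "none"]
    duration: float
    onset: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        if self.kind == "black" and self.direction != "none":
            raise ValueError("black epochs have direction='none'")


@dataclass(frozen=True)
class Protocol:
    """Full presentation timeline: contiguous, non-overlapping epochs."""

    epochs: tuple[StimulusEpoch, ...]
    frame_rate: float
    seed: int
    reps_per_direction: int

    def __post_init__(self) -> None:
        t = 0.0
        for ep in self.epochs:
            if not math.isclose(ep.onset, t, abs_tol=1e-9):
                raise ValueError("epochs must be contiguous and non-overlapping")
            t = ep.onset + ep.duration

    @property
    def total_duration(self) -> float:
        last = self.epochs[-1]
        return last.onset + last.duration

    def moving_epochs(self) -> list[StimulusEpoch]:
        return [e for e in self.epochs if e.kind == "moving"]

    def to_json(self, path=None) -> str:
        payload = {
            "frame_rate": self.frame_rate,
            "seed": self.seed,
            "reps_per_direction": self.reps_per_direction,
            "epochs": [
                {
                    "kind": e.kind,
                    "condition": e.condition,
                    "direction": e.direction,
                    "duration": e.duration,
                    "onset": e.onset,
                }
                for e in self.epochs
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "Protocol":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, ValueError):
            with open(source) as fh:
                payload = json.load(fh)
        if isinstance(payload, str):  # a path was passed that json.loads accepted
            with open(payload) as fh:
                payload = json.load(fh)
        epochs = tuple(StimulusEpoch(**e) for e in payload["epochs"])
        return cls(
            epochs=epochs,
            frame_rate=payload["frame_rate"],
            seed=payload["seed"],
            reps_per_direction=payload["reps_per_direction"],
        )


# ---------------------------------------------------------------------------
# profile synthesis


def _harmonics_for(spec: GratingSpec) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic numbers (relative to the fundamental of ``bar_width``) and
    unit amplitudes for the requested mode, before luminance scaling."""
    n = spec.n_harmonics
    if n is None:
        raise RuntimeError("ideal square wave has no finite harmonic list")
    m = 2 * np.arange(n) + 1  # odd harmonics 1, 3, 5, ...
    amp = (4.0 / np.pi) / m
    if spec.mode == "square":
        return m, amp
    if spec.mode == "missing_fundamental":
        amp = amp.copy()
        amp[0] = 0.0  # F1 = 0
        return m, amp
    # third harmonic: a square wave at 3x the fundamental frequency
    return 3 * m, amp


def _series(spec: GratingSpec, theta: np.ndarray) -> np.ndarray:
    """Evaluate the unit-amplitude harmonic series at fundamental phase theta
    (radians of the *fundamental* period of ``bar_width``)."""
    k, amp = _harmonics_for(spec)
    return np.sum(amp[:, None] * np.sin(k[:, None] * theta[None, :]), axis=0)


def synth_profile(spec: GratingSpec, n_samples: int = 512) -> LuminanceProfile:
    """Synthesize one spatial period of the grating.

    The square-wave mode is affinely mapped to span exactly
    ``[lum_min, lum_max]``; the missing-fundamental mode reuses the square
    wave's scale factor so the harmonic amplitude ratios are preserved (its
    extrema consequently differ from the square wave's).  The mean luminance
    equals ``(lum_min + lum_max) / 2`` in every mode.

    Parameters
    ----------
    spec : GratingSpec
    n_samples : int
        Samples over one fundamental period ``2 * bar_width``.  Must provide
        a comfortable Nyquist margin for the highest retained harmonic.
    """
    factor = 3 if spec.mode == "third_harmonic" else 1
    if spec.n_harmonics is not None:
        needed = 8 * spec.n_harmonics * factor
        if n_samples < needed:
            raise ValueError(
                f"n_samples={n_samples} insufficient for n_harmonics="
                f"{spec.n_harmonics} in mode {spec.mode!r}; need at least {needed}"
            )
    elif n_samples < 8:
        raise ValueError("n_samples must be at least 8")

    lam = spec.wavelength
    x = np.linspace(0.0, lam, n_samples, endpoint=False)
    theta = 2.0 * np.pi * x / lam - np.deg2rad(spec.phase)
    mean = 0.5 * (spec.lum_min + spec.lum_max)

    if spec.n_harmonics is None:
        # ideal two-level square wave (sign of the sine of the fundamental)
        eff = 3.0 if spec.mode == "third_harmonic" else 1.0
        if spec.mode == "missing_fundamental":
            raise ValueError(
                "missing_fundamental requires a finite n_harmonics "
                "(an ideal square wave has no removable fundamental term)"
            )
        s = np.sign(np.sin(eff * theta))
        s[s == 0] = 1.0
        lum = mean + 0.5 * (spec.lum_max - spec.lum_min) * s
        return LuminanceProfile(x, lum)

    s = _series(spec, theta)
    # Scale chosen so the generating square wave spans [lum_min, lum_max];
    # shared by the missing-fundamental mode (same harmonic scale).
    ref = spec if spec.mode != "missing_fundamental" else replace(spec, mode="square")
    s_ref = _series(ref, theta)
    half_range = max(s_ref.max(), -s_ref.min())
    scale = 0.5 * (spec.lum_max - spec.lum_min) / half_range
    lum = mean + scale * s
    return LuminanceProfile(x, lum)


def michelson_contrast(profile: LuminanceProfile) -> float:
    """(Imax - Imin) / (Imax + Imin) of a periodic luminance profile."""
    lo, hi = profile.luminance.min(), profile.luminance.max()
    return (hi - lo) / (hi + lo)


def bar_width_of(profile: LuminanceProfile) -> float:
    """Mean half-period of a grating, measured from mean-level crossings."""
    lum = profile.luminance - profile.luminance.mean()
    signs = np.sign(lum)
    signs[signs == 0] = 1
    # the grid is one circular period: compare each sample with its circular
    # successor so the wrap-around crossing is counted too
    crossings = np.nonzero(signs != np.roll(signs, -1))[0]
    if len(crossings) < 2:
        raise ValueError("profile has fewer than two mean-level crossings")
    dx = profile.positions[1] - profile.positions[0]
    n = len(lum)
    gaps = np.diff(crossings, append=crossings[0] + n)
    return float(np.mean(gaps) * dx)


# ---------------------------------------------------------------------------
# animation


def frame_sequence(spec: GratingSpec, n_steps: int, step_fraction: float) -> FrameSeries:
    """Advance the pattern ``n_steps`` times by ``step_fraction`` of the
    fundamental wavelength per step, in the +position direction.

    Returns ``n_steps + 1`` frames (including the unshifted frame 0).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    profiles = []
    for i in range(n_steps + 1):
        # shifting the pattern by +d is a phase advance of the fundamental
        shifted = replace(spec, phase=spec.phase + 360.0 * step_fraction * i)
        profiles.append(synth_profile(shifted))
    return FrameSeries(tuple(profiles), step_fraction)


def quarter_cycle_sequence(spec: GratingSpec, n_steps: int) -> FrameSeries:
    """Animate the grating in quarter-wavelength jumps of the fundamental."""
    return frame_sequence(spec, n_steps, 0.25)


def apparent_motion_direction(series: FrameSeries) -> int:
    """Sign of the phase velocity of the dominant spatial-frequency component.

    Returns ``+1`` when the strongest Fourier component drifts along the
    pattern-shift (+position) direction and ``-1`` when it drifts opposite.
    Phase steps are unwrapped to the principal interval (-180°, 180°], which
    is what makes a 3/4-wavelength jump of the third harmonic read as a
    backwards quarter-wavelength jump.
    """
    if len(series) < 2:
        raise ValueError("need at least two frames")
    arr = series.as_array()
    spectra = np.fft.rfft(arr - arr.mean(axis=1, keepdims=True), axis=1)
    amplitude = np.abs(spectra).mean(axis=0)
    amplitude[0] = 0.0
    k = int(np.argmax(amplitude))
    if amplitude[k] <= 1e-12 * max(1.0, np.abs(arr).max()):
        raise ValueError("no dominant spatial-frequency component (flat series)")
    phases = np.angle(spectra[:, k])
    dphi = np.diff(phases)
    dphi = (dphi + np.pi) % (2.0 * np.pi) - np.pi  # principal interval
    # a pattern shift by +d multiplies the coefficient by exp(-i k d): the
    # implied displacement is -dphi / k
    displacement = -np.mean(dphi) / k
    if displacement == 0:
        raise ValueError("dominant component shows no phase motion")
    return 1 if displacement > 0 else -1


def cross_correlation_direction(series: FrameSeries) -> int:
    """Independent motion reading: argmax of the circular cross-correlation
    between successive frames (feature/pattern shift, not Fourier phase)."""
    arr = series.as_array()
    n = arr.shape[1]
    lags = []
    for a, b in zip(arr[:-1], arr[1:]):
        fa = np.fft.rfft(a - a.mean())
        fb = np.fft.rfft(b - b.mean())
        corr = np.fft.irfft(fb * np.conj(fa), n=n)
        lag = int(np.argmax(corr))
        if lag > n // 2:
            lag -= n
        lags.append(lag)
    mean_lag = float(np.mean(lags))
    if mean_lag == 0:
        raise ValueError("no detectable pattern shift between frames")
    return 1 if mean_lag > 0 else -1


# ---------------------------------------------------------------------------
# screen-geometry warp


def _flat_of_angle(theta_deg: np.ndarray, dist: float) -> np.ndarray:
    return dist * np.tan(np.deg2rad(theta_deg))


def _angle_of_flat(x: np.ndarray, dist: float) -> np.ndarray:
    return np.rad2deg(np.arctan(x / dist))


def warp_to_screen(
    profile: LuminanceProfile, radius: float, throw: float
) -> LuminanceProfile:
    """Pre-distort a profile for projection onto a cylindrical screen.

    The projector is modeled at the cylinder's center (the viewing position)
    with a flat virtual image plane at distance ``radius + throw``; a flat
    coordinate ``x`` maps to visual angle ``atan(x / (radius + throw))``.
    The input profile is defined on intended visual angle (degrees); the
    output is resampled onto a uniform flat-plane grid covering the same
    angular extent, so that after projection every bar subtends a constant
    visual angle.  ``radius = inf`` flags the identity (flat screen).
    """
    if radius == math.inf:
        return LuminanceProfile(profile.positions.copy(), profile.luminance.copy())
    if radius <= 0 or throw <= 0:
        raise ValueError("radius and throw must be positive")
    dist = radius + throw
    theta = profile.positions
    x_edges = _flat_of_angle(np.array([theta[0], theta[-1]]), dist)
    x = np.linspace(x_edges[0], x_edges[1], len(theta))
    theta_of_x = _angle_of_flat(x, dist)
    lum = np.interp(theta_of_x, theta, profile.luminance, period=None)
    return LuminanceProfile(x, lum)


def unwarp_from_screen(
    profile: LuminanceProfile, radius: float, throw: float
) -> LuminanceProfile:
    """Inverse of :func:`warp_to_screen` (up to interpolation error)."""
    if radius == math.inf:
        return LuminanceProfile(profile.positions.copy(), profile.luminance.copy())
    if radius <= 0 or throw <= 0:
        raise ValueError("radius and throw must be positive")
    dist = radius + throw
    x = profile.positions
    theta_edges = _angle_of_flat(np.array([x[0], x[-1]]), dist)
    theta = np.linspace(theta_edges[0], theta_edges[1], len(x))
    x_of_theta = _flat_of_angle(theta, dist)
    lum = np.interp(x_of_theta, x, profile.luminance)
    return LuminanceProfile(theta, lum)


# ---------------------------------------------------------------------------
# protocol assembly


def build_protocol(
    reps_per_direction: int = 20,
    conditions: Sequence[str] = CONDITIONS,
    seed: int = 0,
    timing: dict | None = None,
    directions: Sequence[str] = ("left", "right"),
    frame_rate: float = 3.91,
) -> Protocol:
    """Assemble the presentation timeline.

    A leading black epoch (baseline for spontaneous activity) is followed by
    a seeded uniform shuffle of the condition x direction presentations, each
    a static epoch then a moving epoch.

    Default timing: 240 s black, 8 s static, 12 s moving.
    """
    if reps_per_direction < 1:
        raise ValueError("reps_per_direction must be >= 1")
    if not conditions:
        raise ValueError("conditions must be non-empty")
    t = dict(black_s=240.0, static_s=8.0, moving_s=12.0)
    if timing:
        t.update(timing)
    if any(v <= 0 for v in t.values()):
        raise ValueError("timing values must be positive")

    presentations = [
        (c, d) for c in conditions for d in directions for _ in range(reps_per_direction)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(presentations))

    epochs = [StimulusEpoch("black", None, "none", t["black_s"], 0.0)]
    onset = t["black_s"]
    for idx in order:
        cond, direction = presentations[idx]
        epochs.append(StimulusEpoch("static", cond, direction, t["static_s"], onset))
        onset += t["static_s"]
        epochs.append(StimulusEpoch("moving", cond, direction, t["moving_s"], onset))
        onset += t["moving_s"]
    return Protocol(tuple(epochs), frame_rate, seed, reps_per_direction)


def build_orthogonal_protocol(
    reps_per_direction: int = 10,
    seed: int = 0,
    segment_s: float = 30.0,
    frame_rate: float = 3.91,
) -> Protocol:
    """Four-direction missing-fundamental variant.

    Each presentation is 30 s of moving missing-fundamental grating (down,
    up, left or right), followed by 30 s of black and 30 s of the static
    grating at the matching orientation; presentation order is a seeded
    shuffle over the direction multiset.
    """
    if reps_per_direction < 1:
        raise ValueError("reps_per_direction must be >= 1")
    directions = ["down", "up", "left", "right"]
    presentations = [d for d in directions for _ in range(reps_per_direction)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(presentations))
    epochs = [StimulusEpoch("black", None, "none", segment_s, 0.0)]
    onset = segment_s
    for idx in order:
        d = presentations[idx]
        epochs.append(
            StimulusEpoch("moving", "missing_fundamental", d, segment_s, onset)
        )
        onset += segment_s
        epochs.append(StimulusEpoch("black", None, "none", segment_s, onset))
        onset += segment_s
        epochs.append(
            StimulusEpoch("static", "missing_fundamental", d, segment_s, onset)
        )
        onset += segment_s
    return Protocol(tuple(epochs), frame_rate, seed, reps_per_direction)
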