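"""Ground-truthed synthetic data for every pipeline stage.

Emulates the study conditions of a two-photon session on larval zebrafish:
nuclear-localized GCaMP6f traces sampled at 3.91 Hz with an instant-rise,
2.88 s exponential-decay transient kernel, epoch-locked firing for neurons
with planted response patterns, Gaussian noise, slow multiplicative
baseline drift, renderable 2-D Gaussian-nucleus movies with movement
artifacts, and sawtooth optokinetic eye traces whose pursuit direction
follows the Fourier-energy direction of each stimulus.

Every generator is deterministic given its seed and emits a
:class:`GroundTruth` record for downstream parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .imaging import MovieStack
from .okr import EyeTrace
from .stimulus import Protocol
from .census import build_epoch_index, MOVING_CONDITIONS

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_traces",
    "render_movie",
    "simulate_eye_traces",
    "simulate_session",
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic session.

    ``planted_patterns`` maps a 6-bit response-pattern id (bit order of
    :data:`~fouriermotion.census.MOVING_CONDITIONS`) to the fraction of
    neurons carrying it; the remainder are silent.  ``snr`` is the transient
    peak amplitude over the noise sigma.  ``caudal_bias`` optionally biases
    a pattern's neurons toward the caudal half of the reference plane.
    """

    n_neurons: int = 200
    planted_patterns: dict[int, float] = field(default_factory=dict)
    snr: float = 5.0
    rate_hz: float = 3.91
    movie_size: int = 256
    nucleus_radius: float = 3.0  # pixels (µm at 1 µm/px)
    artifact_rate: float = 0.0  # per-frame probability
    drift: float = 0.0  # registration drift, px per frame
    seed: int = 0

    # trace model
    noise_sigma: float = 0.05  # ΔF/F units
    tau_decay: float = 2.88  # seconds
    baseline_f: float = 100.0  # raw fluorescence offset
    drift_amp: float = 0.05  # slow multiplicative baseline drift
    spont_rate: float = 0.0005  # spontaneous events per frame
    active_rate: float = 0.35  # events per frame during driven spans
    split: str = "moving_only"  # which stimulus part drives responders

    # spatial model
    caudal_bias: dict[int, float] = field(default_factory=dict)
    min_spacing: float = 0.0  # px between nucleus centers (0 = unconstrained)

    # eye model
    eye_rate_hz: float = 60.0
    pursuit_gain: float = 6.0  # deg/s slow-phase velocity
    saccade_interval: float = 2.0  # s between resetting saccades
    spont_interval: float = 4.0  # s between spontaneous saccades
    spont_amplitude: float = 8.0  # deg
    eye_noise_sigma: float = 0.2  # deg
    energy_opposite: tuple[str, ...] = ("missing_fundamental", "third_harmonic")

    def __post_init__(self) -> None:
        if sum(self.planted_patterns.values()) > 1 + 1e-9:
            raise ValueError("planted pattern fractions must sum to <= 1")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    patterns: np.ndarray  # (N,) pattern id per neuron, 0 = silent
    splits: list[str]  # per neuron: static_only | moving_only | both
    positions: np.ndarray  # (N, 2) row, col in the reference plane
    event_frames: list[list[int]]  # per neuron
    artifact_frames: np.ndarray  # sorted frame indices
    behavior: list[dict]  # per epoch: kind/condition/direction/state

    def to_json(self, path=None) -> str:
        payload = {
            "patterns": np.asarray(self.patterns).tolist(),
            "splits": list(self.splits),
            "positions": np.asarray(self.positions).tolist(),
            "event_frames": [list(map(int, e)) for e in self.event_frames],
            "artifact_frames": np.asarray(self.artifact_frames).tolist(),
            "behavior": self.behavior,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "GroundTruth":
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            patterns=np.asarray(payload["patterns"], dtype=int),
            splits=payload["splits"],
            positions=np.asarray(payload["positions"], dtype=float),
            event_frames=payload["event_frames"],
            artifact_frames=np.asarray(payload["artifact_frames"], dtype=int),
            behavior=payload["behavior"],
        )


# ---------------------------------------------------------------------------
# trace simulation


def _assign_patterns(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    patterns = np.zeros(config.n_neurons, dtype=int)
    start = 0
    for pattern, frac in config.planted_patterns.items():
        count = int(round(frac * config.n_neurons))
        patterns[start : start + count] = pattern
        start += count
    rng.shuffle(patterns)
    return patterns


def _positions_for(
    config: SynthConfig, patterns: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Scatter nuclei over the frame, honoring any planted caudal bias.

    The reference-plane convention used throughout: the midline is the
    vertical line col = size/2 (col > size/2 is the right hemisphere) and
    the rostro-caudal divide is the horizontal line row = size/2
    (row > size/2 is caudal).
    """
    size = config.movie_size
    margin = max(4.0, 2.0 * config.nucleus_radius)
    lo, hi = margin, size - margin
    mid = size / 2.0
    n = len(patterns)
    # row range per neuron, honoring any planted caudal bias
    row_lo = np.full(n, lo)
    row_hi = np.full(n, hi)
    for pattern, frac in config.caudal_bias.items():
        idx = np.nonzero(patterns == pattern)[0]
        caudal = rng.random(len(idx)) < frac
        row_lo[idx] = np.where(caudal, mid + 1.0, lo)
        row_hi[idx] = np.where(caudal, hi, mid - 1.0)
    pos = np.empty((n, 2))
    spacing2 = config.min_spacing**2
    for i in range(n):
        for _ in range(2000):
            cand = (rng.uniform(row_lo[i], row_hi[i]), rng.uniform(lo, hi))
            if spacing2 == 0 or i == 0:
                break
            d2 = np.sum((pos[:i] - cand) ** 2, axis=1)
            if d2.min() >= spacing2:
                break
        else:
            raise ValueError("could not place nuclei at the requested min_spacing")
        pos[i] = cand
    return pos


def _active_spans(
    pattern: int, split: str, index
) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    for bit, cond in enumerate(MOVING_CONDITIONS):
        if not (pattern >> bit & 1):
            continue
        if split in ("moving_only", "both"):
            spans.extend(index.moving(cond))
        if split in ("static_only", "both"):
            spans.extend(index.static(cond))
    return spans


def simulate_traces(
    config: SynthConfig, protocol: Protocol
) -> tuple[np.ndarray, GroundTruth]:
    """Per-neuron raw fluorescence with planted epoch-locked transients.

    Each neuron fires a Bernoulli-per-frame event process: ``spont_rate``
    everywhere, raised to ``active_rate`` inside the spans of its planted
    pattern's conditions.  Events are convolved with the indicator kernel
    (instant rise, ``exp(-t/tau_decay)``), scaled to ``snr x noise_sigma``
    in ΔF/F units, and embedded in a raw trace with additive Gaussian noise
    and a slow multiplicative baseline drift.

    Returns the (frames, neurons) raw array and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    index = build_epoch_index(protocol, config.rate_hz)
    n_frames = index.n_frames
    dt = 1.0 / config.rate_hz

    patterns = _assign_patterns(config, rng)
    splits = [config.split if p > 0 else "none" for p in patterns]
    positions = _positions_for(config, patterns, rng)

    # indicator kernel over ~5 decay constants
    kt = np.arange(int(round(5 * config.tau_decay / dt))) * dt
    kernel = np.exp(-kt / config.tau_decay)

    rates = np.full((n_frames, config.n_neurons), config.spont_rate)
    for i, (pattern, split) in enumerate(zip(patterns, splits)):
        for a, b in _active_spans(pattern, split, index):
            rates[a:b, i] = config.active_rate

    events = rng.random((n_frames, config.n_neurons)) < rates
    amp = config.snr * config.noise_sigma
    signal = np.empty_like(rates)
    for i in range(config.n_neurons):
        signal[:, i] = np.convolve(events[:, i] * amp, kernel)[:n_frames]

    t = np.arange(n_frames) * dt
    drift = 1.0 + config.drift_amp * np.sin(
        2.0 * np.pi * t / max(t[-1], 1.0) + rng.uniform(0, 2 * np.pi)
    )
    noise = rng.standard_normal((n_frames, config.n_neurons)) * config.noise_sigma
    raw = config.baseline_f * drift[:, None] * (1.0 + signal + noise)

    behavior = _planted_behavior(protocol, config)
    truth = GroundTruth(
        patterns=patterns,
        splits=splits,
        positions=positions,
        event_frames=[list(np.nonzero(events[:, i])[0]) for i in range(config.n_neurons)],
        artifact_frames=np.empty(0, dtype=int),
        behavior=behavior,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# movie rendering


def render_movie(
    traces: np.ndarray,
    positions: np.ndarray,
    config: SynthConfig,
    background: float = 10.0,
    shot_scale: float = 0.5,
) -> tuple[MovieStack, np.ndarray, np.ndarray]:
    """Render traces as a movie of 2-D Gaussian nuclei.

    Each neuron is a Gaussian blob (sigma = ``nucleus_radius / 2``) whose
    brightness follows its trace; shot-like noise scales with the square
    root of intensity; optional global linear drift and, at
    ``artifact_rate``, whole-frame random translations emulate movement
    artifacts.

    Returns ``(movie, label_image, artifact_frames)`` where ``label_image``
    is the ground-truth segmentation (disk of radius ``nucleus_radius`` per
    neuron) and ``artifact_frames`` the planted artifact frame indices.
    """
    rng = np.random.default_rng(config.seed + 1)
    traces = np.asarray(traces, dtype=float)
    n_frames, n_neurons = traces.shape
    size = config.movie_size
    positions = np.asarray(positions, dtype=float)
    if len(positions) != n_neurons:
        raise ValueError("positions must match the trace count")
    if np.any(positions < 0) or np.any(positions >= size):
        raise ValueError("positions must lie within the frame")
    if n_neurons > 1:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(positions).query(positions, k=2)
        if d[:, 1].mean() < 2 * config.nucleus_radius:
            import warnings

            warnings.warn("nucleus density high: mean spacing < nucleus diameter")

    rr, cc = np.mgrid[0:size, 0:size]
    sigma = config.nucleus_radius / 2.0
    footprint = np.zeros((n_neurons, size, size))
    labels = np.zeros((size, size), dtype=np.int32)
    for i in range(n_neurons):
        r0, c0 = positions[i]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        footprint[i] = np.exp(-d2 / (2 * sigma**2))
    for i in reversed(range(n_neurons)):  # earlier neurons win overlaps
        r0, c0 = positions[i]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        labels[d2 <= config.nucleus_radius**2] = i + 1

    frames = np.empty((n_frames, size, size))
    flat_fp = footprint.reshape(n_neurons, size * size)
    for t in range(n_frames):
        frames[t] = background + (traces[t] @ flat_fp).reshape(size, size)

    if config.drift:
        for t in range(n_frames):
            shift = int(round(config.drift * t))
            if shift:
                frames[t] = np.roll(frames[t], (shift, shift), axis=(0, 1))

    artifact_frames = np.nonzero(rng.random(n_frames) < config.artifact_rate)[0]
    for t in artifact_frames:
        dr, dc = rng.integers(15, 40, 2) * rng.choice([-1, 1], 2)
        frames[t] = np.roll(frames[t], (int(dr), int(dc)), axis=(0, 1))

    frames += rng.standard_normal(frames.shape) * np.sqrt(frames) * shot_scale
    np.clip(frames, 0, None, out=frames)
    movie = MovieStack(frames, frame_rate=config.rate_hz, pixel_size=1.0)
    return movie, labels, artifact_frames


# ---------------------------------------------------------------------------
# eye traces


def _planted_behavior(protocol: Protocol, config: SynthConfig) -> list[dict]:
    out = []
    for ep in protocol.epochs:
        if ep.kind == "moving" and ep.direction in ("left", "right"):
            direction = ep.direction
            if ep.condition in config.energy_opposite:
                direction = "left" if direction == "right" else "right"
            state = f"pursuit_{direction}"
        else:
            state = "spontaneous"
        out.append(
            {
                "kind": ep.kind,
                "condition": ep.condition,
                "direction": ep.direction,
                "onset": ep.onset,
                "duration": ep.duration,
                "state": state,
            }
        )
    return out


def simulate_eye_traces(
    protocol: Protocol, config: SynthConfig | None = None
) -> tuple[EyeTrace, GroundTruth]:
    """Sawtooth OKR eye-orientation traces with known behavioral states.

    During moving epochs the eyes pursue the stimulus' Fourier-energy
    direction (opposite to the pattern shift for the conditions listed in
    ``energy_opposite``) at ``pursuit_gain`` deg/s, reset by a saccade every
    ``saccade_interval`` seconds.  During black and static epochs the eyes
    produce spontaneous saccades of alternating direction every
    ``spont_interval`` seconds.  Both eyes are conjugate up to independent
    Gaussian angle noise.
    """
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(config.seed + 2)
    dt = 1.0 / config.eye_rate_hz
    n = int(round(protocol.total_duration * config.eye_rate_hz))
    time = np.arange(n) * dt
    angle = np.zeros(n)

    behavior = _planted_behavior(protocol, config)
    current = 0.0
    spont_sign = 1
    for ep in behavior:
        a = int(round(ep["onset"] * config.eye_rate_hz))
        b = min(n, int(round((ep["onset"] + ep["duration"]) * config.eye_rate_hz)))
        if b <= a:
            continue
        state = ep["state"]
        j = np.arange(b - a)
        if state.startswith("pursuit"):
            # pursuit to the left = angle slowly decreasing, reset by fast
            # +1 saccades back to the starting level (stationary sawtooth)
            slope = -config.pursuit_gain if state == "pursuit_left" else config.pursuit_gain
            reset_every = max(2, int(round(config.saccade_interval * config.eye_rate_hz)))
            seg = current + slope * ((j % reset_every) * dt)
        else:
            jump_every = max(2, int(round(config.spont_interval * config.eye_rate_hz)))
            n_jumps = j // jump_every
            # alternating-direction saccades toggle between two fixation
            # levels: +a, -a, +a, ... starting with spont_sign
            offsets = np.where(
                n_jumps % 2 == 1, spont_sign * config.spont_amplitude, 0.0
            )
            seg = current + offsets
            if n_jumps[-1] % 2 == 1:  # keep the alternation across epochs
                spont_sign = -spont_sign
        angle[a:b] = seg
        current = seg[-1]

    noise_l = rng.standard_normal(n) * config.eye_noise_sigma
    noise_r = rng.standard_normal(n) * config.eye_noise_sigma
    trace = EyeTrace(time, angle + noise_l, angle + noise_r)
    truth = GroundTruth(
        patterns=np.empty(0, dtype=int),
        splits=[],
        positions=np.empty((0, 2)),
        event_frames=[],
        artifact_frames=np.empty(0, dtype=int),
        behavior=behavior,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# one-call session


def simulate_session(
    config: SynthConfig, protocol: Protocol, with_movie: bool = False
) -> dict:
    """Full synthetic session: traces, ground truth, eye traces, optionally
    a rendered movie.  All components share the config's seed."""
    raw, truth = simulate_traces(config, protocol)
    eyes, eye_truth = simulate_eye_traces(protocol, config)
    out = {
        "raw": raw,
        "truth": truth,
        "eyes": eyes,
        "eye_truth": eye_truth,
        "protocol": protocol,
    }
    if with_movie:
        movie, labels, artifacts = render_movie(raw, truth.positions, config)
        truth.artifact_frames = artifacts
        out.update({"movie": movie, "labels": labels})
    return out
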