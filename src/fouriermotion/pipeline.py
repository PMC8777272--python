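"""End-to-end glue: raw ROI traces to response profiles.

Chains the standard stages — running-percentile baseline, ΔF/F, ROI sanity
filter, noise model, Bayesian event detection, response scoring and the
responsiveness rule — with the defaults used throughout the package.  Each
stage remains available individually in its own module; this wrapper only
fixes the plumbing between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .census import (
    MOVING_CONDITIONS,
    build_epoch_index,
    profile_neurons,
    responsive_matrix,
    score_responses,
)
from .events import (
    DffTrace,
    IndicatorKernel,
    compute_dff,
    detect_events,
    fit_noise,
    running_baseline,
    sanity_filter,
)
from .stimulus import Protocol

__all__ = ["analyze_traces"]


def analyze_traces(
    raw: np.ndarray,
    protocol: Protocol,
    rate_hz: float | None = None,
    missing: np.ndarray | None = None,
    confidence: float = 0.95,
    tau_decay: float = 2.88,
    conditions=MOVING_CONDITIONS,
    apply_sanity_filter: bool = True,
) -> dict:
    """Run the trace pipeline and return every intermediate product.

    Parameters
    ----------
    raw : (frames, ROIs) array
        Raw fluorescence traces.
    protocol : Protocol
        The presentation timeline the recording followed.
    missing : bool array, optional
        Per-frame artifact flags; flagged frames are excluded everywhere.

    Returns
    -------
    dict with keys ``index``, ``kept`` (ROI columns surviving the sanity
    filter), ``dff``, ``sigma`` (per kept ROI), ``significant`` (frames x
    kept ROIs), ``scores``, ``responsive`` and ``profiles``.
    """
    raw = np.asarray(raw, dtype=float)
    rate = protocol.frame_rate if rate_hz is None else rate_hz
    index = build_epoch_index(protocol, rate, n_frames=raw.shape[0])
    if missing is not None:
        raw = raw.copy()
        raw[np.asarray(missing, dtype=bool)] = np.nan

    baseline = running_baseline(raw, rate)
    if apply_sanity_filter:
        kept, report = sanity_filter(raw, baseline, rate)
    else:
        kept, report = np.arange(raw.shape[1]), {"fraction_discarded": 0.0}
    raw_k = raw[:, kept]
    base_k = baseline[:, kept]
    dff = compute_dff(raw_k, base_k)

    n = raw.shape[0]
    time = np.arange(n) / rate
    miss = np.isnan(raw_k)
    kernel = IndicatorKernel(tau_decay=tau_decay)
    significant = np.zeros_like(dff, dtype=bool)
    sigmas = np.empty(dff.shape[1])
    for j in range(dff.shape[1]):
        noise = fit_noise(dff[:, j])
        sigmas[j] = noise.sigma
        trace = DffTrace(time, np.nan_to_num(dff[:, j]), base_k[:, j], miss[:, j])
        significant[:, j] = detect_events(
            trace, noise, kernel, confidence
        ).significant

    scores = score_responses(significant.astype(float), index, conditions)
    responsive = responsive_matrix(significant, index, scores, conditions)
    profiles = profile_neurons(responsive, conditions)
    profiles["roi_original"] = kept[profiles["roi"].to_numpy()]
    return {
        "index": index,
        "kept": kept,
        "sanity_report": report,
        "dff": dff,
        "sigma": sigmas,
        "significant": significant,
        "scores": scores,
        "responsive": responsive,
        "profiles": profiles,
    }
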