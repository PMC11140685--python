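"""Canonical haemodynamic response model shared by simulation, task
regression and deconvolution.

The double-gamma form peaks at ~6 s with an undershoot at ~16 s and a
peak:undershoot ratio of 6, the standard convention of task-fMRI GLMs.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = ["canonical_hrf", "convolve_hrf", "events_to_boxcar"]


def canonical_hrf(
    sampling_interval_s: float,
    duration_s: float = 32.0,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Sampled double-gamma HRF, normalized to unit peak."""
    if sampling_interval_s <= 0:
        raise ValueError("sampling interval must be positive")
    t = np.arange(0.0, duration_s, sampling_interval_s)
    h = _gamma.pdf(t, peak_delay_s) - _gamma.pdf(t, undershoot_delay_s) / ratio
    peak = np.abs(h).max()
    if peak > 0:
        h = h / peak
    return h


def events_to_boxcar(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_timepoints: int,
    sampling_interval_s: float,
) -> np.ndarray:
    """Sum of amplitude-scaled boxcars on the scan grid.

    An event occupies the frames whose acquisition times fall inside
    [onset, onset + duration).
    """
    x = np.zeros(n_timepoints)
    t = np.arange(n_timepoints) * sampling_interval_s
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        inside = (t >= onset) & (t < onset + dur)
        x[inside] += amp
    return x


def convolve_hrf(signal: np.ndarray, sampling_interval_s: float) -> np.ndarray:
    """Convolve a stimulus function with the canonical HRF, trimmed to length."""
    h = canonical_hrf(sampling_interval_s)
    return np.convolve(signal, h)[: signal.shape[0]]
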