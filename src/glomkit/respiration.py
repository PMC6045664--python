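"""Breath detection and instantaneous-frequency statistics.

Thermocouple or intranasal-pressure traces are band-pass filtered and each
breath cycle is marked by its inhalation peak. The instantaneous frequency
is the reciprocal of each inter-breath interval; the summary statistic is
its arithmetic mean over a fixed analysis window (5 minutes by default).
Basic circular statistics support phase comparisons between simultaneous
respiration signals.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .datatypes import BreathEvents, RespirationTrace


def detect_breaths(
    trace: RespirationTrace,
    band: tuple[float, float] = (0.5, 15.0),
    min_prominence: float = 0.5,
    refractory: float = 0.1,
    polarity: int = 1,
) -> BreathEvents:
    """Band-pass filter then pick one inhalation peak per breath cycle.

    ``min_prominence`` is relative to the filtered signal's standard
    deviation, making detection invariant to amplitude scaling;
    ``refractory`` (s) sets the minimum inter-peak gap. ``polarity`` -1
    flips the signal for sensors with inverted breath deflections.
    """
    lo, hi = band
    nyq = trace.fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError("band must lie within (0, fs/2)")
    sos = butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    filt = sosfiltfilt(sos, polarity * trace.samples)
    sd = float(filt.std())
    if sd == 0:
        return BreathEvents(breath_times=np.empty(0), status="no_peaks")
    peaks, _ = find_peaks(
        filt,
        prominence=min_prominence * sd,
        distance=max(int(round(refractory * trace.fs)), 1),
    )
    if peaks.size == 0:
        return BreathEvents(breath_times=np.empty(0), status="no_peaks")
    # the band-pass filter skews asymmetric waveforms; snap each event to
    # the local maximum of the raw signal so breath times are sample-accurate
    raw = polarity * trace.samples
    half = max(int(round(0.5 * refractory * trace.fs)), 1)
    refined = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        lo_i = max(p - half, 0)
        hi_i = min(p + half + 1, raw.size)
        refined[i] = lo_i + int(np.argmax(raw[lo_i:hi_i]))
    refined = np.unique(refined)
    return BreathEvents(breath_times=refined / trace.fs, status="ok")


def mean_instantaneous_frequency(
    events: BreathEvents, window: float = 300.0
) -> tuple[float, str]:
    """Mean of 1/interval over inter-breath intervals fully inside the window.

    Returns (frequency in Hz, status); fewer than two breaths in the window
    gives (NaN, "undefined").
    """
    bt = events.breath_times
    inside = bt[(bt >= 0) & (bt <= window)]
    if inside.size < 2:
        return float("nan"), "undefined"
    return float(np.mean(1.0 / np.diff(inside))), "ok"


def instantaneous_frequency_histogram(
    events: BreathEvents, window: float = 300.0, bins: int = 40,
    freq_range: tuple[float, float] = (0.0, 5.0),
):
    """Histogram of instantaneous frequency in the window (counts, edges)."""
    bt = events.breath_times
    inside = bt[(bt >= 0) & (bt <= window)]
    if_ = 1.0 / np.diff(inside) if inside.size >= 2 else np.empty(0)
    return np.histogram(if_, bins=bins, range=freq_range)


def circular_phase_stats(phases: np.ndarray) -> tuple[float, float]:
    """Circular mean angle and resultant vector length of phase samples.

    mean = arg(sum exp(i*phi)), resultant = |sum exp(i*phi)| / n. The
    resultant is 1 for perfectly aligned phases and near 1/sqrt(n) for
    uniformly random ones.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("phases must be non-empty")
    if not np.all(np.isfinite(phases)):
        raise ValueError("phases must be finite")
    z = np.exp(1j * phases).sum()
    return float(np.angle(z)), float(np.abs(z) / phases.size)
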