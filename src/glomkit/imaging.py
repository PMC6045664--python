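"""dF/F computation, bleach correction and response-amplitude extraction.

The fractional fluorescence change is (F(t) - F) / F with F the mean raw
fluorescence over a pre-stimulus baseline window. Photobleaching is removed
divisively by fitting a single exponential a*exp(-t/tau) + c to a signal-free
segment (blank trials for multiphoton, the baseline period for
epifluorescence) and dividing the trace by the fitted decay normalized to
its initial value, which leaves fractional signals unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datatypes import (
    FluorescenceMovie,
    ResponseTable,
    RoiSet,
    TraceMatrix,
    validate_trial_table,
)


def extract_roi_traces(movie: FluorescenceMovie, rois: RoiSet) -> np.ndarray:
    """Mean intensity over each ROI's pixels, per frame.

    Returns an (n_rois, n_frames) array ordered as ``rois.roi_ids``.
    """
    if rois.label_image.shape != movie.frames.shape[1:]:
        raise ValueError("ROI label image shape must match movie frames")
    flat = movie.frames.reshape(movie.n_frames, -1)
    labels = rois.label_image.ravel()
    out = np.empty((rois.n_rois, movie.n_frames))
    for i, rid in enumerate(rois.roi_ids):
        idx = np.flatnonzero(labels == rid)
        if idx.size == 0:
            raise ValueError(f"ROI {rid} has no pixels")
        out[i] = flat[:, idx].mean(axis=1)
    return out


def compute_dff(
    raw_trace: np.ndarray, baseline_window: tuple[float, float], frame_rate: float
) -> tuple[np.ndarray, float]:
    """(F - F0) / F0 with F0 the mean raw fluorescence over the baseline window.

    ``baseline_window`` is a half-open [start, stop) interval in seconds.
    Returns the dF/F trace and F0.
    """
    raw = np.asarray(raw_trace, dtype=float)
    i0, i1 = window_to_frames(baseline_window, frame_rate, raw.size)
    if i1 <= i0:
        raise ValueError("baseline window must contain at least one frame")
    f0 = float(raw[i0:i1].mean())
    if f0 <= 0:
        raise ValueError(f"non-physical baseline fluorescence F0 = {f0:g}")
    return (raw - f0) / f0, f0


def window_to_frames(
    window: tuple[float, float], frame_rate: float, n_frames: int
) -> tuple[int, int]:
    """Map a half-open [start, stop) second interval to frame indices by floor."""
    i0 = int(np.floor(window[0] * frame_rate))
    i1 = int(np.floor(window[1] * frame_rate))
    return max(i0, 0), min(i1, n_frames)


@dataclass
class BleachFit:
    amplitude: float
    tau: float
    offset: float
    status: str  # "ok", "flat", "fit_failed"
    residual_norm: float = np.nan


def _exp_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def fit_bleach_exponential(t: np.ndarray, y: np.ndarray) -> BleachFit:
    """Least-squares fit of a*exp(-t/tau) + c to the designated samples."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise ValueError("bleach fit needs at least 5 frames")
    span = float(t[-1] - t[0]) or 1.0
    y_range = float(y.max() - y.min())
    if y_range < 1e-12 * max(abs(y.mean()), 1.0):
        # constant input: tau -> infinity branch, nothing to correct
        return BleachFit(0.0, np.inf, float(y.mean()), "flat", 0.0)
    p0 = (y[0] - y[-1], span / 2.0, y[-1])
    try:
        popt, _ = curve_fit(
            _exp_model, t - t[0], y, p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return BleachFit(np.nan, np.nan, np.nan, "fit_failed")
    a, tau, c = popt
    resid = float(np.linalg.norm(y - _exp_model(t - t[0], *popt)))
    if tau <= 0 or not np.isfinite(tau):
        return BleachFit(a, tau, c, "fit_failed", resid)
    return BleachFit(float(a), float(tau), float(c), "ok", resid)


def correct_bleaching(
    trace: np.ndarray,
    frame_rate: float,
    mode: str = "baseline_period",
    fit_window: tuple[float, float] | None = None,
    blank_segments: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, BleachFit]:
    """Divide out a fitted single-exponential photobleaching decay.

    mode "baseline_period" fits over ``fit_window`` (epifluorescence);
    mode "blank_trials" fits over the concatenated ``blank_segments``
    (multiphoton). On a failed or non-physical fit the trace is returned
    uncorrected with the failure recorded in the fit status.
    """
    y = np.asarray(trace, dtype=float)
    t = np.arange(y.size) / frame_rate
    if mode == "baseline_period":
        if fit_window is None:
            raise ValueError("baseline_period mode requires fit_window")
        i0, i1 = window_to_frames(fit_window, frame_rate, y.size)
        sel = np.arange(i0, i1)
    elif mode == "blank_trials":
        if not blank_segments:
            raise ValueError("blank_trials mode requires blank_segments")
        parts = []
        for w in blank_segments:
            i0, i1 = window_to_frames(w, frame_rate, y.size)
            parts.append(np.arange(i0, i1))
        sel = np.concatenate(parts)
    else:
        raise ValueError(f"unknown bleach-correction mode: {mode!r}")
    if sel.size < 5:
        raise ValueError("bleach fit span must contain at least 5 frames")

    fit = fit_bleach_exponential(t[sel], y[sel])
    if fit.status != "ok":
        return y.copy(), fit
    # evaluate the fitted decay on the full timeline, anchored at the fit start
    decay = _exp_model(t - t[sel[0]], fit.amplitude, fit.tau, fit.offset)
    d0 = decay[0]
    if d0 <= 0 or np.any(decay <= 0):
        return y.copy(), BleachFit(fit.amplitude, fit.tau, fit.offset,
                                   "fit_failed", fit.residual_norm)
    return y / (decay / d0), fit


def response_amplitude(
    dff: np.ndarray, onset: float, frame_rate: float, window: float = 5.0
) -> float:
    """Mean dF/F over the half-open [onset, onset + window) interval."""
    dff = np.asarray(dff, dtype=float)
    if window < 1.0 / frame_rate:
        raise ValueError("window must cover at least one frame")
    i0, i1 = window_to_frames((onset, onset + window), frame_rate, dff.size)
    if i1 > dff.size or i0 >= dff.size:
        raise ValueError("response window extends past the trace")
    return float(dff[i0:i1].mean())


def build_response_table(
    traces: TraceMatrix, trials: pd.DataFrame, window: float = 5.0
) -> ResponseTable:
    """Repeat-averaged glomerulus x odor amplitudes plus per-blank amplitudes.

    Amplitudes are the mean dF/F in the ``window`` seconds after onset,
    averaged (unweighted) over however many repeats of each odor exist.
    """
    validate_trial_table(trials)
    odor_ids = sorted(int(o) for o in trials.loc[~trials["is_blank"], "odor_id"].unique())
    n_g = traces.n_rois
    trial_dur = traces.dff.shape[2] / traces.frame_rate

    replicate: list[list[np.ndarray]] = []
    blank_cols: list[np.ndarray] = []
    amp = np.zeros((n_g, len(odor_ids)))
    per_trial_onset = trials["onset"].to_numpy() % trial_dur

    for g in range(n_g):
        row: list[np.ndarray] = []
        for j, odor in enumerate(odor_ids):
            ks = trials.index[trials["odor_id"] == odor].to_numpy()
            vals = np.array(
                [
                    response_amplitude(
                        traces.dff[g, k], per_trial_onset[k], traces.frame_rate, window
                    )
                    for k in ks
                ]
            )
            row.append(vals)
            amp[g, j] = vals.mean()
        replicate.append(row)
    blank_idx = trials.index[trials["is_blank"]].to_numpy()
    blanks = np.array(
        [
            [
                response_amplitude(
                    traces.dff[g, k], per_trial_onset[k], traces.frame_rate, window
                )
                for k in blank_idx
            ]
            for g in range(n_g)
        ]
    ) if blank_idx.size else np.zeros((n_g, 0))

    return ResponseTable(
        amplitude=amp,
        odor_ids=odor_ids,
        replicate_amplitudes=replicate,
        blank_amplitudes=blanks,
    )


def count_responsive(
    responses: ResponseTable, threshold: float
) -> tuple[pd.Series, np.ndarray]:
    """Per-odor counts of glomeruli with amplitude strictly above threshold.

    Returns the counts (indexed by odor id) and the boolean mask.
    """
    if not np.isfinite(threshold):
        mask = np.zeros_like(responses.amplitude, dtype=bool)
    else:
        mask = responses.amplitude > threshold
    counts = pd.Series(
        mask.sum(axis=0), index=pd.Index(responses.odor_ids, name="odor_id"),
        name="n_responsive",
    )
    return counts, mask


def movie_to_traces(
    movie: FluorescenceMovie,
    rois: RoiSet,
    trials: pd.DataFrame,
    bleach_mode: str | None = None,
) -> TraceMatrix:
    """Extract per-trial dF/F traces from a movie: ROI means, optional
    bleach correction over the whole recording, then per-trial baselining.

    Trials are assumed to tile the recording contiguously and equally.
    """
    validate_trial_table(trials)
    raw = extract_roi_traces(movie, rois)
    fr = movie.frame_rate
    n_trials = len(trials)
    frames_per_trial = movie.n_frames // n_trials
    trial_dur = frames_per_trial / fr
    onsets_in_trial = trials["onset"].to_numpy() % trial_dur

    if bleach_mode == "blank_trials":
        # blank trials carry no stimulus, so their full span is signal-free
        segs = [
            (k * trial_dur, (k + 1) * trial_dur)
            for k in trials.index[trials["is_blank"]]
        ]
        corrected = np.array(
            [correct_bleaching(r, fr, "blank_trials", blank_segments=segs)[0]
             for r in raw]
        )
    elif bleach_mode == "baseline_period":
        corrected = np.array(
            [
                correct_bleaching(
                    r, fr, "baseline_period",
                    fit_window=(0.0, onsets_in_trial[0]),
                )[0]
                for r in raw
            ]
        )
    else:
        corrected = raw

    dff = np.empty((len(rois.roi_ids), n_trials, frames_per_trial))
    f0 = np.empty((len(rois.roi_ids), n_trials))
    for k in range(n_trials):
        seg = corrected[:, k * frames_per_trial : (k + 1) * frames_per_trial]
        for g in range(seg.shape[0]):
            dff[g, k], f0[g, k] = compute_dff(
                seg[g], (0.0, onsets_in_trial[k]), fr
            )
    return TraceMatrix(
        dff=dff,
        frame_rate=fr,
        onset_in_trial=float(onsets_in_trial[0]),
        baseline_window=(0.0, float(onsets_in_trial.min())),
        f_baseline=f0,
    )
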