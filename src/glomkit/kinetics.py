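"""Single-trial rise-time and decay-constant estimation for dF/F transients.

Rise time is the interval from the first frame at which the signal exceeds
the baseline mean by ``k`` baseline standard deviations (k = 3.5 by default)
to the peak of the response. The decay constant comes from a least-squares
single-exponential fit starting at the peak. Both estimators operate on
individual trials, never on repeat-averaged traces, so that trial-to-trial
onset variability (e.g. from respiration) is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .imaging import window_to_frames


@dataclass
class KineticsResult:
    rise_time: float  # s; NaN unless fit_status == "ok"
    decay_tau: float  # s; NaN unless decay fit succeeded
    peak_time: float  # s
    peak_value: float  # dF/F
    baseline_mean: float
    baseline_sd: float
    fit_status: str  # "ok", "no_crossing", "fit_failed"
    residual_norm: float = np.nan


def rise_time(
    dff: np.ndarray,
    frame_rate: float,
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
    k: float = 3.5,
) -> KineticsResult:
    """Time from the k-SD threshold crossing to the response peak.

    The crossing is the first frame in ``response_window`` whose value
    exceeds baseline_mean + k * baseline_sd; the peak is the maximum of the
    response window (earliest frame on ties). Status "no_crossing" is
    returned when the signal never crosses, when the peak precedes the
    crossing, or when the baseline is degenerate (zero variance on a
    constant trace).
    """
    y = np.asarray(dff, dtype=float)
    b0, b1 = window_to_frames(baseline_window, frame_rate, y.size)
    if b1 - b0 < 3:
        raise ValueError("baseline window must contain at least 3 frames")
    r0, r1 = window_to_frames(response_window, frame_rate, y.size)
    if r1 <= r0:
        raise ValueError("response window is empty")
    mu = float(y[b0:b1].mean())
    sd = float(y[b0:b1].std(ddof=0))

    resp = y[r0:r1]
    peak_rel = int(np.argmax(resp))  # earliest frame on ties
    peak_idx = r0 + peak_rel
    peak_t = peak_idx / frame_rate
    peak_v = float(resp[peak_rel])

    if sd == 0 and np.ptp(y) == 0:
        return KineticsResult(np.nan, np.nan, peak_t, peak_v, mu, sd, "no_crossing")
    above = np.flatnonzero(resp > mu + k * sd)
    if above.size == 0 or r0 + above[0] > peak_idx:
        return KineticsResult(np.nan, np.nan, peak_t, peak_v, mu, sd, "no_crossing")
    cross_idx = r0 + int(above[0])
    rt = (peak_idx - cross_idx) / frame_rate
    return KineticsResult(rt, np.nan, peak_t, peak_v, mu, sd, "ok")


def _decay_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def decay_constant(
    dff: np.ndarray,
    frame_rate: float,
    peak_time: float,
    fit_end: float | None = None,
) -> KineticsResult:
    """Single-exponential decay constant fitted from the peak onward.

    Fits a * exp(-(t - t_peak)/tau) + c over [peak_time, fit_end] (fit_end
    defaults to the end of the trace). Non-convergence, a non-positive tau,
    or a trace that rises over the fit span yields status "fit_failed".
    """
    y = np.asarray(dff, dtype=float)
    n = y.size
    if fit_end is None:
        fit_end = n / frame_rate
    i0, i1 = window_to_frames((peak_time, fit_end), frame_rate, n)
    if i1 - i0 < 5:
        raise ValueError("need at least 5 frames between peak and fit_end")
    seg = y[i0:i1]
    t = (np.arange(i0, i1) - i0) / frame_rate
    peak_t = i0 / frame_rate
    peak_v = float(seg[0])

    if np.ptp(seg) < 1e-12 * max(abs(seg.mean()), 1.0):
        return KineticsResult(np.nan, np.nan, peak_t, peak_v, np.nan, np.nan,
                              "fit_failed")
    # a robust linear trend check: clearly increasing traces are not decays
    slope = np.polyfit(t, seg, 1)[0]
    if slope > 0 and seg[-1] > seg[0]:
        return KineticsResult(np.nan, np.nan, peak_t, peak_v, np.nan, np.nan,
                              "fit_failed")
    p0 = (seg[0] - seg[-1], max((t[-1] - t[0]) / 3.0, 1.0 / frame_rate), seg[-1])
    try:
        popt, _ = curve_fit(
            _decay_model, t, seg, p0=p0,
            bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return KineticsResult(np.nan, np.nan, peak_t, peak_v, np.nan, np.nan,
                              "fit_failed")
    a, tau, c = popt
    resid = float(np.linalg.norm(seg - _decay_model(t, *popt)))
    if tau <= 0 or not np.isfinite(tau):
        return KineticsResult(np.nan, np.nan, peak_t, peak_v, np.nan, np.nan,
                              "fit_failed", resid)
    # a time constant much longer than the fit span is unidentifiable
    # (near-flat segment): reject rather than report an arbitrary value
    if tau > 2.0 * (t[-1] - t[0]):
        return KineticsResult(np.nan, np.nan, peak_t, peak_v, np.nan, np.nan,
                              "fit_failed", resid)
    return KineticsResult(np.nan, float(tau), peak_t, peak_v, np.nan, np.nan,
                          "ok", resid)


def analyze_trial(
    dff: np.ndarray,
    frame_rate: float,
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
    k: float = 3.5,
    fit_end: float | None = None,
) -> KineticsResult:
    """Rise time and decay constant of one trial's transient, combined.

    Trials whose rise estimation fails keep status "no_crossing"; a failed
    decay fit after a successful rise keeps the rise time with status
    "fit_failed" on the decay side recorded in ``decay_tau`` being NaN.
    """
    r = rise_time(dff, frame_rate, baseline_window, response_window, k)
    if r.fit_status != "ok":
        return r
    try:
        d = decay_constant(dff, frame_rate, r.peak_time, fit_end)
    except ValueError:
        # peak too close to the trial end for a meaningful fit
        d = KineticsResult(np.nan, np.nan, r.peak_time, r.peak_value,
                           np.nan, np.nan, "fit_failed")
    return KineticsResult(
        rise_time=r.rise_time,
        decay_tau=d.decay_tau,
        peak_time=r.peak_time,
        peak_value=r.peak_value,
        baseline_mean=r.baseline_mean,
        baseline_sd=r.baseline_sd,
        fit_status="ok" if d.fit_status == "ok" else "fit_failed",
        residual_norm=d.residual_norm,
    )
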