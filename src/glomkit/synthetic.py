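"""Seeded generators for imaging, respiration and open-arena data.

Every generator records its full ground truth so that downstream estimators
(amplitude, rise time, decay constant, breath rate, localization latency)
can be validated by parameter recovery. The same config and seed always
produce bit-identical output.

The generative model for a tuned glomerulus-odor trial is a linear ramp
from zero at odor onset to the pair's peak amplitude over ``rise_interval``
seconds, followed by single-exponential decay with time constant
``decay_tau``. Untuned pairs and blank trials carry noise only. In movie
mode the fluorescence of a glomerulus is

    F(t) = F0 * exp(-t / bleach_tau) * (1 + transient(t)) + noise,

so dividing out the bleach decay and normalizing by baseline recovers the
transient exactly in the noiseless limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    ArenaGeometry,
    FluorescenceMovie,
    GroundTruth,
    RespirationTrace,
    RoiSet,
    TraceMatrix,
    Trajectory,
    make_trial_table,
)


@dataclass
class SimImagingConfig:
    """Parameters of the synthetic imaging experiment.

    Defaults mirror the multiphoton recording configuration: 4 frames/s,
    a 15-odor panel delivered 3-5 times for 5 s each, with blank (solvent)
    trials interleaved to supply the noise distribution.
    """

    n_glomeruli: int = 20
    field_of_view: tuple[int, int] = (128, 128)  # pixels (h, w)
    frame_rate: float = 4.0  # Hz; 8 for epifluorescence
    n_odors: int = 15
    n_repeats: int = 3
    odor_duration: float = 5.0  # s; 2 for concentration series
    baseline_duration: float = 5.0  # s pre-odor per trial
    inter_trial_gap: float = 15.0  # s post-odor per trial
    amplitude_mu: float = -2.3  # lognormal log-mean of tuned peak dF/F
    amplitude_sigma: float = 1.0  # lognormal log-sd (heavy-tailed tuning)
    responder_fraction: float = 0.3  # P(glomerulus-odor pair is tuned)
    fixed_amplitude: float | None = None  # overrides the lognormal law if set
    rise_interval: float = 2.35  # s, designed onset-to-peak
    decay_tau: float = 4.74  # s
    bleach_tau: float = 600.0  # s; np.inf disables bleaching
    noise_sd: float = 0.01  # dF/F units per ROI trace
    blank_trials: int = 3
    onset_jitter: float = 0.0  # s, uniform sub-frame jitter added to onsets
    baseline_level: float = 100.0  # raw fluorescence inside glomeruli
    background_level: float = 10.0  # raw fluorescence outside
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("odor_duration", "baseline_duration", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.inter_trial_gap < 0 or self.onset_jitter < 0:
            raise ValueError("durations must be non-negative")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.n_glomeruli < 1 or self.n_odors < 1 or self.n_repeats < 1:
            raise ValueError("counts must be >= 1")
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be positive (np.inf disables)")

    @property
    def trial_duration(self) -> float:
        return self.baseline_duration + self.odor_duration + self.inter_trial_gap

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_duration * self.frame_rate))

    @property
    def n_trials(self) -> int:
        return self.n_odors * self.n_repeats + self.blank_trials


def transient_waveform(
    t: np.ndarray, onset: float, amplitude: float, rise: float, tau: float
) -> np.ndarray:
    """Closed-form ramp-plus-exponential transient evaluated at times ``t``."""
    out = np.zeros_like(t, dtype=float)
    peak_t = onset + rise
    rising = (t > onset) & (t <= peak_t)
    if rise > 0:
        out[rising] = amplitude * (t[rising] - onset) / rise
    else:
        rising = np.zeros_like(rising)
    decaying = t > peak_t
    out[decaying] = amplitude * np.exp(-(t[decaying] - peak_t) / tau)
    return out


def expected_window_amplitude(
    config: SimImagingConfig, peak_amplitude: float | np.ndarray,
    window: float = 5.0, onset: float | None = None,
) -> float | np.ndarray:
    """Noiseless mean dF/F over the response window for a given peak amplitude.

    The measured response amplitude is the frame-mean of the transient over
    the half-open [onset, onset + window) interval, which for the ramp +
    exponential waveform is a fixed fraction of the peak. Used to align
    ground-truth peak amplitudes with pipeline window means exactly.
    """
    if onset is None:
        onset = config.baseline_duration
    t = np.arange(config.frames_per_trial) / config.frame_rate
    unit = transient_waveform(t, onset, 1.0, config.rise_interval, config.decay_tau)
    i0 = int(np.floor(onset * config.frame_rate))
    i1 = int(np.floor((onset + window) * config.frame_rate))
    frac = float(unit[i0:i1].mean())
    return peak_amplitude * frac


def _draw_tuning(config: SimImagingConfig, rng: np.random.Generator) -> np.ndarray:
    """Glomerulus x odor peak amplitudes; zeros for untuned pairs."""
    tuned = rng.random((config.n_glomeruli, config.n_odors)) < config.responder_fraction
    if config.fixed_amplitude is not None:
        amps = np.full((config.n_glomeruli, config.n_odors), config.fixed_amplitude)
    else:
        amps = rng.lognormal(
            config.amplitude_mu, config.amplitude_sigma,
            size=(config.n_glomeruli, config.n_odors),
        )
    return np.where(tuned, amps, 0.0)


def _build_trials(config: SimImagingConfig, rng: np.random.Generator):
    """Shuffled trial order (odor x repeat plus blanks) with absolute times."""
    entries = [(o, r) for o in range(config.n_odors) for r in range(config.n_repeats)]
    entries += [(-1, r) for r in range(config.blank_trials)]
    order = rng.permutation(len(entries))
    records = []
    onsets_in_trial = np.empty(len(entries))
    for k, idx in enumerate(order):
        odor, rep = entries[idx]
        jitter = rng.uniform(0, config.onset_jitter) if config.onset_jitter else 0.0
        t0 = k * config.trial_duration
        onsets_in_trial[k] = config.baseline_duration + jitter
        records.append(
            {
                "trial": k,
                "odor_id": odor,
                "concentration": float("nan"),
                "onset": t0 + config.baseline_duration + jitter,
                "offset": t0 + config.baseline_duration + jitter + config.odor_duration,
                "is_blank": odor < 0,
                "repeat_index": rep,
            }
        )
    return make_trial_table(records), onsets_in_trial


def generate_traces(config: SimImagingConfig):
    """Per-ROI dF/F traces straight from the generative model (no pixel stage).

    Returns ``(TraceMatrix, trial_table, GroundTruth)``. Traces are noisy
    realizations of the closed-form transient; blank trials and untuned
    pairs are pure noise. Bleaching is a property of raw fluorescence and
    therefore only enters movie mode.
    """
    rng = np.random.default_rng(config.seed)
    amps = _draw_tuning(config, rng)
    trials, onsets_in_trial = _build_trials(config, rng)

    nf = config.frames_per_trial
    t = np.arange(nf) / config.frame_rate
    dff = np.zeros((config.n_glomeruli, config.n_trials, nf))
    for k in range(config.n_trials):
        odor = int(trials.loc[k, "odor_id"])
        if odor < 0:
            continue
        onset = onsets_in_trial[k]
        for g in range(config.n_glomeruli):
            a = amps[g, odor]
            if a > 0:
                dff[g, k] = transient_waveform(
                    t, onset, a, config.rise_interval, config.decay_tau
                )
    if config.noise_sd > 0:
        dff += rng.normal(0.0, config.noise_sd, size=dff.shape)

    tm = TraceMatrix(
        dff=dff,
        frame_rate=config.frame_rate,
        onset_in_trial=config.baseline_duration,
        baseline_window=(0.0, config.baseline_duration),
    )
    gt = GroundTruth(
        true_amplitudes=amps,
        true_rise_interval=config.rise_interval,
        true_decay_tau=config.decay_tau,
        true_bleach_tau=config.bleach_tau,
        noise_sd=config.noise_sd,
        trial_onsets=onsets_in_trial,
    )
    return tm, trials, gt


def _place_ellipses(config: SimImagingConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping elliptical ROIs by rejection sampling; labels from 1."""
    h, w = config.field_of_view
    label = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    placed = []
    max_tries = 2000
    for gid in range(1, config.n_glomeruli + 1):
        for _ in range(max_tries):
            a = rng.uniform(3.0, 6.0)  # semi-axes in pixels
            b = rng.uniform(3.0, 6.0)
            cx = rng.uniform(a + 1, w - a - 1)
            cy = rng.uniform(b + 1, h - b - 1)
            # pad centre spacing so ellipses cannot touch
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 > (max(a, b) + max(pa, pb) + 1) ** 2
                for px, py, pa, pb in placed
            ):
                mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
                label[mask] = gid
                placed.append((cx, cy, a, b))
                break
        else:
            raise RuntimeError(
                f"could not place {config.n_glomeruli} non-overlapping glomeruli "
                f"in a {h}x{w} field of view"
            )
    return label


def generate_movie(config: SimImagingConfig):
    """Full synthetic recording: movie stack, ROI labels, trials, ground truth.

    Glomeruli are drawn as non-overlapping ellipses over a dim background;
    each glomerulus pixel follows the shared bleach-modulated transient
    model with independent pixel noise.
    """
    rng = np.random.default_rng(config.seed)
    amps = _draw_tuning(config, rng)
    trials, onsets_in_trial = _build_trials(config, rng)
    label = _place_ellipses(config, rng)

    n_frames = config.frames_per_trial * config.n_trials
    t = np.arange(n_frames) / config.frame_rate
    bleach = (
        np.exp(-t / config.bleach_tau)
        if np.isfinite(config.bleach_tau)
        else np.ones_like(t)
    )

    # per-glomerulus fractional signal over the whole timeline
    signal = np.ones((config.n_glomeruli, n_frames))
    for k in range(config.n_trials):
        odor = int(trials.loc[k, "odor_id"])
        if odor < 0:
            continue
        onset_abs = k * config.trial_duration + onsets_in_trial[k]
        for g in range(config.n_glomeruli):
            a = amps[g, odor]
            if a > 0:
                signal[g] += transient_waveform(
                    t, onset_abs, a, config.rise_interval, config.decay_tau
                )

    h, w = config.field_of_view
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    base = np.full((h, w), config.background_level, dtype=float)
    frames[:] = (base * bleach[:, None, None]).astype(np.float32)
    for g in range(config.n_glomeruli):
        mask = label == (g + 1)
        frames[:, mask] = (
            config.baseline_level * bleach[:, None] * signal[g][:, None]
        ).astype(np.float32)
    if config.noise_sd > 0:
        # pixel noise scaled so ROI-averaged dF/F noise has sd ~ noise_sd
        frames += rng.normal(
            0.0, config.noise_sd * config.baseline_level, size=frames.shape
        ).astype(np.float32)
        np.clip(frames, 0.0, None, out=frames)

    movie = FluorescenceMovie(frames=frames, frame_rate=config.frame_rate,
                              modality="multiphoton" if config.frame_rate <= 4
                              else "epifluorescence")
    rois = RoiSet(label_image=label)
    gt = GroundTruth(
        roi_label_image=label,
        true_amplitudes=amps,
        true_rise_interval=config.rise_interval,
        true_decay_tau=config.decay_tau,
        true_bleach_tau=config.bleach_tau,
        baseline_level=config.baseline_level,
        noise_sd=config.noise_sd,
        trial_onsets=onsets_in_trial,
    )
    return movie, rois, trials, gt


def generate_respiration(
    rate: float,
    jitter_cv: float = 0.1,
    duration: float = 300.0,
    fs: float = 1000.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    inhale_fraction: float = 0.35,
):
    """Quasi-periodic breathing trace with known breath (peak) times.

    Each inter-breath interval is 1/f with f drawn from a normal
    distribution of mean ``rate`` and coefficient of variation ``jitter_cv``
    (truncated at 20% of the mean), so the ground-truth mean instantaneous
    frequency is unbiased by construction. The waveform between consecutive
    inhalation peaks is an asymmetric raised cosine — a slow fall over the
    first ``1 - inhale_fraction`` of the cycle, then a faster rise back to
    the next peak — resembling a smooth thermocouple signal.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if fs < 120:
        raise ValueError("fs must be at least 120 Hz (2 x 60 Hz filter band)")
    if duration < 2.0 / rate:
        raise ValueError("duration must cover at least 2 breaths")
    rng = np.random.default_rng(seed)

    # per-cycle instantaneous frequencies -> peak-to-peak intervals
    n_guess = int(duration * rate * 2) + 10
    freqs = rng.normal(rate, jitter_cv * rate, size=n_guess)
    freqs = np.clip(freqs, 0.2 * rate, None)
    intervals = 1.0 / freqs
    first_peak = inhale_fraction / rate
    peaks = first_peak + np.concatenate([[0.0], np.cumsum(intervals)])
    peaks = peaks[peaks < duration]

    t = np.arange(int(round(duration * fs))) / fs
    signal = np.zeros_like(t)
    # leading rise from rest to the first peak (zero slope at the peak)
    lead = t < peaks[0]
    signal[lead] = 0.5 * (1.0 - np.cos(np.pi * t[lead] / peaks[0]))
    fall = 1.0 - inhale_fraction  # fraction of the cycle spent falling
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        seg = (t >= p0) & (t < p1)
        phi = (t[seg] - p0) / (p1 - p0)  # cycle phase in [0, 1)
        g = np.where(
            phi < fall,
            0.5 * phi / fall,
            0.5 + 0.5 * (phi - fall) / inhale_fraction,
        )
        signal[seg] = 0.5 * (1.0 + np.cos(2 * np.pi * g))
    # trailing fall after the last peak, using one more drawn interval
    iv_last = intervals[peaks.size - 1] if peaks.size <= intervals.size else 1.0 / rate
    tail = t >= peaks[-1]
    phi = np.minimum((t[tail] - peaks[-1]) / (iv_last * fall), 1.0)
    signal[tail] = 0.5 * (1.0 + np.cos(np.pi * phi))
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)

    trace = RespirationTrace(samples=signal, fs=fs, source="thermocouple")
    gt = GroundTruth(breath_times=peaks, breath_rate=rate)
    return trace, gt


def generate_trajectory(
    arena: ArenaGeometry,
    pre_duration: float = 600.0,
    approach_delay: float = 5.0,
    speed: float = 8.0,
    tortuosity: float = 0.5,
    frame_rate: float = 8.0,
    seed: int = 0,
    start: tuple[float, float] | None = None,
    post_duration: float = 120.0,
):
    """Explore-then-approach arena trajectory.

    The animal performs a persistent random walk (heading diffusion scaled
    by ``tortuosity``) for ``pre_duration`` seconds of baseline plus
    ``approach_delay`` seconds after odor onset, then walks toward the
    active inlet with heading noise of the same scale. ``tortuosity = 0``
    gives a perfectly straight approach. Positions are confined to the
    arena by reflecting headings at the wall.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    onset = pre_duration
    n_steps = int(round((pre_duration + post_duration) * frame_rate))
    times = np.arange(n_steps + 1) * dt

    cx, cy = arena.center
    r_max = arena.radius - 0.5  # keep the body off the wall
    target = arena.active_inlet_position()
    if start is None:
        ang = rng.uniform(0, 2 * np.pi)
        rad = arena.radius * 0.6 * np.sqrt(rng.uniform())
        pos = np.array([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
    else:
        pos = np.asarray(start, dtype=float)
    heading = rng.uniform(0, 2 * np.pi)

    positions = np.empty((n_steps + 1, 2))
    positions[0] = pos
    arrived_at = None
    for i in range(1, n_steps + 1):
        t_now = times[i - 1]
        approaching = t_now >= onset + approach_delay
        if approaching:
            to_target = target - pos
            dist = np.hypot(*to_target)
            if arrived_at is None and dist <= arena.arrival_radius * 0.5:
                arrived_at = t_now
            if arrived_at is not None:
                positions[i] = pos  # stays at the source once reached
                continue
            heading = math.atan2(to_target[1], to_target[0])
            if tortuosity > 0:
                heading += rng.normal(0.0, tortuosity * 0.5)
        else:
            heading += rng.normal(0.0, tortuosity) if tortuosity > 0 else 0.0
        step = speed * dt * np.array([math.cos(heading), math.sin(heading)])
        new = pos + step
        # reflect off the wall back toward the interior
        d_c = np.hypot(new[0] - cx, new[1] - cy)
        if d_c > r_max and not approaching:
            heading = math.atan2(cy - new[1], cx - new[0]) + rng.uniform(-0.5, 0.5)
            new = pos + speed * dt * np.array([math.cos(heading), math.sin(heading)])
            d_c = np.hypot(new[0] - cx, new[1] - cy)
        if d_c > arena.radius:
            new = np.array([cx, cy]) + (new - [cx, cy]) * (arena.radius / d_c)
        pos = new
        positions[i] = pos

    traj = Trajectory(times=times, positions=positions)
    gt = GroundTruth(
        approach_onset=onset + approach_delay,
        source_position=target,
        speed=speed,
        start_position=positions[int(round(onset * frame_rate))].copy(),
    )
    return traj, gt


def render_arena_video(
    traj: Trajectory,
    arena: ArenaGeometry,
    pixel_scale: float = 0.5,
    blob_radius: float = 1.5,
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """Synthetic tracking video: a bright Gaussian blob on a dark background.

    ``pixel_scale`` is cm per pixel; returns a float32 stack scaled to [0, 1]
    plus noise, one frame per trajectory sample.
    """
    rng = np.random.default_rng(seed)
    npix = int(math.ceil(arena.diameter / pixel_scale)) + 1
    yy, xx = np.mgrid[0:npix, 0:npix]
    frames = np.empty((traj.times.size, npix, npix), dtype=np.float32)
    sigma_px = blob_radius / pixel_scale
    for i, (x, y) in enumerate(traj.positions):
        px, py = x / pixel_scale, y / pixel_scale
        blob = np.exp(-(((xx - px) ** 2 + (yy - py) ** 2) / (2 * sigma_px**2)))
        frames[i] = blob
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape).astype(np.float32)
    return frames
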