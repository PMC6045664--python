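"""Shared containers for glomerular imaging, respiration and behavior data.

Conventions used throughout the package:

* time origin t = 0 at recording start; all times in seconds
* frames are 0-based; a time ``t`` maps to frame ``floor(t * frame_rate)``
* analysis windows are half-open ``[start, stop)``
* trial tables are :class:`pandas.DataFrame` objects with the columns
  ``trial, odor_id, concentration, onset, offset, is_blank, repeat_index``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "trial",
    "odor_id",
    "concentration",
    "onset",
    "offset",
    "is_blank",
    "repeat_index",
]


@dataclass
class FluorescenceMovie:
    """Raw imaging record: a time x height x width intensity stack."""

    frames: np.ndarray  # (t, h, w), arbitrary intensity units
    frame_rate: float  # Hz
    modality: str = "epifluorescence"  # or "multiphoton"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be a 3-D stack with >= 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class RoiSet:
    """Glomerular regions of interest as an integer label image (0 = background)."""

    label_image: np.ndarray
    roi_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if not self.roi_ids:
            ids = np.unique(self.label_image)
            self.roi_ids = [int(i) for i in ids if i > 0]
        for rid in self.roi_ids:
            if rid <= 0:
                raise ValueError("roi ids must be positive integers")
            if not np.any(self.label_image == rid):
                raise ValueError(f"ROI {rid} has no pixels")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)


@dataclass
class TraceMatrix:
    """Per-ROI, per-trial dF/F time series.

    ``dff`` has shape (n_rois, n_trials, n_frames_per_trial); each trial's
    time axis restarts at 0 with the odor onset at ``onset_in_trial`` seconds.
    """

    dff: np.ndarray
    frame_rate: float
    onset_in_trial: float  # s from trial start to odor onset
    baseline_window: tuple[float, float]  # s, precedes the onset
    f_baseline: Optional[np.ndarray] = None  # (n_rois, n_trials) raw baseline F

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 3:
            raise ValueError("dff must be (roi, trial, time)")
        if self.baseline_window[1] > self.onset_in_trial + 1e-9:
            raise ValueError("baseline window must precede odor onset")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff must be finite")

    @property
    def n_rois(self) -> int:
        return self.dff.shape[0]

    @property
    def n_trials(self) -> int:
        return self.dff.shape[1]


@dataclass
class ResponseTable:
    """Glomerulus x odor response amplitudes (mean dF/F over the odor window).

    ``amplitude[i, j]`` is the repeat-averaged response of glomerulus i to
    odor j; ``replicate_amplitudes[i][j]`` holds the per-repeat values and
    ``blank_amplitudes[i]`` the per-blank-trial values for glomerulus i.
    """

    amplitude: np.ndarray  # (n_glomeruli, n_odors)
    odor_ids: list
    replicate_amplitudes: list[list[np.ndarray]]
    blank_amplitudes: np.ndarray  # (n_glomeruli, n_blanks)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim != 2:
            raise ValueError("amplitude must be glomerulus x odor")
        if self.amplitude.shape[1] != len(self.odor_ids):
            raise ValueError("odor_ids length must match amplitude columns")

    @property
    def n_glomeruli(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_odors(self) -> int:
        return self.amplitude.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.amplitude,
            index=pd.RangeIndex(self.n_glomeruli, name="glomerulus"),
            columns=pd.Index(self.odor_ids, name="odor_id"),
        )


@dataclass
class RespirationTrace:
    """Digitized breathing signal (thermocouple or intranasal pressure)."""

    samples: np.ndarray  # volts
    fs: float = 1000.0  # Hz
    source: str = "thermocouple"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size < 2 * self.fs:
            raise ValueError("need at least 2 s of data")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class BreathEvents:
    """Detected breath times and the instantaneous frequency series."""

    breath_times: np.ndarray  # s, strictly increasing
    window: float = 300.0  # s analysis span
    status: str = "ok"

    def __post_init__(self) -> None:
        self.breath_times = np.asarray(self.breath_times, dtype=float)
        if self.breath_times.size > 1 and np.any(np.diff(self.breath_times) <= 0):
            raise ValueError("breath_times must be strictly increasing")

    @property
    def inst_freq(self) -> np.ndarray:
        """Instantaneous frequency, 1 / inter-breath interval (Hz)."""
        if self.breath_times.size < 2:
            return np.empty(0)
        return 1.0 / np.diff(self.breath_times)

    @property
    def n_breaths(self) -> int:
        return int(self.breath_times.size)


@dataclass
class ArenaGeometry:
    """Circular open-field arena with odor inlets on its circumference."""

    diameter: float = 56.0  # cm
    center: tuple[float, float] = (28.0, 28.0)  # cm
    n_inlets: int = 4
    active_inlet: int = 0
    arrival_radius: float = 1.0  # cm
    odor_onset: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.arrival_radius <= 0:
            raise ValueError("arrival_radius must be positive")
        if not 0 <= self.active_inlet < self.n_inlets:
            raise ValueError("active_inlet out of range")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def inlet_positions(self) -> np.ndarray:
        """Inlets equally spaced on the circle, inlet 0 at angle 0."""
        ang = 2 * np.pi * np.arange(self.n_inlets) / self.n_inlets
        cx, cy = self.center
        return np.column_stack([cx + self.radius * np.cos(ang),
                                cy + self.radius * np.sin(ang)])

    def active_inlet_position(self) -> np.ndarray:
        return self.inlet_positions()[self.active_inlet]


@dataclass
class Trajectory:
    """Timestamped arena positions in cm."""

    times: np.ndarray  # s
    positions: np.ndarray  # (n, 2) cm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 2):
            raise ValueError("positions must be (n, 2) matching times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x": self.positions[:, 0], "y": self.positions[:, 1]}
        )


@dataclass
class GroundTruth:
    """Generative parameters recorded by the synthetic-data module.

    Only the fields relevant to the generator that produced it are set.
    """

    roi_label_image: Optional[np.ndarray] = None
    true_amplitudes: Optional[np.ndarray] = None  # glomerulus x odor dF/F
    true_rise_interval: Optional[float] = None  # s, designed onset-to-peak
    true_decay_tau: Optional[float] = None  # s
    true_bleach_tau: Optional[float] = None  # s
    baseline_level: Optional[float] = None
    noise_sd: Optional[float] = None
    trial_onsets: Optional[np.ndarray] = None  # s, per trial (within trial)
    breath_times: Optional[np.ndarray] = None  # s
    breath_rate: Optional[float] = None  # Hz
    approach_onset: Optional[float] = None  # s
    source_position: Optional[np.ndarray] = None  # cm
    speed: Optional[float] = None  # cm/s
    start_position: Optional[np.ndarray] = None  # cm


def make_trial_table(records: list[dict]) -> pd.DataFrame:
    """Build and validate a trial table from per-trial records."""
    df = pd.DataFrame(records, columns=TRIAL_COLUMNS)
    validate_trial_table(df)
    return df


def validate_trial_table(df: pd.DataFrame) -> None:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if np.any(df["offset"].to_numpy() <= df["onset"].to_numpy()):
        raise ValueError("every trial needs offset > onset")
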