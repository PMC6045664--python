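"""Reading and writing the package's on-disk formats.

Movies and ROI label images are multi-page / single-page TIFF (via
tifffile); trial tables, traces, trajectories and results are CSV with the
column conventions documented in :mod:`glomkit.datatypes`; configs are
YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import (
    FluorescenceMovie,
    RespirationTrace,
    RoiSet,
    TraceMatrix,
    Trajectory,
    validate_trial_table,
)


def write_movie(path: str | Path, movie: FluorescenceMovie) -> None:
    tifffile.imwrite(
        str(path), movie.frames,
        metadata={"frame_rate": movie.frame_rate, "modality": movie.modality},
    )


def read_movie(
    path: str | Path, frame_rate: float, modality: str = "epifluorescence"
) -> FluorescenceMovie:
    frames = tifffile.imread(str(path))
    return FluorescenceMovie(frames=frames, frame_rate=frame_rate,
                             modality=modality)


def write_rois(path: str | Path, rois: RoiSet) -> None:
    tifffile.imwrite(str(path), rois.label_image.astype(np.int32))


def read_rois(path: str | Path) -> RoiSet:
    return RoiSet(label_image=tifffile.imread(str(path)))


def write_trials(path: str | Path, trials: pd.DataFrame) -> None:
    validate_trial_table(trials)
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_trial_table(df)
    return df


def write_traces(path: str | Path, traces: TraceMatrix) -> None:
    """Long-format CSV: roi, trial, frame, dff (+ header metadata comment)."""
    n_r, n_t, n_f = traces.dff.shape
    idx = pd.MultiIndex.from_product(
        [range(n_r), range(n_t), range(n_f)], names=["roi", "trial", "frame"]
    )
    df = pd.DataFrame({"dff": traces.dff.ravel()}, index=idx).reset_index()
    with open(path, "w") as fh:
        fh.write(
            f"# frame_rate={traces.frame_rate} onset_in_trial={traces.onset_in_trial} "
            f"baseline={traces.baseline_window[0]},{traces.baseline_window[1]}\n"
        )
        df.to_csv(fh, index=False)


def read_traces(path: str | Path) -> TraceMatrix:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    n_r = df["roi"].max() + 1
    n_t = df["trial"].max() + 1
    n_f = df["frame"].max() + 1
    b0, b1 = (float(v) for v in meta["baseline"].split(","))
    return TraceMatrix(
        dff=df["dff"].to_numpy().reshape(n_r, n_t, n_f),
        frame_rate=float(meta["frame_rate"]),
        onset_in_trial=float(meta["onset_in_trial"]),
        baseline_window=(b0, b1),
    )


def write_respiration(path: str | Path, trace: RespirationTrace) -> None:
    pd.DataFrame({"t": trace.times(), "v": trace.samples}).to_csv(path, index=False)


def read_respiration(path: str | Path, source: str = "thermocouple") -> RespirationTrace:
    df = pd.read_csv(path)
    dt = np.diff(df["t"].to_numpy())
    fs = 1.0 / float(np.median(dt))
    return RespirationTrace(samples=df["v"].to_numpy(), fs=fs, source=source)


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(times=df["t"].to_numpy(),
                      positions=df[["x", "y"]].to_numpy())


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def dump_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
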