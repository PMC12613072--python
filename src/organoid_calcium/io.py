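"""File formats: TIFF/HDF5 movies, CSV/HDF5 traces, CSV events and records.

Movies are multi-page TIFF (written as 16-bit unsigned with rounding, read
back as float) or HDF5 datasets (float64, lossless); traces are wide CSV
tables (frame, time_s, roi_0, roi_1, ...) or HDF5; ROI seeds are CSV
(roi_id, seed_row, seed_col) and ROI masks 16-bit label images (0 =
background, label = roi_id + 1). All pixel coordinates are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .types import CaEvent, CellActivityRecord, Movie, OrganoidSummary, ROI

__all__ = [
    "write_movie_tiff", "read_movie_tiff",
    "write_movie_h5", "read_movie_h5", "read_movie",
    "write_traces_csv", "read_traces_csv",
    "write_traces_h5", "read_traces_h5",
    "read_roi_seeds_csv", "write_roi_seeds_csv",
    "write_roi_mask_tiff", "read_roi_mask_tiff",
    "write_events_csv", "read_events_csv",
    "write_records_csv", "write_summary_csv",
    "write_shifts_csv", "read_shifts_csv",
    "write_params_json",
]


# -- movies -----------------------------------------------------------------

def write_movie_tiff(path, movie: Movie) -> None:
    """Write as multi-page 16-bit TIFF; intensities rounded and clipped."""
    data = np.clip(np.round(movie.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16),
                     metadata={"frame_rate_hz": movie.frame_rate})


def read_movie_tiff(path, frame_rate: float = None) -> Movie:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray().astype(float)
        if frame_rate is None:
            meta = tif.shaped_metadata or ({},)
            frame_rate = float(meta[0].get("frame_rate_hz", 30.0))
    if frames.ndim == 2:
        frames = frames[None]
    return Movie(frames=frames, frame_rate=frame_rate)


def write_movie_h5(path, movie: Movie, dataset: str = "movie") -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(dataset, data=movie.frames)
        ds.attrs["frame_rate_hz"] = movie.frame_rate


def read_movie_h5(path, dataset: str = "movie") -> Movie:
    with h5py.File(path, "r") as fh:
        ds = fh[dataset]
        return Movie(frames=ds[...].astype(float),
                     frame_rate=float(ds.attrs.get("frame_rate_hz", 30.0)))


def read_movie(path, frame_rate: float = None) -> Movie:
    """Dispatch on extension (.tif/.tiff or .h5/.hdf5)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return read_movie_tiff(path, frame_rate)
    if suffix in (".h5", ".hdf5"):
        movie = read_movie_h5(path)
        if frame_rate is not None:
            movie.frame_rate = frame_rate
        return movie
    raise ValueError(f"unrecognised movie format: {path}")


# -- traces -----------------------------------------------------------------

def _traces_frame(matrix: np.ndarray, frame_rate: float,
                  roi_ids: Sequence[int]) -> pd.DataFrame:
    matrix = np.atleast_2d(matrix)
    df = pd.DataFrame(matrix.T, columns=[f"roi_{i}" for i in roi_ids])
    df.insert(0, "frame", np.arange(matrix.shape[1]))
    df.insert(1, "time_s", np.arange(matrix.shape[1]) / frame_rate)
    return df


def write_traces_csv(path, matrix: np.ndarray, frame_rate: float,
                     roi_ids: Sequence[int] = None) -> None:
    matrix = np.atleast_2d(matrix)
    if roi_ids is None:
        roi_ids = range(matrix.shape[0])
    _traces_frame(matrix, frame_rate, roi_ids).to_csv(path, index=False)


def read_traces_csv(path) -> tuple:
    """Returns ``(matrix (n_rois, n_frames), frame_rate, roi_ids)``."""
    df = pd.read_csv(path)
    roi_cols = [c for c in df.columns if c.startswith("roi_")]
    if not roi_cols:
        raise ValueError(f"no roi_* columns in {path}")
    t = df["time_s"].to_numpy()
    frame_rate = 1.0 / (t[1] - t[0]) if t.size > 1 else 30.0
    ids = [int(c.split("_", 1)[1]) for c in roi_cols]
    return df[roi_cols].to_numpy().T, float(frame_rate), ids


def write_traces_h5(path, channels: dict, frame_rate: float,
                    roi_ids: Sequence[int] = None) -> None:
    """Write named channel matrices (raw/smoothed/f0/dff) to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.attrs["frame_rate_hz"] = frame_rate
        for name, matrix in channels.items():
            fh.create_dataset(name, data=np.atleast_2d(matrix))
        if roi_ids is not None:
            fh.create_dataset("roi_ids", data=np.asarray(roi_ids, dtype=int))


def read_traces_h5(path) -> tuple:
    """Returns ``(channels dict, frame_rate, roi_ids)``."""
    with h5py.File(path, "r") as fh:
        frame_rate = float(fh.attrs.get("frame_rate_hz", 30.0))
        roi_ids = fh["roi_ids"][...].tolist() if "roi_ids" in fh else None
        channels = {k: fh[k][...] for k in fh.keys() if k != "roi_ids"}
    if roi_ids is None and channels:
        n = next(iter(channels.values())).shape[0]
        roi_ids = list(range(n))
    return channels, frame_rate, roi_ids


# -- ROIs -------------------------------------------------------------------

def read_roi_seeds_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"roi_id", "seed_row", "seed_col"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"ROI seed CSV needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return df


def write_roi_seeds_csv(path, rois: Sequence[ROI]) -> None:
    rows = [{"roi_id": r.id,
             "seed_row": r.seed[0] if r.seed else r.pixels[:, 0].mean(),
             "seed_col": r.seed[1] if r.seed else r.pixels[:, 1].mean()}
            for r in rois]
    pd.DataFrame(rows, columns=["roi_id", "seed_row", "seed_col"]).to_csv(
        path, index=False)


def write_roi_mask_tiff(path, rois: Sequence[ROI], shape) -> None:
    """16-bit label image: background 0, ROI ``i`` painted as ``i + 1``."""
    mask = np.zeros(shape, dtype=np.uint16)
    for roi in rois:
        mask[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.id + 1
    tifffile.imwrite(path, mask)


def read_roi_mask_tiff(path) -> List[ROI]:
    mask = tifffile.imread(path)
    rois = []
    for label in np.unique(mask):
        if label == 0:
            continue
        rois.append(ROI(id=int(label) - 1, pixels=np.argwhere(mask == label)))
    return rois


# -- events, records, summaries --------------------------------------------

EVENT_COLUMNS = ["roi_id", "peak_frame", "peak_time_s", "height_dff",
                 "width_frames", "prominence"]


def write_events_csv(path, events: Sequence[CaEvent]) -> None:
    rows = [{"roi_id": e.roi_id, "peak_frame": e.peak_frame,
             "peak_time_s": e.peak_time, "height_dff": e.height,
             "width_frames": e.width, "prominence": e.prominence}
            for e in events]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path) -> List[CaEvent]:
    df = pd.read_csv(path)
    return [CaEvent(roi_id=int(r.roi_id), peak_frame=int(r.peak_frame),
                    peak_time=float(r.peak_time_s), height=float(r.height_dff),
                    width=float(r.width_frames), prominence=float(r.prominence))
            for r in df.itertuples()]


def write_records_csv(path, records: Sequence[CellActivityRecord]) -> None:
    rows = [{"roi_id": r.roi_id, "skewness": r.skewness, "sd_dff": r.sd,
             "n_events": r.n_events, "active": r.active,
             "freq_per_min": r.frequency, "mean_amp": r.mean_amplitude}
            for r in records]
    pd.DataFrame(rows, columns=["roi_id", "skewness", "sd_dff", "n_events",
                                "active", "freq_per_min", "mean_amp"]
                 ).to_csv(path, index=False)


def write_summary_csv(path, summaries: Sequence[OrganoidSummary]) -> None:
    rows = [{"organoid_id": s.organoid_id, "group": s.group,
             "n_rois": s.n_rois, "n_active": s.n_active,
             "active_cell_rate_pct": s.active_cell_rate,
             "mean_freq_per_min": float(np.mean(s.frequencies))
             if s.frequencies.size else np.nan,
             "mean_amplitude_dff": float(np.mean(s.amplitudes))
             if s.amplitudes.size else np.nan}
            for s in summaries]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_shifts_csv(path, shifts) -> None:
    arr = shifts.shifts if hasattr(shifts, "shifts") else np.asarray(shifts)
    df = pd.DataFrame({"frame": np.arange(arr.shape[0]),
                       "dy": arr[:, 0], "dx": arr[:, 1]})
    df.to_csv(path, index=False)


def read_shifts_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["dy", "dx"]].to_numpy()


def write_params_json(path, params: dict) -> None:
    """Provenance sidecar: every parameter the run used."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
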