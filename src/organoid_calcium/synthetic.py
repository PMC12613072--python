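"""Synthetic two-photon recordings with exact ground truth.

The generator emulates the statistical structure of GCaMP population
recordings from cortical organoids: a slowly drifting baseline, sparse
calcium transients shaped like slow synchronized network events, additive
Gaussian noise, and (for movies) disk-shaped cells on a dark background
with rigid frame-to-frame motion. Every random element is recorded in a
:class:`GroundTruth` object so downstream stages can be validated without
real recordings.

Model for one cell's raw fluorescence::

    F(t) = B(t) * (1 + sum_i a_i * k(t - t_i)) + eps(t)
    B(t) = baseline_level * (1 + drift_amplitude * sin(2*pi*t/P + phi))

where ``k`` is a peak-normalised difference-of-exponentials kernel
``(1 - exp(-t/rise_tau)) * exp(-t/decay_tau)``, so the programmed event
amplitude ``a_i`` is the true dF/F0 peak height regardless of drift
(transients scale with the local baseline, as fluorescence does), and
``eps`` is i.i.d. Gaussian noise. Event times of active cells follow a
homogeneous Poisson process; inactive cells have exactly zero events.

Default kinetics (rise 1.5 s, decay 6 s) describe the slow network-wide
events that dominate organoid population activity rather than isolated
single-cell fast-indicator transients; see the methods note for why the
analysis chain presupposes events on this time scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Movie, ROI, Trace

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "transient_kernel",
    "generate_trace",
    "generate_traces",
    "generate_movie",
    "make_cohort",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recording generator.

    Times are seconds, rates events/min, fluorescence arbitrary units.
    ``amplitude_mean``/``amplitude_sd`` are in dF/F0 units (programmed true
    peak heights). ``drift_period`` defaults to the recording duration.
    """

    n_frames: int = 3600  # 120 s at 30 Hz
    frame_rate: float = 30.0
    height: int = 64
    width: int = 64
    n_cells: int = 8
    active_fraction: float = 0.5
    event_rate_active: float = 2.0  # events/min
    amplitude_mean: float = 0.6
    amplitude_sd: float = 0.1
    amplitude_min: float = 0.1
    rise_tau: float = 1.5
    decay_tau: float = 6.0
    baseline_level: float = 100.0
    drift_amplitude: float = 0.05
    drift_period: Optional[float] = None
    noise_sd: float = 2.0
    motion_max_shift: int = 0
    roi_radius: int = 4
    background_level: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if not self.baseline_level > 0:
            raise ValueError(
                "baseline_level must be > 0 (dF/F0 is undefined otherwise)"
            )
        if self.noise_sd < 0 or self.amplitude_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not self.rise_tau < self.decay_tau:
            raise ValueError("rise_tau must be smaller than decay_tau")
        if self.motion_max_shift < 0:
            raise ValueError("motion_max_shift must be >= 0")

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def n_active(self) -> int:
        """floor(n_cells * active_fraction), but at least 1 if fraction > 0."""
        if self.active_fraction == 0.0:
            return 0
        return max(1, int(np.floor(self.n_cells * self.active_fraction)))


@dataclass
class GroundTruth:
    """Everything the generator randomised, for use as a test oracle."""

    labels: np.ndarray  # bool, (n_cells,): True = active
    event_times: List[np.ndarray]  # seconds, one array per cell
    event_amplitudes: List[np.ndarray]  # dF/F0 units, matching event_times
    shifts: Optional[np.ndarray] = None  # (n_frames, 2) int, (dy, dx)
    rois: Optional[List[ROI]] = None
    centers: Optional[np.ndarray] = None  # (n_cells, 2) int
    clean_traces: Optional[np.ndarray] = None  # (n_cells, n_frames)

    def cell(self, i: int) -> "GroundTruth":
        """The single-cell slice of the truth."""
        return GroundTruth(
            labels=self.labels[i:i + 1],
            event_times=[self.event_times[i]],
            event_amplitudes=[self.event_amplitudes[i]],
        )

    @property
    def n_cells(self) -> int:
        return self.labels.size


def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Peak-normalised difference-of-exponentials calcium transient.

    ``k(t) = (1 - exp(-t/rise)) * exp(-t/decay) / k_peak`` for t >= 0, zero
    before onset; the analytic peak sits at ``rise * log(1 + decay/rise)``,
    so an event of programmed amplitude ``a`` contributes a true dF/F0 peak
    of exactly ``a``.
    """
    t = np.asarray(t, dtype=float)
    tp = np.maximum(t, 0.0)
    k = (1.0 - np.exp(-tp / rise_tau)) * np.exp(-tp / decay_tau)
    t_peak = rise_tau * np.log(1.0 + decay_tau / rise_tau)
    k_peak = (1.0 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)
    return np.where(t >= 0, k / k_peak, 0.0)


def _sample_cell_events(cfg: SynthConfig, rng: np.random.Generator, active: bool):
    if not active:
        return np.empty(0), np.empty(0)
    n_ev = rng.poisson(cfg.event_rate_active * cfg.duration / 60.0)
    times = np.sort(rng.uniform(0.0, cfg.duration, n_ev))
    amps = np.clip(
        rng.normal(cfg.amplitude_mean, cfg.amplitude_sd, n_ev),
        cfg.amplitude_min, None,
    )
    return times, amps


def _sample_truth(cfg: SynthConfig, rng: np.random.Generator) -> GroundTruth:
    labels = np.zeros(cfg.n_cells, dtype=bool)
    labels[: cfg.n_active] = True
    times, amps = [], []
    for i in range(cfg.n_cells):
        t_i, a_i = _sample_cell_events(cfg, rng, labels[i])
        times.append(t_i)
        amps.append(a_i)
    return GroundTruth(labels=labels, event_times=times, event_amplitudes=amps)


def _clean_signal(cfg: SynthConfig, times: np.ndarray, amps: np.ndarray,
                  phase: float) -> np.ndarray:
    t = np.arange(cfg.n_frames) / cfg.frame_rate
    period = cfg.drift_period if cfg.drift_period else cfg.duration
    drift = cfg.drift_amplitude * np.sin(2.0 * np.pi * t / period + phase)
    sig = np.zeros(cfg.n_frames)
    for ti, ai in zip(times, amps):
        sig += ai * transient_kernel(t - ti, cfg.rise_tau, cfg.decay_tau)
    return cfg.baseline_level * (1.0 + drift) * (1.0 + sig)


def generate_trace(
    cfg: SynthConfig,
    truth: Optional[GroundTruth] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Generate one cell's raw fluorescence trace.

    If ``truth`` (a single-cell slice) is given, its event schedule is used;
    otherwise events are drawn from a homogeneous Poisson process at
    ``event_rate_active`` (the cell is treated as active if
    ``active_fraction > 0``).

    Returns ``(trace, truth_slice)``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if truth is None:
        active = cfg.active_fraction > 0
        times, amps = _sample_cell_events(cfg, rng, active)
        truth = GroundTruth(
            labels=np.array([active]),
            event_times=[times],
            event_amplitudes=[amps],
        )
    phase = rng.uniform(0.0, 2.0 * np.pi) if cfg.drift_amplitude > 0 else 0.0
    clean = _clean_signal(cfg, truth.event_times[0], truth.event_amplitudes[0],
                          phase)
    raw = clean + rng.normal(0.0, cfg.noise_sd, cfg.n_frames) \
        if cfg.noise_sd > 0 else clean.copy()
    truth.clean_traces = clean[None, :]
    return Trace(raw=raw, frame_rate=cfg.frame_rate), truth


def generate_traces(
    cfg: SynthConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Generate an ``(n_cells, n_frames)`` raw-trace matrix plus truth.

    The trace-level counterpart of :func:`generate_movie` for studies where
    the spatial/ROI stages are not under test (cohort simulations).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    truth = _sample_truth(cfg, rng)
    raw = np.empty((cfg.n_cells, cfg.n_frames))
    clean = np.empty_like(raw)
    for i in range(cfg.n_cells):
        phase = rng.uniform(0.0, 2.0 * np.pi) if cfg.drift_amplitude > 0 else 0.0
        clean[i] = _clean_signal(cfg, truth.event_times[i],
                                 truth.event_amplitudes[i], phase)
        raw[i] = clean[i]
        if cfg.noise_sd > 0:
            raw[i] += rng.normal(0.0, cfg.noise_sd, cfg.n_frames)
    truth.clean_traces = clean
    return raw, truth


def _place_cells(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping disk centers, kept clear of borders and motion range."""
    margin = cfg.roi_radius + cfg.motion_max_shift + 1
    lo_r, hi_r = margin, cfg.height - margin
    lo_c, hi_c = margin, cfg.width - margin
    min_sep = 2 * cfg.roi_radius + 2  # disjoint with a 1-px gap
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError(
            f"frame {cfg.height}x{cfg.width} too small for ROI radius "
            f"{cfg.roi_radius} with motion_max_shift {cfg.motion_max_shift}"
        )
    centers: list = []
    attempts = 0
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > 10000:
            raise ValueError(
                f"cannot place {cfg.n_cells} non-overlapping ROIs of radius "
                f"{cfg.roi_radius} in a {cfg.height}x{cfg.width} frame"
            )
        r = rng.integers(lo_r, hi_r)
        c = rng.integers(lo_c, hi_c)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep ** 2
               for rr, cc in centers):
            centers.append((r, c))
    return np.array(centers, dtype=int)


def _disk_pixels(center, radius: int, shape) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    return np.argwhere(mask)


def _shift_frame_int(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Translate by integer (dy, dx) with constant fill (no wrap-around)."""
    out = np.full_like(frame, fill)
    h, w = frame.shape
    src_r = slice(max(0, -dy), min(h, h - dy))
    dst_r = slice(max(0, dy), min(h, h + dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out


def generate_movie(
    cfg: SynthConfig, rng: Optional[np.random.Generator] = None
) -> tuple:
    """Generate a movie of disk-shaped cells plus full ground truth.

    Cells are uniform disks whose pixel intensity follows the cell's clean
    trace; the background is a dark constant. Each frame is rigidly shifted
    by an integer (dy, dx) drawn uniformly in ``[-motion_max_shift,
    motion_max_shift]`` (frame 0 is the unshifted anchor), then i.i.d.
    Gaussian pixel noise is added.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    truth = _sample_truth(cfg, rng)
    centers = _place_cells(cfg, rng)
    shape = (cfg.height, cfg.width)
    rois = [ROI(id=i, pixels=_disk_pixels(centers[i], cfg.roi_radius, shape),
                seed=tuple(centers[i]))
            for i in range(cfg.n_cells)]

    clean = np.empty((cfg.n_cells, cfg.n_frames))
    for i in range(cfg.n_cells):
        phase = rng.uniform(0.0, 2.0 * np.pi) if cfg.drift_amplitude > 0 else 0.0
        clean[i] = _clean_signal(cfg, truth.event_times[i],
                                 truth.event_amplitudes[i], phase)

    shifts = np.zeros((cfg.n_frames, 2), dtype=int)
    if cfg.motion_max_shift > 0 and cfg.n_frames > 1:
        shifts[1:] = rng.integers(-cfg.motion_max_shift,
                                  cfg.motion_max_shift + 1,
                                  size=(cfg.n_frames - 1, 2))

    base = np.full(shape, cfg.background_level)
    frames = np.empty((cfg.n_frames,) + shape)
    for t in range(cfg.n_frames):
        frame = base.copy()
        for i, roi in enumerate(rois):
            frame[roi.pixels[:, 0], roi.pixels[:, 1]] = clean[i, t]
        dy, dx = shifts[t]
        if dy or dx:
            frame = _shift_frame_int(frame, dy, dx, cfg.background_level)
        frames[t] = frame
    if cfg.noise_sd > 0:
        frames += rng.normal(0.0, cfg.noise_sd, frames.shape)

    truth.shifts = shifts
    truth.rois = rois
    truth.centers = centers
    truth.clean_traces = clean
    return Movie(frames=frames, frame_rate=cfg.frame_rate), truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _truth_to_json(truth: GroundTruth) -> dict:
    out = {
        "labels": truth.labels.astype(int).tolist(),
        "event_times_s": [t.tolist() for t in truth.event_times],
        "event_amplitudes": [a.tolist() for a in truth.event_amplitudes],
    }
    if truth.shifts is not None:
        out["shifts"] = truth.shifts.tolist()
    if truth.centers is not None:
        out["centers"] = truth.centers.tolist()
    return out


def sample_cohort_configs(
    base: SynthConfig,
    n_organoids: int,
    mean_active_fraction: float,
    fraction_sd: float = 0.02,
    seed: int = 0,
) -> List[SynthConfig]:
    """Per-organoid configs for one experimental group.

    Each organoid's active fraction is drawn from a normal distribution
    around the group mean (truncated to [0, 1]), emulating the large
    organoid-to-organoid variability of real cohorts; seeds are derived
    from ``seed`` so a cohort is reproducible as a whole.
    """
    rng = np.random.default_rng(seed)
    fractions = np.clip(
        rng.normal(mean_active_fraction, fraction_sd, n_organoids), 0.0, 1.0
    )
    return [
        SynthConfig(**{**base.__dict__, "active_fraction": float(f),
                       "seed": int(rng.integers(2 ** 31))})
        for f in fractions
    ]


def make_cohort(
    configs: Sequence[SynthConfig],
    out_dir,
    organoid_ids: Optional[Sequence[str]] = None,
    groups: Optional[Sequence[str]] = None,
    mode: str = "traces",
) -> pd.DataFrame:
    """Write one simulated organoid per config plus a manifest table.

    ``mode="traces"`` writes per-organoid raw-trace CSVs (frames x cells);
    ``mode="movies"`` writes multi-page TIFF movies. Ground truth goes to a
    JSON sidecar per organoid. Returns the manifest
    (organoid_id, group, path, truth_path), also written as
    ``manifest.csv``.
    """
    from . import io as _io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if organoid_ids is None:
        organoid_ids = [f"org{i:03d}" for i in range(len(configs))]
    if groups is None:
        groups = ["default"] * len(configs)
    if len(set(organoid_ids)) != len(organoid_ids):
        dupes = sorted({x for x in organoid_ids if list(organoid_ids).count(x) > 1})
        raise ValueError(f"duplicate organoid ids: {dupes}")
    if not (len(configs) == len(organoid_ids) == len(groups)):
        raise ValueError("configs, organoid_ids and groups must align")

    rows = []
    for cfg, oid, grp in zip(configs, organoid_ids, groups):
        truth_path = out_dir / f"{oid}_truth.json"
        if mode == "traces":
            path = out_dir / f"{oid}_traces.csv"
            raw, truth = generate_traces(cfg)
            df = pd.DataFrame(
                raw.T, columns=[f"roi_{i}" for i in range(cfg.n_cells)]
            )
            df.insert(0, "frame", np.arange(cfg.n_frames))
            df.insert(1, "time_s", np.arange(cfg.n_frames) / cfg.frame_rate)
            df.to_csv(path, index=False, float_format="%.6f")
        elif mode == "movies":
            path = out_dir / f"{oid}_movie.tif"
            movie, truth = generate_movie(cfg)
            _io.write_movie_tiff(path, movie)
        else:
            raise ValueError(f"unknown cohort mode {mode!r}")
        with open(truth_path, "w") as fh:
            json.dump(_truth_to_json(truth), fh)
        rows.append({"organoid_id": oid, "group": grp,
                     "path": str(path), "truth_path": str(truth_path)})
    manifest = pd.DataFrame(rows, columns=["organoid_id", "group", "path",
                                           "truth_path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
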