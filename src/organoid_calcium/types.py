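"""Core data containers shared across the pipeline.

Conventions: pixel coordinates are 0-based ``(row, col)``; frame indices are
0-based; times are seconds; fluorescence is in arbitrary units; dF/F0 is
dimensionless. A rigid shift ``(dy, dx)`` means the frame content moved
*down* by ``dy`` rows and *right* by ``dx`` columns relative to the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Movie",
    "Trace",
    "ROI",
    "RigidShift",
    "CaEvent",
    "CellActivityRecord",
    "OrganoidSummary",
]


@dataclass
class Movie:
    """An ordered stack of 2-D grayscale frames with a frame rate.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Pixel intensities in arbitrary fluorescence units.
    frame_rate : float
        Acquisition rate in Hz; must be positive.
    """

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a 3-D (n_frames, height, width) array, "
                f"got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("a movie needs at least one frame")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.frame_rate


@dataclass
class Trace:
    """One ROI's fluorescence time series and its derived channels.

    ``raw`` is the mean ROI intensity per frame; ``smoothed``, ``f0`` and
    ``dff`` are filled in by the trace-processing stage.
    """

    raw: np.ndarray
    frame_rate: float
    roi_id: int = 0
    smoothed: Optional[np.ndarray] = None
    f0: Optional[np.ndarray] = None
    dff: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 1:
            raise ValueError("raw must be 1-D")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        for name in ("smoothed", "f0", "dff"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.shape != self.raw.shape:
                    raise ValueError(f"channel {name!r} length differs from raw")
                setattr(self, name, ch)

    @property
    def n_frames(self) -> int:
        return self.raw.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def with_channels(self, **channels: np.ndarray) -> "Trace":
        """Return a copy with the given derived channels attached."""
        return replace(self, **channels)


@dataclass
class ROI:
    """A cell's pixel set: 0-based (row, col) coordinates, row-major."""

    id: int
    pixels: np.ndarray  # shape (n_pixels, 2), int
    seed: Optional[tuple] = None

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if self.pixels.size == 0:
            raise ValueError("ROI pixel set must be non-empty")
        if self.pixels.shape[1] != 2:
            raise ValueError("pixels must have shape (n, 2)")

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def as_set(self) -> set:
        return {tuple(p) for p in self.pixels}


@dataclass
class RigidShift:
    """Per-frame rigid displacements estimated against a reference image.

    ``shifts[t] = (dy, dx)`` is the translation of frame ``t`` relative to
    the reference; ``flags[t]`` is True where estimation was degenerate
    (e.g. a zero-variance frame) and the shift defaulted to (0, 0).
    """

    shifts: np.ndarray  # shape (n_frames, 2), float
    flags: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.shifts = np.atleast_2d(np.asarray(self.shifts, dtype=float))
        if self.shifts.shape[1] != 2:
            raise ValueError("shifts must have shape (n_frames, 2)")
        if self.flags is None:
            self.flags = np.zeros(self.shifts.shape[0], dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape[0] != self.shifts.shape[0]:
                raise ValueError("flags length must match shifts")

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]


@dataclass(frozen=True)
class CaEvent:
    """One detected Ca2+ transient on a dF/F0 trace."""

    roi_id: int
    peak_frame: int
    peak_time: float  # seconds
    height: float  # dF/F0 at the peak
    width: float  # frames, at half prominence (or half height, see config)
    prominence: float  # dF/F0 units


@dataclass(frozen=True)
class CellActivityRecord:
    """Per-ROI activity statistics and the active/inactive verdict.

    ``frequency`` (events/min) is defined whenever the recording duration is
    known; ``mean_amplitude`` only when at least one event was detected
    (``None`` otherwise — never silently zero).
    """

    roi_id: int
    skewness: float
    sd: float
    n_events: int
    active: bool
    frequency: Optional[float] = None
    mean_amplitude: Optional[float] = None


@dataclass
class OrganoidSummary:
    """Per-recording roll-up of cell activity records."""

    organoid_id: str
    group: str
    n_rois: int
    n_active: int
    active_cell_rate: float  # percent of ROIs
    frequencies: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.n_active > self.n_rois:
            raise ValueError("n_active cannot exceed n_rois")
        if not 0.0 <= self.active_cell_rate <= 100.0:
            raise ValueError("active_cell_rate must be in [0, 100]")
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
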