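"""Ca2+ event detection on dF/F0 traces.

Events are defined with the semantics of the classic MATLAB ``findpeaks``
criteria, treated here as a compatibility contract:

* ``min_height`` — absolute dF/F0 threshold on the value at the peak;
* ``min_width`` — minimum peak width in frames, measured by default at half
  prominence (the reference implementation's default); half height is
  available via ``width_reference="half_height"``;
* ``min_distance`` — peaks closer than this many frames to a taller
  retained peak are discarded (taller-first greedy suppression; for equal
  heights the earlier peak wins). Retained peaks are therefore pairwise
  separated by at least ``min_distance`` frames.

For a flat-topped (plateau) local maximum the peak position is the middle
sample of the plateau, rounded down.

Candidate maxima, prominences and widths are computed with
:mod:`scipy.signal`; the three criteria and the suppression rule are applied
on top, in the order: enumerate candidates -> height filter -> width filter
-> distance suppression.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks as _scipy_find_peaks
from scipy.signal import peak_prominences, peak_widths
from sklearn.base import BaseEstimator

from .types import CaEvent, Trace

__all__ = [
    "EventDetector",
    "find_events",
    "event_rate",
    "mean_amplitude",
]

DEFAULT_MIN_HEIGHT = 0.2  # dF/F0
DEFAULT_MIN_DISTANCE = 30  # frames (1 s at 30 Hz)
DEFAULT_MIN_WIDTH = 15  # frames (0.5 s at 30 Hz)


def _suppress(peaks: np.ndarray, heights: np.ndarray, min_distance: int) -> np.ndarray:
    """Taller-first greedy suppression; ties broken toward the earlier peak.

    A peak is discarded when a taller (or equal, earlier) retained peak lies
    strictly closer than ``min_distance`` frames, so retained peaks end up
    pairwise separated by >= ``min_distance``.
    """
    order = np.lexsort((peaks, -heights))  # height desc, then position asc
    keep = np.ones(peaks.size, dtype=bool)
    for idx in order:
        if not keep[idx]:
            continue
        close = np.abs(peaks - peaks[idx]) < min_distance
        close[idx] = False
        keep[close] = False
        keep[idx] = True
    return keep


class EventDetector(BaseEstimator):
    """Detect Ca2+ transients on dF/F0 traces.

    Parameters
    ----------
    min_height : float, default 0.2
        Minimum dF/F0 at the peak (absolute threshold).
    min_distance : int, default 30
        Minimum separation between retained peaks, frames.
    min_width : int, default 15
        Minimum peak width, frames.
    width_reference : {"half_prominence", "half_height"}
        Level at which width is measured.
    frame_rate : float, default 30.0
        Used to convert peak frames to seconds.
    """

    def __init__(
        self,
        min_height: float = DEFAULT_MIN_HEIGHT,
        min_distance: int = DEFAULT_MIN_DISTANCE,
        min_width: int = DEFAULT_MIN_WIDTH,
        width_reference: str = "half_prominence",
        frame_rate: float = 30.0,
    ):
        self.min_height = min_height
        self.min_distance = min_distance
        self.min_width = min_width
        self.width_reference = width_reference
        self.frame_rate = frame_rate

    def _validate_params(self) -> None:
        if not self.min_height > 0:
            raise ValueError("min_height must be > 0")
        if self.min_distance < 1 or self.min_width < 1:
            raise ValueError("min_distance and min_width must be >= 1")
        if self.width_reference not in ("half_prominence", "half_height"):
            raise ValueError(
                f"unknown width_reference {self.width_reference!r}"
            )
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")

    def detect(self, dff: np.ndarray, roi_id: int = 0) -> List[CaEvent]:
        """Return the detected events of one dF/F0 trace, sorted by frame."""
        self._validate_params()
        dff = np.asarray(dff, dtype=float)
        if dff.ndim != 1:
            raise ValueError("dff must be a 1-D trace")
        if dff.size < 3:
            return []
        cand, _ = _scipy_find_peaks(dff)  # all strict/plateau local maxima
        if cand.size == 0:
            return []
        heights = dff[cand]
        prom = peak_prominences(dff, cand)
        if self.width_reference == "half_prominence":
            widths = peak_widths(dff, cand, rel_height=0.5,
                                 prominence_data=prom)[0]
        else:
            # width where the trace crosses half the *peak height*:
            # rel_height such that peak - rel*prominence == height/2
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(prom[0] > 0, (heights / 2.0) / prom[0], 0.0)
            widths = np.array([
                peak_widths(dff, cand[i:i + 1], rel_height=min(rel[i], 1.0),
                            prominence_data=tuple(a[i:i + 1] for a in prom))[0][0]
                for i in range(cand.size)
            ])
        ok = (heights >= self.min_height) & (widths >= self.min_width)
        cand, heights, widths = cand[ok], heights[ok], widths[ok]
        proms = prom[0][ok]
        keep = _suppress(cand, heights, self.min_distance)
        events = [
            CaEvent(
                roi_id=roi_id,
                peak_frame=int(p),
                peak_time=float(p / self.frame_rate),
                height=float(h),
                width=float(w),
                prominence=float(pr),
            )
            for p, h, w, pr in zip(
                cand[keep], heights[keep], widths[keep], proms[keep]
            )
        ]
        return events

    def detect_trace(self, trace: Trace) -> List[CaEvent]:
        if trace.dff is None:
            raise ValueError(
                "trace has no dff channel; run TraceProcessor first"
            )
        det = self
        if trace.frame_rate != self.frame_rate:
            det = EventDetector(**{**self.get_params(),
                                   "frame_rate": trace.frame_rate})
        return det.detect(trace.dff, roi_id=trace.roi_id)

    def detect_all(self, dff_matrix: np.ndarray,
                   roi_ids: Optional[Sequence[int]] = None) -> List[List[CaEvent]]:
        """Detect events for every row of an (n_traces, n_frames) array."""
        dff_matrix = np.atleast_2d(np.asarray(dff_matrix, dtype=float))
        if roi_ids is None:
            roi_ids = range(dff_matrix.shape[0])
        return [self.detect(row, roi_id=rid)
                for row, rid in zip(dff_matrix, roi_ids)]


def find_events(trace: Trace, **params) -> List[CaEvent]:
    """Detect Ca2+ events on a processed trace (dff channel required)."""
    det = EventDetector(**{"frame_rate": trace.frame_rate, **params})
    return det.detect_trace(trace)


def event_rate(events: Sequence[CaEvent], duration: float) -> float:
    """Events per minute over a recording of ``duration`` seconds."""
    if not duration > 0:
        raise ValueError(f"duration must be > 0 s, got {duration}")
    return len(events) / (duration / 60.0)


def mean_amplitude(events: Sequence[CaEvent]) -> float:
    """Mean peak height (dF/F0) over detected events.

    Undefined for an empty event list: raises rather than returning zero.
    """
    if len(events) == 0:
        raise ValueError("mean amplitude is undefined without events")
    return float(np.mean([e.height for e in events]))
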