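"""ROI definition and per-ROI trace extraction.

Cell ROIs are defined by seeded region growing: starting from a seed pixel,
the connected set of pixels whose intensity lies within a relative
tolerance of the seed neighbourhood's mean is grown, clipped to a maximum
radius. This is an automated surrogate for interactive cell-outlining
tools; seeds come from a CSV or, in validation studies, from the synthetic
generator's ground truth.

The trace of an ROI is the mean intensity over its pixels at each frame
(mean rather than sum, so traces are invariant to ROI size and comparable
across cells). Pixel coordinates are 0-based (row, col).
"""

from __future__ import annotations

from typing import List, Sequence, Union

import numpy as np
from scipy import ndimage

from .types import Movie, ROI, Trace

__all__ = [
    "grow_roi",
    "extract_trace",
    "extract_traces",
    "check_disjoint",
]

BACKGROUND_FLOOR = 1e-9  # absolute intensity below which a seed is rejected


def grow_roi(
    frame: np.ndarray,
    seed: tuple,
    max_radius: int = 8,
    min_radius: int = 1,
    tolerance: float = 0.3,
    roi_id: int = 0,
    background_floor: float = None,
) -> ROI:
    """Grow a connected ROI around ``seed`` on a single image.

    Pixels within ``tolerance * m`` of the seed neighbourhood's mean ``m``
    (the 3x3 block around the seed) are candidates; the ROI is the candidate
    connected component containing the seed, intersected with a disk of
    ``max_radius`` around it. Deterministic.

    Raises if the seed sits on background: neighbourhood mean below
    ``background_floor`` (default: half the image median).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    r, c = int(seed[0]), int(seed[1])
    h, w = frame.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"seed {seed} outside the {h}x{w} frame")
    if max_radius < min_radius or min_radius < 1:
        raise ValueError("need max_radius >= min_radius >= 1")

    neigh = frame[max(0, r - 1): r + 2, max(0, c - 1): c + 2]
    ref = float(neigh.mean())
    if background_floor is None:
        # background if the neighbourhood is no brighter than typical
        # pixels: a quarter of the way from the median to the bright tail
        med = float(np.median(frame))
        bright = float(np.percentile(frame, 99.5))
        background_floor = max(BACKGROUND_FLOOR, med + 0.25 * (bright - med))
    if ref < background_floor:
        raise ValueError(
            f"seed {seed} lies on background (neighbourhood mean {ref:.3g} "
            f"< floor {background_floor:.3g}); no ROI can be grown"
        )

    candidate = np.abs(frame - ref) <= tolerance * abs(ref)
    rr, cc = np.ogrid[:h, :w]
    candidate &= (rr - r) ** 2 + (cc - c) ** 2 <= max_radius ** 2
    labels, _ = ndimage.label(candidate)
    lab = labels[r, c]
    if lab == 0:  # seed itself outside tolerance of its neighbourhood mean
        pixels = np.array([[r, c]])
    else:
        pixels = np.argwhere(labels == lab)
    return ROI(id=roi_id, pixels=pixels, seed=(r, c))


def check_disjoint(rois: Sequence[ROI]) -> None:
    """Raise if any two ROIs of one recording share a pixel."""
    seen: dict = {}
    for roi in rois:
        for p in map(tuple, roi.pixels):
            if p in seen:
                raise ValueError(
                    f"ROIs {seen[p]} and {roi.id} overlap at pixel {p}"
                )
            seen[p] = roi.id


def extract_trace(movie: Union[Movie, np.ndarray], roi: ROI) -> Trace:
    """Mean intensity over the ROI's pixels at every frame."""
    frames = movie.frames if isinstance(movie, Movie) else np.asarray(movie)
    frame_rate = movie.frame_rate if isinstance(movie, Movie) else 1.0
    if frames.ndim != 3:
        raise ValueError("expected a (n_frames, height, width) stack")
    if roi.n_pixels == 0:
        raise ValueError("cannot extract a trace from an empty ROI")
    rr, cc = roi.pixels[:, 0], roi.pixels[:, 1]
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= frames.shape[1] \
            or cc.max() >= frames.shape[2]:
        raise ValueError(f"ROI {roi.id} has pixels outside the frame")
    raw = frames[:, rr, cc].mean(axis=1)
    return Trace(raw=raw, frame_rate=frame_rate, roi_id=roi.id)


def extract_traces(movie: Union[Movie, np.ndarray],
                   rois: Sequence[ROI]) -> List[Trace]:
    """Extract one trace per ROI, enforcing pairwise disjointness."""
    check_disjoint(rois)
    return [extract_trace(movie, roi) for roi in rois]
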