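"""Rigid motion correction by cross-correlation.

Each frame's translation relative to a reference image is estimated as the
argmax of the FFT-based cross-correlation of the mean-subtracted images,
searched within ``+/- max_shift`` pixels. The estimate is integer-pixel by
default; a parabolic sub-pixel refinement is available behind a flag.
Frames are corrected by translating them by the negated shift; pixels moved
in from outside the field are filled with a constant 0 (wrap-around would
leak content across the field and corrupt ROI traces).

The default reference is the mean image over all frames, which is stabler
than any single frame; ``"first"`` or an explicit frame index can be used
instead.
"""

from __future__ import annotations

import warnings
from typing import Union

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .types import Movie, RigidShift

__all__ = ["MotionCorrector", "estimate_shifts", "apply_shifts"]

FILL_VALUE = 0.0


def _as_frames(movie: Union[Movie, np.ndarray]) -> np.ndarray:
    frames = movie.frames if isinstance(movie, Movie) else np.asarray(movie)
    if frames.ndim != 3:
        raise ValueError("expected a (n_frames, height, width) stack")
    return frames.astype(float, copy=False)


def _reference_image(frames: np.ndarray, reference) -> np.ndarray:
    if isinstance(reference, str):
        if reference == "mean":
            return frames.mean(axis=0)
        if reference == "first":
            return frames[0]
        raise ValueError(f"unknown reference {reference!r}")
    idx = int(reference)
    if not 0 <= idx < frames.shape[0]:
        raise ValueError(f"reference index {idx} out of range")
    return frames[idx]


def _parabolic_offset(cm: float, cc: float, cp: float) -> float:
    """Sub-pixel offset of a parabola through three correlation samples."""
    denom = cm - 2.0 * cc + cp
    if denom == 0:
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -0.5, 0.5))


def _xcorr_shift(frame: np.ndarray, ref_fft_conj: np.ndarray, shape,
                 max_shift: int, subpixel: bool) -> tuple:
    """(dy, dx) maximising the circular cross-correlation with the reference.

    Positive (dy, dx) means the frame content is displaced down/right
    relative to the reference.
    """
    f = frame - frame.mean()
    corr = np.fft.irfft2(np.fft.rfft2(f) * ref_fft_conj, s=shape)
    corr = np.fft.fftshift(corr)
    cy, cx = shape[0] // 2, shape[1] // 2
    win = corr[cy - max_shift: cy + max_shift + 1,
               cx - max_shift: cx + max_shift + 1]
    iy, ix = np.unravel_index(np.argmax(win), win.shape)
    dy = iy - max_shift
    dx = ix - max_shift
    if subpixel:
        gy = cy + dy
        gx = cx + dx
        if 0 < gy < shape[0] - 1:
            dy = dy + _parabolic_offset(corr[gy - 1, gx], corr[gy, gx],
                                        corr[gy + 1, gx])
        if 0 < gx < shape[1] - 1:
            dx = dx + _parabolic_offset(corr[gy, gx - 1], corr[gy, gx],
                                        corr[gy, gx + 1])
    return float(dy), float(dx)


class MotionCorrector(BaseEstimator):
    """Estimate and undo per-frame rigid displacements.

    ``fit`` estimates the shifts (stored as ``shifts_``); ``transform``
    applies their negation to realign the frames. Zero-variance frames
    cannot be registered; they get shift (0, 0) and a True entry in
    ``degenerate_flags_``, with a warning.

    Parameters
    ----------
    reference : {"mean", "first"} or int, default "mean"
        Image the frames are aligned to.
    max_shift : int, default 20
        Search radius in pixels; must be smaller than half the frame size.
    subpixel : bool, default False
        Parabolic refinement of the correlation peak.
    """

    def __init__(self, reference="mean", max_shift: int = 20,
                 subpixel: bool = False):
        self.reference = reference
        self.max_shift = max_shift
        self.subpixel = subpixel

    def fit(self, X, y=None):
        frames = _as_frames(X)
        n, h, w = frames.shape
        if self.max_shift < 1:
            raise ValueError("max_shift must be >= 1")
        if self.max_shift >= min(h, w) // 2:
            raise ValueError(
                f"max_shift {self.max_shift} must be below half the frame "
                f"size ({h}x{w})"
            )
        ref = _reference_image(frames, self.reference)
        ref0 = ref - ref.mean()
        if not ref0.any():
            raise ValueError("reference image has zero variance")
        ref_fft_conj = np.conj(np.fft.rfft2(ref0))
        shifts = np.zeros((n, 2))
        flags = np.zeros(n, dtype=bool)
        for t in range(n):
            if np.ptp(frames[t]) == 0:
                flags[t] = True  # featureless frame: leave at (0, 0)
                continue
            shifts[t] = _xcorr_shift(frames[t], ref_fft_conj, (h, w),
                                     self.max_shift, self.subpixel)
        if flags.any():
            warnings.warn(
                f"{int(flags.sum())} zero-variance frame(s) could not be "
                f"registered; their shift defaults to (0, 0)",
                stacklevel=2,
            )
        self.shifts_ = RigidShift(shifts=shifts, flags=flags)
        self.reference_image_ = ref
        return self

    def transform(self, X) -> Union[Movie, np.ndarray]:
        if not hasattr(self, "shifts_"):
            raise RuntimeError("fit must be called before transform")
        return apply_shifts(X, self.shifts_)

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def estimate_shifts(movie: Union[Movie, np.ndarray], reference="mean",
                    max_shift: int = 20, subpixel: bool = False) -> RigidShift:
    """Per-frame (dy, dx) of each frame relative to the reference image."""
    frames = _as_frames(movie)
    if frames.shape[0] < 2:
        raise ValueError("shift estimation needs at least 2 frames")
    mc = MotionCorrector(reference=reference, max_shift=max_shift,
                         subpixel=subpixel)
    return mc.fit(frames).shifts_


def apply_shifts(movie: Union[Movie, np.ndarray],
                 shifts: Union[RigidShift, np.ndarray]) -> Union[Movie, np.ndarray]:
    """Translate every frame by the negated shift (out-of-field fill = 0).

    Integer shifts are applied exactly; fractional shifts use bilinear
    interpolation. Returns the same type as the input.
    """
    frames = _as_frames(movie)
    arr = shifts.shifts if isinstance(shifts, RigidShift) else \
        np.atleast_2d(np.asarray(shifts, dtype=float))
    if arr.shape[0] != frames.shape[0]:
        raise ValueError(
            f"{arr.shape[0]} shifts for {frames.shape[0]} frames"
        )
    out = np.empty_like(frames)
    for t, (dy, dx) in enumerate(arr):
        if dy == 0 and dx == 0:
            out[t] = frames[t]
        elif float(dy).is_integer() and float(dx).is_integer():
            out[t] = _translate_int(frames[t], -int(dy), -int(dx))
        else:
            out[t] = ndimage.shift(frames[t], (-dy, -dx), order=1,
                                   mode="constant", cval=FILL_VALUE)
    if isinstance(movie, Movie):
        return Movie(frames=out, frame_rate=movie.frame_rate)
    return out


def _translate_int(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.full_like(frame, FILL_VALUE)
    h, w = frame.shape
    src_r = slice(max(0, -dy), min(h, h - dy))
    dst_r = slice(max(0, dy), min(h, h + dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out
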