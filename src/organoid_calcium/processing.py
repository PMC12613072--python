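"""Trace smoothing, percentile-filter baseline (F0), and dF/F0.

The processing chain follows common practice for slow population calcium
signals: (1) Savitzky-Golay smoothing to suppress high-frequency electrical
noise, (2) a running low-percentile baseline F0 that tracks slow drift while
ignoring transients, and (3) dF/F0 = (F - F0) / F0 computed on the smoothed
trace.

The baseline "low-pass percentile filter" with percentile p and cutoff
frequency f_c is realised as a centered sliding-window percentile whose
window spans ``round(frame_rate / f_c)`` frames (1/f_c seconds); windows are
truncated at the trace edges, never padded. With the defaults (p = 10,
f_c = 1/15 Hz, 30 Hz acquisition) the window is 450 frames. An alternative
reading — percentile filter followed by a zero-phase Butterworth low-pass at
f_c — is available via ``baseline_mode="percentile+butterworth"``.

Percentiles use the standard linear-interpolation definition, identical to
:func:`numpy.percentile`; the sorted-window implementation is JIT-compiled
when numba is available and falls back to a vectorised numpy path otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, filtfilt, savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .types import Trace

__all__ = [
    "TraceProcessor",
    "smooth",
    "baseline_f0",
    "compute_dff",
    "process_trace",
    "rolling_percentile",
]

DEFAULT_SG_WIDTH = 301
DEFAULT_SG_POLYORDER = 3
DEFAULT_BASELINE_PERCENTILE = 10.0
DEFAULT_BASELINE_CUTOFF = 1.0 / 15.0  # Hz


# ---------------------------------------------------------------------------
# rolling percentile
# ---------------------------------------------------------------------------

def _percentile_window_extents(window: int) -> tuple:
    """Left/right half-extents of a centered window of ``window`` frames.

    For even windows the extra sample goes to the right:
    window = left + right + 1 with left = (window-1)//2, right = window//2.
    """
    return (window - 1) // 2, window // 2


def _rolling_percentile_numpy(x: np.ndarray, window: int, q: float) -> np.ndarray:
    n = x.size
    left, right = _percentile_window_extents(window)
    out = np.empty(n, dtype=float)
    if n >= window:
        out[left:n - right] = np.percentile(
            sliding_window_view(x, window), q, axis=-1
        )
        head = range(left)
        tail = range(n - right, n)
    else:
        head = range(min(left, n))
        tail = range(min(left, n), n)
    for i in head:
        out[i] = np.percentile(x[: i + right + 1], q)
    for i in tail:
        out[i] = np.percentile(x[max(0, i - left): min(n, i + right + 1)], q)
    return out


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _sorted_insert(buf, m, val):
        lo, hi = 0, m
        while lo < hi:
            mid = (lo + hi) // 2
            if buf[mid] < val:
                lo = mid + 1
            else:
                hi = mid
        for j in range(m, lo, -1):
            buf[j] = buf[j - 1]
        buf[lo] = val
        return m + 1

    @njit(cache=True)
    def _sorted_remove(buf, m, val):
        lo, hi = 0, m
        while lo < hi:
            mid = (lo + hi) // 2
            if buf[mid] < val:
                lo = mid + 1
            else:
                hi = mid
        for j in range(lo, m - 1):
            buf[j] = buf[j + 1]
        return m - 1

    @njit(cache=True)
    def _pct_from_sorted(buf, m, q):
        # numpy 'linear' interpolation, including its t >= 0.5 lerp branch
        v = q / 100.0 * (m - 1)
        lo = int(np.floor(v))
        if lo >= m - 1:
            return buf[m - 1]
        t = v - lo
        a = buf[lo]
        b = buf[lo + 1]
        if t < 0.5:
            return a + (b - a) * t
        return b - (b - a) * (1.0 - t)

    @njit(cache=True)
    def _rolling_percentile_jit(x, window, q):
        n = x.size
        left = (window - 1) // 2
        right = window // 2
        out = np.empty(n, dtype=np.float64)
        buf = np.empty(window, dtype=np.float64)
        m = 0
        stop = right if right < n - 1 else n - 1
        for j in range(stop + 1):
            m = _sorted_insert(buf, m, x[j])
        out[0] = _pct_from_sorted(buf, m, q)
        for i in range(1, n):
            enter = i + right
            if enter < n:
                m = _sorted_insert(buf, m, x[enter])
            leave = i - left - 1
            if leave >= 0:
                m = _sorted_remove(buf, m, x[leave])
            out[i] = _pct_from_sorted(buf, m, q)
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def rolling_percentile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Centered sliding-window percentile with edge truncation.

    Equivalent to ``np.percentile(x[max(0, i-(window-1)//2) :
    i+window//2+1], q)`` evaluated at every index ``i``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 < q < 100:
        raise ValueError("percentile must be strictly between 0 and 100")
    if _HAVE_NUMBA:
        return _rolling_percentile_jit(x, window, q)
    return _rolling_percentile_numpy(x, window, q)


# ---------------------------------------------------------------------------
# channel computations
# ---------------------------------------------------------------------------

def _effective_sg_width(width: int, polyorder: int, n: int) -> int:
    """Auto-shrink the SG window to the largest valid odd length <= n."""
    if width % 2 == 0:
        raise ValueError(f"sg_width must be odd, got {width}")
    if width <= n:
        return width
    shrunk = n if n % 2 == 1 else n - 1
    if shrunk < polyorder + 2:
        raise ValueError(
            f"trace of {n} frames is too short for a Savitzky-Golay fit "
            f"of order {polyorder}"
        )
    warnings.warn(
        f"Savitzky-Golay window shrunk from {width} to {shrunk} frames to "
        f"fit a {n}-frame trace",
        stacklevel=2,
    )
    return shrunk


def smooth(
    x: np.ndarray,
    sg_width: int = DEFAULT_SG_WIDTH,
    sg_polyorder: int = DEFAULT_SG_POLYORDER,
) -> np.ndarray:
    """Savitzky-Golay smoothing along the last axis.

    Edges are handled by fitting a polynomial of the same order to the first
    and last window (no reflection padding), so polynomial signals up to
    ``sg_polyorder`` pass through unchanged everywhere.
    """
    x = np.asarray(x, dtype=float)
    if sg_polyorder < 0:
        raise ValueError("sg_polyorder must be >= 0")
    width = _effective_sg_width(sg_width, sg_polyorder, x.shape[-1])
    if width < sg_polyorder + 2:
        raise ValueError("sg_width must be >= sg_polyorder + 2")
    return savgol_filter(x, width, sg_polyorder, axis=-1, mode="interp")


def baseline_window_frames(frame_rate: float, cutoff: float) -> int:
    """Window length (frames) of the percentile baseline: round(fs / f_c)."""
    if not cutoff > 0:
        raise ValueError("baseline cutoff must be > 0")
    if not frame_rate > 0:
        raise ValueError("frame_rate must be > 0")
    return max(1, round(frame_rate / cutoff))


def baseline_f0(
    smoothed: np.ndarray,
    frame_rate: float,
    percentile: float = DEFAULT_BASELINE_PERCENTILE,
    cutoff: float = DEFAULT_BASELINE_CUTOFF,
    mode: str = "window",
    butter_order: int = 2,
) -> np.ndarray:
    """Estimate the per-frame baseline F0 of a smoothed trace.

    mode="window" (default): sliding-window percentile over 1/cutoff
    seconds. mode="percentile+butterworth": the same percentile filter
    followed by a zero-phase Butterworth low-pass at ``cutoff`` Hz.

    Raises if any F0 sample is <= 0 (dF/F0 would be undefined); traces with
    a non-positive background offset must be corrected upstream.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    window = baseline_window_frames(frame_rate, cutoff)
    one_d = smoothed.ndim == 1
    rows = smoothed[None, :] if one_d else smoothed
    f0 = np.empty_like(rows)
    for i, row in enumerate(rows):
        f0[i] = rolling_percentile(row, window, percentile)
    if mode == "percentile+butterworth":
        nyq = frame_rate / 2.0
        if cutoff >= nyq:
            raise ValueError("cutoff must be below the Nyquist frequency")
        b, a = butter(butter_order, cutoff / nyq, btype="low")
        f0 = filtfilt(b, a, f0, axis=-1)
    elif mode != "window":
        raise ValueError(f"unknown baseline mode {mode!r}")
    if np.any(f0 <= 0):
        raise ValueError(
            "baseline F0 is non-positive for some frames; dF/F0 is undefined. "
            "Subtract the camera/background offset so fluorescence stays "
            "positive before processing."
        )
    return f0[0] if one_d else f0


def compute_dff(smoothed: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """dF/F0 = (F - F0) / F0 on the smoothed trace."""
    smoothed = np.asarray(smoothed, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if smoothed.shape != f0.shape:
        raise ValueError("smoothed and f0 must have the same shape")
    if np.any(f0 <= 0):
        raise ValueError("F0 must be strictly positive everywhere")
    return (smoothed - f0) / f0


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class TraceProcessor(BaseEstimator, TransformerMixin):
    """Transform raw ROI fluorescence traces into dF/F0.

    A stateless scikit-learn-style transformer: ``transform`` maps an
    ``(n_traces, n_frames)`` array of raw traces to dF/F0 of the same shape.
    The intermediate channels from the most recent call are retained as
    ``smoothed_`` and ``f0_`` for inspection and file output.

    Parameters
    ----------
    sg_width : int, default 301
        Savitzky-Golay window (frames); must be odd. Auto-shrinks with a
        warning for traces shorter than the window.
    sg_polyorder : int, default 3
        Savitzky-Golay polynomial order.
    baseline_percentile : float, default 10
        Percentile of the running baseline.
    baseline_cutoff : float, default 1/15
        Baseline cutoff frequency in Hz; the window percentile spans
        ``1/cutoff`` seconds.
    frame_rate : float, default 30.0
        Acquisition rate in Hz.
    baseline_mode : {"window", "percentile+butterworth"}
    """

    def __init__(
        self,
        sg_width: int = DEFAULT_SG_WIDTH,
        sg_polyorder: int = DEFAULT_SG_POLYORDER,
        baseline_percentile: float = DEFAULT_BASELINE_PERCENTILE,
        baseline_cutoff: float = DEFAULT_BASELINE_CUTOFF,
        frame_rate: float = 30.0,
        baseline_mode: str = "window",
    ):
        self.sg_width = sg_width
        self.sg_polyorder = sg_polyorder
        self.baseline_percentile = baseline_percentile
        self.baseline_cutoff = baseline_cutoff
        self.frame_rate = frame_rate
        self.baseline_mode = baseline_mode

    def _validate_params(self) -> None:
        if self.sg_width % 2 == 0 or self.sg_width < self.sg_polyorder + 2:
            raise ValueError(
                "sg_width must be odd and >= sg_polyorder + 2, "
                f"got {self.sg_width}"
            )
        if not 0 < self.baseline_percentile < 100:
            raise ValueError("baseline_percentile must be in (0, 100)")
        if not self.baseline_cutoff > 0:
            raise ValueError("baseline_cutoff must be > 0")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")

    def fit(self, X, y=None):
        self._validate_params()
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[-1]
        return self

    def transform(self, X) -> np.ndarray:
        """Return dF/F0 for each row of ``X`` (raw traces)."""
        self._validate_params()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        smoothed = smooth(X, self.sg_width, self.sg_polyorder)
        f0 = baseline_f0(
            smoothed,
            self.frame_rate,
            percentile=self.baseline_percentile,
            cutoff=self.baseline_cutoff,
            mode=self.baseline_mode,
        )
        self.smoothed_ = smoothed
        self.f0_ = f0
        return compute_dff(smoothed, f0)

    def process_trace(self, trace: Trace) -> Trace:
        """Return a copy of ``trace`` with smoothed, f0 and dff channels."""
        dff = self.transform(trace.raw[None, :])[0]
        return trace.with_channels(
            smoothed=self.smoothed_[0], f0=self.f0_[0], dff=dff
        )


def process_trace(trace: Trace, **params) -> Trace:
    """Functional one-shot: attach smoothed, f0 and dff channels."""
    proc = TraceProcessor(**{"frame_rate": trace.frame_rate, **params})
    return proc.process_trace(trace)
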