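"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive each quantity from its definition with plain
loops, independently of the library code paths they are checked against.
"""

from __future__ import annotations

import numpy as np


# -- peak detection ---------------------------------------------------------

def enumerate_local_maxima(x: np.ndarray):
    """All interior local maxima; plateau peaks sit at the middle sample
    (rounded down). Returns a list of peak indices."""
    n = len(x)
    peaks = []
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                peaks.append(i + (j - i) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def prominence_and_bases(x: np.ndarray, peak: int):
    """Topographic prominence: height above the lowest contour line that
    separates the peak from any higher terrain (or the signal border)."""
    n = len(x)
    left_min = x[peak]
    left_base = peak
    i = peak
    while i >= 0 and x[i] <= x[peak]:
        if x[i] < left_min:
            left_min = x[i]
            left_base = i
        i -= 1
    right_min = x[peak]
    right_base = peak
    i = peak
    while i < n and x[i] <= x[peak]:
        if x[i] < right_min:
            right_min = x[i]
            right_base = i
        i += 1
    return x[peak] - max(left_min, right_min), left_base, right_base


def width_at_rel_height(x: np.ndarray, peak: int, prominence: float,
                        left_base: int, right_base: int,
                        rel_height: float = 0.5):
    """Width (in samples) where the trace crosses
    ``x[peak] - rel_height * prominence``, linearly interpolated, bounded
    by the prominence bases."""
    height = x[peak] - prominence * rel_height
    i = peak
    while left_base < i and height < x[i]:
        i -= 1
    left_ip = float(i)
    if x[i] < height:
        left_ip += (height - x[i]) / (x[i + 1] - x[i])
    i = peak
    while i < right_base and height < x[i]:
        i += 1
    right_ip = float(i)
    if x[i] < height:
        right_ip -= (height - x[i]) / (x[i - 1] - x[i])
    return right_ip - left_ip


def brute_force_find_events(x: np.ndarray, min_height: float,
                            min_distance: int, min_width: int):
    """Enumerate all local maxima, apply the height and width criteria,
    then taller-first greedy distance suppression (ties: earlier peak
    wins). Returns a sorted list of (peak_index, height, width)."""
    x = np.asarray(x, dtype=float)
    candidates = []
    for p in enumerate_local_maxima(x):
        h = x[p]
        if h < min_height:
            continue
        prom, lb, rb = prominence_and_bases(x, p)
        w = width_at_rel_height(x, p, prom, lb, rb, 0.5)
        if w < min_width:
            continue
        candidates.append((p, h, w))
    # taller first; for equal heights the earlier peak
    kept = []
    for p, h, w in sorted(candidates, key=lambda c: (-c[1], c[0])):
        if all(abs(p - q) >= min_distance for q, _, _ in kept):
            kept.append((p, h, w))
    return sorted(kept)


# -- baseline ---------------------------------------------------------------

def brute_force_rolling_percentile(x: np.ndarray, window: int,
                                   q: float) -> np.ndarray:
    """Per-frame percentile over the explicit truncated centered window."""
    x = np.asarray(x, dtype=float)
    n = x.size
    left = (window - 1) // 2
    right = window // 2
    return np.array([
        np.percentile(x[max(0, i - left): min(n, i + right + 1)], q)
        for i in range(n)
    ])


# -- registration -----------------------------------------------------------

def exhaustive_shift_search(frame: np.ndarray, ref: np.ndarray,
                            max_shift: int):
    """Best integer (dy, dx) by maximising the overlap correlation of
    mean-subtracted images over all shifts within +/- max_shift."""
    f = frame - frame.mean()
    r = ref - ref.mean()
    best, best_val = (0, 0), -np.inf
    h, w = f.shape
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            fs = np.roll(np.roll(f, -dy, axis=0), -dx, axis=1)
            val = float((fs * r).sum())
            if val > best_val:
                best_val, best = val, (dy, dx)
    return best
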