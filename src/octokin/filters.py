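"""Window filter primitives used by the trajectory-cleaning chain.

All filters are centered; at sequence edges the window shrinks to the
available samples (no padding, no fabricated data).  Invalid samples are
excluded from every window; a window with no valid sample yields NaN.

Even window widths are accepted only where a caller explicitly needs them
(the moving-median outlier baseline); a width-``w`` window at index ``i``
spans ``[i - w//2, i + (w - 1 - w//2)]``.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "window_median",
    "moving_median",
    "moving_average",
    "median_window_2d",
]


def window_median(values: np.ndarray) -> float:
    """Median of a 1-D array: sort and take the middle (mean of the two
    middles for even counts)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        return np.nan
    if n % 2:
        return float(v[n // 2])
    return float((v[n // 2 - 1] + v[n // 2]) / 2.0)


def _window_bounds(i: int, n: int, window: int) -> tuple[int, int]:
    half = window // 2
    lo = max(0, i - half)
    hi = min(n - 1, i + (window - 1 - half))
    return lo, hi


def moving_median(
    values: np.ndarray, valid: np.ndarray | None = None, window: int = 5
) -> np.ndarray:
    """Centered moving median over valid neighbours."""
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.size
    if valid is None:
        valid = np.isfinite(values)
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = _window_bounds(i, n, window)
        win = values[lo : hi + 1][valid[lo : hi + 1]]
        if win.size:
            out[i] = window_median(win)
    return out


def moving_average(
    values: np.ndarray, valid: np.ndarray | None = None, window: int = 5
) -> np.ndarray:
    """Centered moving average over valid neighbours."""
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.size
    if valid is None:
        valid = np.isfinite(values)
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = _window_bounds(i, n, window)
        win = values[lo : hi + 1][valid[lo : hi + 1]]
        if win.size:
            out[i] = float(np.mean(win))
    return out


def median_window_2d(
    image: np.ndarray,
    valid: np.ndarray,
    row: int,
    col: int,
    window: int = 11,
    min_valid_fraction: float = 0.5,
) -> float:
    """Median of the valid pixels in a ``window x window`` box centred at
    (row, col).

    Pixels outside the image count as invalid.  Returns NaN when fewer than
    ``min_valid_fraction`` of the full window area is valid.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    h, w = image.shape
    half = window // 2
    r0, r1 = max(0, row - half), min(h, row + half + 1)
    c0, c1 = max(0, col - half), min(w, col + half + 1)
    if r0 >= r1 or c0 >= c1:
        return np.nan
    patch = image[r0:r1, c0:c1]
    mask = valid[r0:r1, c0:c1]
    n_valid = int(mask.sum())
    if n_valid < min_valid_fraction * window * window:
        return np.nan
    return window_median(patch[mask])
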