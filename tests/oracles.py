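"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the mathematical definitions with explicit loops
and share no code with the package's vectorised/spectral evaluation paths.
"""

from __future__ import annotations

import numpy as np


def naive_ridf(stored: np.ndarray, current: np.ndarray, col_start: int) -> np.ndarray:
    """d[s, k] = mean |stored_s - window_k(current)| by explicit looping."""
    n_mem, h, w = stored.shape
    n_az = current.shape[1]
    d = np.empty((n_mem, n_az))
    for s in range(n_mem):
        for k in range(n_az):
            total = 0.0
            for c in range(w):
                col = (col_start + c + k) % n_az
                total += float(np.abs(stored[s][:, c] - current[:, col]).sum())
            d[s, k] = total / (w * h)
    return d


def naive_recover(
    stored: np.ndarray, current: np.ndarray, col_start: int, resolution: float
) -> tuple[int, int, float]:
    """Exhaustive perfect-memory search over every (view, rotation) pair.

    Returns (best_view, best_shift, min_value) with the tie-break: smallest
    rotation magnitude first, then the earliest stored view, then the shift.
    """
    d = naive_ridf(stored, current, col_start)
    best = None
    for s in range(d.shape[0]):
        for k in range(d.shape[1]):
            theta = abs((k * resolution + 180.0) % 360.0 - 180.0)
            key = (d[s, k], theta, s, k)
            if best is None or key < best:
                best = key
    return best[2], best[3], best[0]
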