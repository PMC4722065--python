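"""Rotational image difference computation.

The rotational image difference function (rIDF) between a stored view I
(width w, height h, FOV-trimmed) and a full-360 current panorama J evaluates,
for every candidate rotation of k pixels,

    d(I, J, k) = sum_{r,c} |I[r,c] - J[r, (c0 + c + k) mod N]| / (w h)

where N is the eye's full azimuthal pixel count and c0 the column of the full
panorama where the trimmed field of view starts.  The candidate rotations are
the N integer pixel shifts of the panorama.

Two evaluation strategies produce identical values:

* a direct vectorised sweep over rotations (small problems);
* a cross-correlation path for large problems, built on the exact identity
  |a - b| = a + b - 2 min(a, b) and a split of each image into its pure-sky
  part (value 1), pure-object part (0) and sparse boundary greys:
  min(a, b) = [a==1]*b + g_a*[b==1] + min(g_a, g_b) with g the grey-masked
  values.  The two dense terms become FFT cross-correlations accumulated over
  rows; the grey/grey term touches only boundary-pixel pairs and is summed
  exactly with a compiled kernel.  Pixel values are exact lattice fractions
  (multiples of 1/supersample^2 and their block averages), so the split is
  exact and the FFT path matches the direct path to float64 round-off.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["RIDFMatcher"]

#: Above this many elementary operations (memories x rotations x pixels) the
#: cross-correlation path is used.
_DIRECT_OP_LIMIT = 4e7


@njit(cache=True)
def _grey_pair_corr(n_mem, n_rows, a_ptr, a_col, a_val, b_ptr, b_col, b_val, out, n_az):
    """Accumulate sum-of-min over grey(stored) x grey(current) pixel pairs.

    out[s, k] += sum over same-row pairs with column offset k of min(va, vb).
    """
    for s in range(n_mem):
        for r in range(n_rows):
            a0, a1 = a_ptr[s * n_rows + r], a_ptr[s * n_rows + r + 1]
            b0, b1 = b_ptr[r], b_ptr[r + 1]
            if a0 == a1 or b0 == b1:
                continue
            for ia in range(a0, a1):
                ca = a_col[ia]
                va = a_val[ia]
                for ib in range(b0, b1):
                    k = b_col[ib] - ca
                    if k < 0:
                        k += n_az
                    vb = b_val[ib]
                    out[s, k] += va if va < vb else vb


def _classify(px: np.ndarray):
    """Split pixels into sky indicator, grey values, object handled implicitly."""
    sky = px == 1.0
    grey = (px > 0.0) & ~sky
    return sky, px * grey


class RIDFMatcher:
    """Evaluates rIDFs of a fixed stack of stored views against panoramas.

    Parameters
    ----------
    stored : ndarray (n_mem, h, w)
        FOV-trimmed stored views (route memory, or one sector of it).
    az_pixels_full : int
        Pixel count N of a full panorama at the eye's resolution.
    col_start : int
        Column of the full panorama covered by stored column 0 at rotation 0.
    strategy : {"auto", "direct", "fft"}
        Evaluation path; "auto" picks by problem size.  Both give the same
        values to float64 round-off.
    """

    def __init__(self, stored, az_pixels_full, col_start, strategy="auto"):
        stored = np.ascontiguousarray(stored, dtype=float)
        if stored.ndim != 3:
            raise ValueError("stored must have shape (n_mem, h, w)")
        if not 0 < stored.shape[2] <= az_pixels_full:
            raise ValueError("stored width must lie in [1, az_pixels_full]")
        self.stored = stored
        self.n_mem, self.h, self.w = stored.shape
        self.n_az = int(az_pixels_full)
        self.col_start = int(col_start) % self.n_az
        ops = self.n_mem * self.h * self.w * self.n_az
        if strategy == "auto":
            strategy = "fft" if ops > _DIRECT_OP_LIMIT else "direct"
        if strategy not in ("direct", "fft"):
            raise ValueError(f"unknown strategy {strategy!r}")
        self.strategy = strategy
        self._sum_stored = stored.sum(axis=(1, 2))
        if strategy == "fft":
            self._prepare_fft()

    # -- fft path ----------------------------------------------------------

    def _prepare_fft(self):
        n_mem, h, w, N = self.n_mem, self.h, self.w, self.n_az
        c0 = self.col_start
        n_freq = N // 2 + 1
        # Stacked spectra of [sky indicator; grey values], zero-padded into
        # the full-panorama frame, so one contraction serves both dense terms.
        self._spec = np.empty((n_mem, 2 * h, n_freq), dtype=complex)
        cols = (c0 + np.arange(w)) % N
        a_rows, a_cols, a_vals = [], [], []
        pad = np.zeros((2 * h, N))
        for s in range(n_mem):
            sky, grey = _classify(self.stored[s])
            pad[:] = 0.0
            pad[:h, cols] = sky
            pad[h:, cols] = grey
            self._spec[s] = np.conj(np.fft.rfft(pad, axis=1))
            gr, gc = np.nonzero(grey)
            a_rows.append(gr + s * h)
            a_cols.append(cols[gc])
            a_vals.append(grey[gr, gc])
        rows = np.concatenate(a_rows)
        order = np.argsort(rows, kind="stable")
        self._grey_ptr = np.searchsorted(rows[order], np.arange(n_mem * h + 1)).astype(np.int64)
        self._grey_col = np.concatenate(a_cols)[order].astype(np.int64)
        self._grey_val = np.concatenate(a_vals)[order]

    def _ridf_fft(self, current: np.ndarray) -> np.ndarray:
        h, w, N = self.h, self.w, self.n_az
        sky, grey = _classify(current)
        # Spectra of [current values; current sky indicator]: term pairing is
        # stored-sky x current-values and stored-grey x current-sky.
        cur = np.concatenate([current, sky.astype(float)], axis=0)
        f_cur = np.fft.rfft(cur, axis=1)
        x = np.einsum("shf,hf->sf", self._spec, f_cur)
        corr = np.fft.irfft(x, n=N, axis=1)

        b_ptr = np.zeros(h + 1, dtype=np.int64)
        gr, gc = np.nonzero(grey)
        b_ptr[1:] = np.bincount(gr, minlength=h).cumsum()
        order = np.argsort(gr, kind="stable")
        _grey_pair_corr(
            self.n_mem, h,
            self._grey_ptr, self._grey_col, self._grey_val,
            b_ptr, gc[order].astype(np.int64), grey[gr, gc][order],
            corr, N,
        )

        # Window sum of the current panorama for every rotation, via cumsum.
        colsum = current.sum(axis=0)
        cum = np.concatenate([[0.0], np.cumsum(np.concatenate([colsum, colsum]))])
        k = np.arange(N)
        sum_win = cum[k + self.col_start + w] - cum[k + self.col_start]

        d = self._sum_stored[:, None] + sum_win[None, :] - 2.0 * corr
        return np.maximum(d, 0.0) / (w * h)

    # -- direct path -------------------------------------------------------

    def _ridf_direct(self, current: np.ndarray) -> np.ndarray:
        n_mem, h, w, N = self.n_mem, self.h, self.w, self.n_az
        out = np.empty((n_mem, N))
        chunk = max(1, int(4e6 // max(1, n_mem * h * w)))
        base = (self.col_start + np.arange(w)) % N
        for k0 in range(0, N, chunk):
            ks = np.arange(k0, min(k0 + chunk, N))
            idx = (base[None, :] + ks[:, None]) % N          # (chunk, w)
            win = current[:, idx]                            # (h, chunk, w)
            win = np.moveaxis(win, 1, 0)                     # (chunk, h, w)
            diff = np.abs(self.stored[:, None] - win[None])  # (n_mem, chunk, h, w)
            out[:, ks] = diff.mean(axis=(2, 3))
        return out

    # -- public ------------------------------------------------------------

    def ridf_all(self, current: np.ndarray) -> np.ndarray:
        """rIDF values, shape (n_mem, N): entry [s, k] is d(stored_s, J, k)."""
        current = np.ascontiguousarray(current, dtype=float)
        if current.shape != (self.h, self.n_az):
            raise ValueError(
                f"current panorama must have shape {(self.h, self.n_az)}, "
                f"got {current.shape}"
            )
        if self.strategy == "fft":
            return self._ridf_fft(current)
        return self._ridf_direct(current)
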