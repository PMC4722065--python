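"""Heading recovery from stored route views.

The navigating agent carries an ordered memory of views stored while walking
a training route, each captured facing along the local route direction.  At a
test location it rotates its current panorama through every candidate
orientation and, for every stored view I and rotation theta, evaluates the
rotational image difference d(I, J, theta) (mean absolute pixel difference).
Per stored view the rIDF minimum is

    m(I, J) = min_theta d(I, J, theta)
    h(I, J) = argmin_theta d(I, J, theta)

and the agent adopts the heading h(I, J) of the stored view with the lowest
minimum ("perfect memory": every stored view is searched, the globally best
match wins).

Signal strength is a match-confidence heuristic: the familiarity in the most
familiar direction (the lowest per-direction rIDF value over the whole
memory) compared with the median familiarity across all tested directions.
We report median/min by default so that larger values mean a stronger,
more reliable signal; the literal min/median reading is available via
``ratio="min_over_median"``.

Sector matching splits the (300 deg, 5 deg/pixel by default) field of view
into 1-6 contiguous equal subfields, recovers a heading per subfield
independently against the same-index subfields of the stored views, and
combines them by an unweighted circular mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .eye import EyeModel, SampledView, fov_offset, subsample, trim_fov
from .render import PanoramicImage
from .ridf import RIDFMatcher

__all__ = [
    "RouteMemory",
    "RIDF",
    "HeadingEstimate",
    "image_difference",
    "ridf",
    "recover_heading",
    "signal_strength",
    "sector_headings",
    "directional_error",
    "circular_mean_deg",
    "PerfectMemoryNavigator",
]

MAX_SECTORS = 6


def _wrap180(a):
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def directional_error(estimate, true_heading):
    """Absolute wrapped angular difference in degrees, in [0, 180]."""
    err = np.abs(_wrap180(np.asarray(estimate, dtype=float) - np.asarray(true_heading, dtype=float)))
    return err if err.ndim else float(err)


def circular_mean_deg(angles_deg) -> float:
    """Unit-vector (circular) mean of angles in degrees, in [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    mean = float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) % 360.0)
    return 0.0 if mean == 360.0 else mean


def image_difference(I, J) -> float:
    """Mean absolute difference between two equally sized images."""
    a = I.pixels if isinstance(I, SampledView) else np.asarray(I, dtype=float)
    b = J.pixels if isinstance(J, SampledView) else np.asarray(J, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def signal_strength(per_direction_best, ratio: str = "median_over_min") -> float:
    """Best-direction familiarity against the median over all directions.

    ``per_direction_best[k]`` is the lowest rIDF value over all stored views
    at rotation k.  With the default orientation larger means stronger; a
    perfect match (minimum 0) gives +inf.  A flat profile gives 1 (no signal).
    """
    v = np.asarray(per_direction_best, dtype=float)
    if v.size < 2:
        raise ValueError("signal strength needs at least two directions")
    lo = float(v.min())
    med = float(np.median(v))
    if ratio == "median_over_min":
        return med / lo if lo > 0 else (1.0 if med == lo else float("inf"))
    if ratio == "min_over_median":
        return lo / med if med > 0 else (1.0 if med == lo else float("inf"))
    raise ValueError(f"unknown ratio convention {ratio!r}")


@dataclass(frozen=True)
class RIDF:
    """rIDF values per candidate rotation (indexed by pixel shift)."""

    values: np.ndarray
    resolution: float

    @property
    def min_value(self) -> float:
        return float(self.values.min())

    @property
    def best_shift(self) -> int:
        return int(np.argmin(self.values))


@dataclass(frozen=True)
class HeadingEstimate:
    """Recovered heading plus the evidence behind it."""

    heading: float                  # degrees, world frame, [0, 360)
    min_value: float                # rIDF value at the chosen minimum
    best_memory_index: int
    signal_strength: float
    rotation_pixels: int = 0        # chosen shift of the current panorama
    sector_headings_deg: tuple = ()


@dataclass
class RouteMemory:
    """Ordered stored views along a training route, sharing one eye model.

    ``views`` is (n_mem, h, w) with w the trimmed FOV width; ``headings``
    holds the world-frame facing each view was stored at (the local route
    direction).
    """

    views: np.ndarray
    headings: np.ndarray
    eye: EyeModel
    _matchers: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.views = np.asarray(self.views, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float) % 360.0
        if self.views.ndim != 3 or len(self.views) == 0:
            raise ValueError("views must be a non-empty (n_mem, h, w) stack")
        if len(self.headings) != len(self.views):
            raise ValueError("one heading per stored view required")
        if self.views.shape[2] != self.eye.fov_pixels:
            raise ValueError(
                f"stored view width {self.views.shape[2]} does not match the "
                f"eye's FOV width {self.eye.fov_pixels}"
            )

    def __len__(self) -> int:
        return len(self.views)

    def matcher(self, n_sectors: int = 1, sector: int = 0, strategy: str = "auto") -> RIDFMatcher:
        """Cached rIDF engine for the whole field or one of n equal sectors."""
        w = self.eye.fov_pixels
        if not 1 <= n_sectors <= MAX_SECTORS:
            raise ValueError(f"n_sectors must lie in 1..{MAX_SECTORS}")
        if w % n_sectors != 0:
            raise ValueError(
                f"FOV of {w} pixels does not divide into {n_sectors} equal sectors"
            )
        key = (n_sectors, sector, strategy)
        if key not in self._matchers:
            sw = w // n_sectors
            c1 = sector * sw
            self._matchers[key] = RIDFMatcher(
                self.views[:, :, c1 : c1 + sw],
                self.eye.az_pixels_full,
                fov_offset(self.eye) + c1,
                strategy=strategy,
            )
        return self._matchers[key]

    # -- archive I/O -------------------------------------------------------

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            views=self.views,
            headings=self.headings,
            az_pixels_full=self.eye.az_pixels_full,
            fov_degrees=self.eye.fov_degrees,
        )

    @classmethod
    def load(cls, path) -> "RouteMemory":
        with np.load(path) as z:
            eye = EyeModel(int(z["az_pixels_full"]), float(z["fov_degrees"]))
            return cls(views=z["views"], headings=z["headings"], eye=eye)


def _as_full_view(current, eye: EyeModel) -> SampledView:
    if isinstance(current, SampledView):
        if current.eye.az_pixels_full != eye.az_pixels_full:
            raise ValueError("current view was sampled at a different resolution")
        if not current.is_full:
            raise ValueError("heading recovery needs the full 360 deg panorama")
        if current.eye != eye:  # same resolution, different FOV: retag
            return SampledView(current.pixels, eye, current.centre_heading)
        return current
    if isinstance(current, np.ndarray):
        current = PanoramicImage(pixels=current)
    if isinstance(current, PanoramicImage):
        return subsample(current, eye)
    raise TypeError(f"cannot interpret {type(current)} as a panorama")


def ridf(current, stored: SampledView | np.ndarray, eye: EyeModel, strategy="auto") -> RIDF:
    """rIDF of one stored (FOV-trimmed) view against a full current panorama."""
    cur = _as_full_view(current, eye)
    spx = stored.pixels if isinstance(stored, SampledView) else np.asarray(stored, dtype=float)
    if spx.shape != (eye.el_pixels, eye.fov_pixels):
        raise ValueError("stored view does not match the eye's trimmed geometry")
    m = RIDFMatcher(spx[None], eye.az_pixels_full, fov_offset(eye), strategy=strategy)
    return RIDF(values=m.ridf_all(cur.pixels)[0], resolution=eye.resolution)


def _pick_minimum(d: np.ndarray, resolution: float) -> tuple[int, int]:
    """Deterministic argmin over (stored view, rotation).

    Ties at the global minimum prefer the smallest rotation magnitude
    (straight ahead), then the earliest stored view.
    """
    s_idx, k_idx = np.nonzero(d == d.min())
    theta = np.abs(_wrap180(k_idx * resolution))
    pick = np.lexsort((k_idx, s_idx, theta))[0]
    return int(s_idx[pick]), int(k_idx[pick])


def _estimate_from_matcher(
    matcher: RIDFMatcher, cur: SampledView, ratio: str
) -> HeadingEstimate:
    d = matcher.ridf_all(cur.pixels)
    res = cur.eye.resolution
    s, k = _pick_minimum(d, res)
    return HeadingEstimate(
        heading=(cur.centre_heading + k * res) % 360.0,
        min_value=float(d[s, k]),
        best_memory_index=s,
        signal_strength=signal_strength(d.min(axis=0), ratio=ratio),
        rotation_pixels=k,
    )


def recover_heading(
    current, memory: RouteMemory, ratio: str = "median_over_min", strategy: str = "auto"
) -> HeadingEstimate:
    """Perfect-memory heading recovery: best (stored view, rotation) pair."""
    cur = _as_full_view(current, memory.eye)
    return _estimate_from_matcher(memory.matcher(strategy=strategy), cur, ratio)


def sector_headings(
    current,
    memory: RouteMemory,
    n_sectors: int,
    ratio: str = "median_over_min",
    strategy: str = "auto",
) -> HeadingEstimate:
    """Independent per-subfield matching combined by a circular mean.

    The FOV is cut into ``n_sectors`` contiguous equal subfields (even counts
    meet at the forward direction; odd counts centre the middle subfield on
    it).  Each subfield slides over the full panorama to find its own best
    heading; the final heading is the unweighted circular mean.
    """
    cur = _as_full_view(current, memory.eye)
    parts = [
        _estimate_from_matcher(memory.matcher(n_sectors, i, strategy), cur, ratio)
        for i in range(n_sectors)
    ]
    if n_sectors == 1:
        return parts[0]
    headings = [p.heading for p in parts]
    best = min(parts, key=lambda p: p.min_value)
    return HeadingEstimate(
        heading=circular_mean_deg(headings),
        min_value=float(np.mean([p.min_value for p in parts])),
        best_memory_index=best.best_memory_index,
        signal_strength=float(np.mean([p.signal_strength for p in parts])),
        rotation_pixels=best.rotation_pixels,
        sector_headings_deg=tuple(headings),
    )


# ---------------------------------------------------------------------------
# Estimator interface
# ---------------------------------------------------------------------------


class PerfectMemoryNavigator(BaseEstimator):
    """Scikit-learn style interface to perfect-memory route navigation.

    Parameters
    ----------
    az_pixels_full : int
        Even azimuthal pixel count of a full 360 deg panorama for this eye.
    fov_degrees : float
        Azimuthal field of view, symmetric about the forward direction.
    n_sectors : int
        Number of independently matched subfields (1 = whole-field matching).
    signal_ratio : {"median_over_min", "min_over_median"}
        Orientation of the signal-strength ratio.
    strategy : {"auto", "direct", "fft"}
        rIDF evaluation path (identical values either way).

    After ``fit`` the trained route memory is available as ``memory_``.
    ``predict`` returns world-frame headings in degrees; ``score`` returns
    the negative mean directional error so that larger is better.
    """

    def __init__(
        self,
        az_pixels_full: int = 1024,
        fov_degrees: float = 360.0,
        n_sectors: int = 1,
        signal_ratio: str = "median_over_min",
        strategy: str = "auto",
    ):
        self.az_pixels_full = az_pixels_full
        self.fov_degrees = fov_degrees
        self.n_sectors = n_sectors
        self.signal_ratio = signal_ratio
        self.strategy = strategy

    def fit(self, X: Sequence, y=None) -> "PerfectMemoryNavigator":
        """Store the training views.

        X: sequence of base panoramas (PanoramicImage or raw base-resolution
        arrays) or full-360 SampledViews at the eye's resolution, each facing
        along the local route direction.  y: the world-frame facing of each
        view (defaults to each panorama's own ``centre_heading``).
        """
        eye = EyeModel(self.az_pixels_full, self.fov_degrees)
        views, headings = [], []
        for i, item in enumerate(X):
            full = _as_full_view(item, eye)
            views.append(trim_fov(full, eye).pixels)
            headings.append(full.centre_heading if y is None else y[i])
        self.eye_ = eye
        self.memory_ = RouteMemory(np.asarray(views), np.asarray(headings), eye)
        # warm the matcher so repeated predicts reuse the precomputation
        self.memory_.matcher(strategy=self.strategy)
        return self

    def _check_fitted(self):
        if not hasattr(self, "memory_"):
            raise RuntimeError("navigator is not fitted; call fit() first")

    def _estimate(self, item) -> HeadingEstimate:
        if self.n_sectors == 1:
            return recover_heading(item, self.memory_, self.signal_ratio, self.strategy)
        return sector_headings(
            item, self.memory_, self.n_sectors, self.signal_ratio, self.strategy
        )

    def predict(self, X: Sequence) -> np.ndarray:
        """Recovered world-frame heading (degrees) per test panorama."""
        self._check_fitted()
        return np.array([self._estimate(item).heading for item in X])

    def predict_info(self, X: Sequence) -> pd.DataFrame:
        """Full evidence per test panorama (heading, rIDF minimum, signal)."""
        self._check_fitted()
        rows = []
        for item in X:
            est = self._estimate(item)
            rows.append(
                {
                    "heading": est.heading,
                    "min_value": est.min_value,
                    "best_memory_index": est.best_memory_index,
                    "signal_strength": est.signal_strength,
                    "rotation_pixels": est.rotation_pixels,
                }
            )
        return pd.DataFrame(rows)

    def score(self, X: Sequence, y) -> float:
        """Negative mean directional error in degrees (larger is better)."""
        err = directional_error(self.predict(X), np.asarray(y, dtype=float))
        return -float(np.mean(err))
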