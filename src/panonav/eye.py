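"""Parameterised eye models: resolution subsampling and field-of-view trimming.

An :class:`EyeModel` is defined by the number of azimuthal pixels a full
360 deg panorama would have (even, because the model targets bilaterian
animals with mirror-symmetric eyes; minimum 2) and an azimuthal field of view
symmetric about the forward direction.  Views are always produced by the
pipeline render -> subsample -> trim: the world is rendered once at base
resolution (1024 azimuthal pixels), box-averaged down to the eye's
resolution, and only then cut to the field of view.

Vertical resolution co-varies with azimuthal resolution (pixels stay roughly
square): the subsampled image has ``round(75 / resolution)`` rows (at least
one), produced by an area-weighted box filter over the 75 deg elevation
window, which preserves the mean intensity of the panorama exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .render import BASE_AZ_PIXELS, BASE_EL_PIXELS, EL_EXTENT, PanoramicImage

__all__ = ["EyeModel", "SampledView", "subsample", "trim_fov", "rotate_view", "EyeSampler"]


@dataclass(frozen=True)
class EyeModel:
    """An eye: azimuthal pixel count for a full panorama plus field of view."""

    az_pixels_full: int
    fov_degrees: float = 360.0

    def __post_init__(self):
        n = self.az_pixels_full
        if n < 2 or n % 2 != 0:
            raise ValueError("az_pixels_full must be an even integer >= 2")
        if not (0.0 < self.fov_degrees <= 360.0):
            raise ValueError("fov_degrees must lie in (0, 360]")

    @property
    def resolution(self) -> float:
        """Degrees of azimuth per pixel."""
        return 360.0 / self.az_pixels_full

    @property
    def fov_pixels(self) -> int:
        """Width of the trimmed view: the nearest even pixel count to the
        requested angular field, floored at the two-pixel minimum so every
        (resolution, FOV) combination in the factorial sweep yields a view."""
        return max(2, 2 * round(self.az_pixels_full * self.fov_degrees / 720.0))

    @property
    def el_pixels(self) -> int:
        return max(1, round(EL_EXTENT / self.resolution))


@dataclass(frozen=True)
class SampledView:
    """An image as seen through an eye; may be full 360 deg or FOV-trimmed."""

    pixels: np.ndarray
    eye: EyeModel
    centre_heading: float = 0.0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if px.shape[1] not in (self.eye.az_pixels_full, self.eye.fov_pixels):
            raise ValueError(
                f"view width {px.shape[1]} matches neither the full panorama "
                f"({self.eye.az_pixels_full}) nor the trimmed FOV "
                f"({self.eye.fov_pixels}) of the eye"
            )

    @property
    def is_full(self) -> bool:
        return self.pixels.shape[1] == self.eye.az_pixels_full

    @property
    def w(self) -> int:
        return self.pixels.shape[1]

    @property
    def h(self) -> int:
        return self.pixels.shape[0]


@lru_cache(maxsize=64)
def _box_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Area-weighted box filter matrix (n_out x n_in) over a shared interval.

    Row i averages the input bins overlapping output bin i; rows sum to one
    exactly, so the filter conserves the image mean.
    """
    edges_in = np.arange(n_in + 1) / n_in
    edges_out = np.arange(n_out + 1) / n_out
    lo = np.maximum(edges_out[:-1, None], edges_in[None, :-1])
    hi = np.minimum(edges_out[1:, None], edges_in[None, 1:])
    w = np.clip(hi - lo, 0.0, None)
    w /= w.sum(axis=1, keepdims=True)
    return w


def _snap_binary(px: np.ndarray) -> np.ndarray:
    # Float box filtering can leave pure sky/object a few ulp off the exact
    # values; snap so downstream code can classify pixels exactly.
    px[np.abs(px - 1.0) < 1e-12] = 1.0
    px[np.abs(px) < 1e-12] = 0.0
    return px


def subsample(base: PanoramicImage | SampledView, eye: EyeModel) -> SampledView:
    """Box-average a full-360 panorama down to the eye's resolution.

    Azimuth uses exact pixel blocks when the input width is a multiple of the
    eye's pixel count and an area-weighted average otherwise; elevation always
    uses the area-weighted filter over the common 75 deg window.
    """
    px = base.pixels
    n_in = px.shape[1]
    n_out = eye.az_pixels_full
    if isinstance(base, SampledView) and not base.is_full:
        raise ValueError("subsample requires a full 360 deg panorama")
    if n_out > n_in:
        raise ValueError("cannot subsample to a finer resolution than the input")
    if n_in % n_out == 0:
        block = n_in // n_out
        az_avg = px.reshape(px.shape[0], n_out, block).mean(axis=2)
    else:
        logging.getLogger("panonav").debug(
            "azimuthal pixel count %d does not divide %d; using area-weighted averaging",
            n_out, n_in,
        )
        az_avg = px @ _box_matrix(n_in, n_out).T
    out = _box_matrix(px.shape[0], eye.el_pixels) @ az_avg
    return SampledView(
        pixels=_snap_binary(out), eye=eye, centre_heading=getattr(base, "centre_heading", 0.0)
    )


def trim_fov(view: SampledView, eye: EyeModel | None = None) -> SampledView:
    """Keep the central ``fov_pixels`` columns, symmetric about the forward
    direction (the centre column boundary)."""
    eye = eye or view.eye
    if not view.is_full:
        raise ValueError("trim_fov requires a full 360 deg view")
    n = eye.az_pixels_full
    w = eye.fov_pixels
    if w == n:
        return view
    c0 = (n - w) // 2
    return SampledView(
        pixels=view.pixels[:, c0 : c0 + w], eye=eye, centre_heading=view.centre_heading
    )


def fov_offset(eye: EyeModel) -> int:
    """Column index in the full panorama where the trimmed FOV starts."""
    return (eye.az_pixels_full - eye.fov_pixels) // 2


def rotate_view(view: SampledView, k: int) -> SampledView:
    """The view after the agent rotates its facing by ``k`` pixels (angle
    ``k * resolution`` counter-clockwise); a pure circular column shift."""
    if not view.is_full:
        raise ValueError("rotate_view requires a full 360 deg view")
    n = view.eye.az_pixels_full
    k = int(k) % n
    return SampledView(
        pixels=np.roll(view.pixels, -k, axis=1),
        eye=view.eye,
        centre_heading=(view.centre_heading + k * view.eye.resolution) % 360.0,
    )


class EyeSampler(BaseEstimator, TransformerMixin):
    """Transformer mapping base panoramas to eye-limited views.

    Parameters
    ----------
    az_pixels_full : int
        Even azimuthal pixel count of a full panorama at this resolution.
    fov_degrees : float
        Azimuthal field of view, symmetric about the forward direction.
    trim : bool
        If True (default) ``transform`` returns FOV-trimmed views; otherwise
        full 360 deg views at the eye's resolution.
    """

    def __init__(self, az_pixels_full: int = 1024, fov_degrees: float = 360.0, trim: bool = True):
        self.az_pixels_full = az_pixels_full
        self.fov_degrees = fov_degrees
        self.trim = trim

    def _eye(self) -> EyeModel:
        return EyeModel(self.az_pixels_full, self.fov_degrees)

    def fit(self, X=None, y=None):
        self.eye_ = self._eye()
        return self

    def transform(self, X) -> np.ndarray:
        """X: iterable of PanoramicImage/SampledView or array (n, h, 1024).

        Returns an array (n, h_eye, w) of pixel grids.
        """
        eye = getattr(self, "eye_", None) or self._eye()
        out = []
        for item in X:
            if isinstance(item, np.ndarray):
                item = PanoramicImage(pixels=item)
            view = subsample(item, eye)
            if self.trim:
                view = trim_fov(view, eye)
            out.append(view.pixels)
        return np.asarray(out)
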