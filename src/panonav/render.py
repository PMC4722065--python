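"""Panoramic silhouette rendering.

Views are rendered the way a navigating insect is assumed to see a sparse
habitat: opaque black vegetation against a uniformly white sky, over the full
360 deg of azimuth and 75 deg of elevation above the horizon.  Pixels on an
object/sky boundary take the grey value equal to the fraction of the pixel's
solid angle covered by sky, estimated with a deterministic stratified
supersampling grid (S x S rays per pixel), so grey levels are exact multiples
of 1/S^2.

The projection is equirectangular (equal-angle azimuth x elevation bins),
which makes a rotation of the agent an exact circular column shift of the
image.  The base image is 1024 azimuthal pixels (0.3515625 deg/pixel) by 213
elevation rows spanning the 75 deg window.

Implementation: rather than intersecting every ray with every triangle, each
triangle is projected to a conservative azimuth/elevation bounding box and
only the supersample rays inside that box are tested (Moller-Trumbore),
OR-ing hits into a shared buffer.  Ray results are exact; the box is only a
culling device, so the image equals the brute-force all-rays render.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numba import njit

from .worldgen import World

__all__ = [
    "BASE_AZ_PIXELS",
    "BASE_EL_PIXELS",
    "EL_EXTENT",
    "Viewpoint",
    "PanoramicImage",
    "render_panorama",
    "ray_hits_world",
    "save_png",
    "load_png",
]

BASE_AZ_PIXELS = 1024
EL_EXTENT = 75.0
#: Elevation rows at base resolution: round(75 / (360/1024)) = 213.
BASE_EL_PIXELS = 213

_EPS_T = 1e-9       # minimum hit range (metres)
_EPS_PAR = 1e-12    # parallel-ray determinant cutoff


@dataclass(frozen=True)
class Viewpoint:
    """Agent pose: ground position, eye height and facing direction."""

    x: float
    y: float
    eye_height: float = 0.02
    heading: float = 0.0

    def __post_init__(self):
        if not self.eye_height > 0:
            raise ValueError("eye_height must be positive")
        object.__setattr__(self, "heading", float(self.heading) % 360.0)

    @property
    def origin(self) -> np.ndarray:
        return np.array([self.x, self.y, self.eye_height])


@dataclass(frozen=True)
class PanoramicImage:
    """Equirectangular grey image: row 0 is the top of the view (75 deg).

    Column ``j`` covers azimuth offsets ``[-180 + j*pitch, -180 + (j+1)*pitch)``
    relative to ``centre_heading``, so the centre column boundary is the
    forward direction.  Values lie in [0, 1]: 0 = object, 1 = sky.
    """

    pixels: np.ndarray
    centre_heading: float = 0.0
    az_extent: float = 360.0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if px.size and (px.min() < -1e-12 or px.max() > 1 + 1e-12):
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def el_pixels(self) -> int:
        return self.pixels.shape[0]

    @property
    def az_pixels(self) -> int:
        return self.pixels.shape[1]

    @property
    def resolution(self) -> float:
        """Azimuthal angular resolution, degrees per pixel."""
        return self.az_extent / self.az_pixels


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _wrap180(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def _triangle_boxes(tri: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Conservative (az_lo, az_width, el_lo, el_hi) per viewer-relative triangle.

    Azimuth bounds use the fact that azimuth is monotone along any great-circle
    arc not through the zenith; elevation bounds pad the vertex range by the
    full azimuthal width, which bounds the bulge of an arc above its endpoints.
    Triangles whose spherical projection contains the zenith, or that touch the
    viewpoint, fall back to the full azimuth range.
    """
    n = tri.shape[0]
    r = np.linalg.norm(tri, axis=2)                      # (n, 3)
    degenerate = r.min(axis=1) < 1e-9
    rs = np.where(r < 1e-30, 1.0, r)
    unit = tri / rs[:, :, None]

    az = np.degrees(np.arctan2(tri[:, :, 1], tri[:, :, 0]))   # (n, 3)
    el = np.degrees(np.arcsin(np.clip(unit[:, :, 2], -1.0, 1.0)))

    # Edge arcs: (0,1), (1,2), (2,0).
    ia = np.array([0, 1, 2])
    ib = np.array([1, 2, 0])
    ua = unit[:, ia, :]
    ub = unit[:, ib, :]
    en = np.cross(ua, ub)                                # (n, 3 edges, 3)
    nz = en[:, :, 2]
    s = np.where(nz >= 0.0, 1.0, -1.0)
    width = (s * (az[:, ib] - az[:, ia])) % 360.0        # (n, 3)
    # An arc in a meridian plane keeps its azimuth (unless it crosses the
    # zenith, handled below); take the short interval between its endpoints.
    near_meridian = np.abs(nz) < 1e-12
    short = np.abs(_wrap180(az[:, ib] - az[:, ia]))
    width = np.where(near_meridian, short, width)
    s = np.where(near_meridian, np.sign(_wrap180(az[:, ib] - az[:, ia]) + 1e-30), s)

    ref = az[:, 0]
    rel_start = _wrap180(az[:, ia] - ref[:, None])
    rel_end = rel_start + s * width
    lo = np.minimum(rel_start, rel_end).min(axis=1)
    hi = np.maximum(rel_start, rel_end).max(axis=1)
    span = hi - lo

    # Zenith strictly inside the spherical triangle -> full azimuth range.
    # The zenith is inside iff, for every edge plane, it lies on the same side
    # as the opposite vertex.
    opp = np.array([2, 0, 1])
    side_z = nz
    side_v = np.einsum("nek,nek->ne", en, unit[:, opp, :])
    zin = (side_z * side_v > 0).all(axis=1)
    full = zin | degenerate | (span >= 360.0)

    # Elevation bulge of an arc beyond its endpoints is bounded by the arc's
    # own azimuthal width; pad per edge, then take the extremes.
    el_a, el_b = el[:, ia], el[:, ib]
    el_hi = (np.maximum(el_a, el_b) + width).max(axis=1)
    el_lo = (np.minimum(el_a, el_b) - width).min(axis=1)
    el_lo = np.clip(el_lo, 0.0, EL_EXTENT)
    el_hi = np.clip(el_hi, 0.0, EL_EXTENT)
    el_lo = np.where(full, 0.0, el_lo)
    el_hi = np.where(full | zin, EL_EXTENT, el_hi)

    az_lo = np.where(full, -180.0, ref + lo)
    az_width = np.where(full, 360.0, span)
    return az_lo, az_width, el_lo, el_hi


@njit(cache=True)
def _cast_hits(tris, r0s, r1s, j0s, j1s, cos_az, sin_az, cos_el, sin_el, eps_par, eps_t, hit):
    """Moller-Trumbore over each triangle's bounding-box ray grid, OR-ing
    results into the supersample hit buffer."""
    n_az = cos_az.shape[0]
    for i in range(tris.shape[0]):
        v0x, v0y, v0z = tris[i, 0, 0], tris[i, 0, 1], tris[i, 0, 2]
        e1x, e1y, e1z = tris[i, 1, 0] - v0x, tris[i, 1, 1] - v0y, tris[i, 1, 2] - v0z
        e2x, e2y, e2z = tris[i, 2, 0] - v0x, tris[i, 2, 1] - v0y, tris[i, 2, 2] - v0z
        # q = s x e1 with s = -v0 (ray origin at 0); constant per triangle
        qx = -v0y * e1z + v0z * e1y
        qy = -v0z * e1x + v0x * e1z
        qz = -v0x * e1y + v0y * e1x
        tdotq = e2x * qx + e2y * qy + e2z * qz
        n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        n2 = np.sqrt(e2x * e2x + e2y * e2y + e2z * e2z)
        cutoff = eps_par * max(1.0, n1 * n2)
        for r in range(r0s[i], r1s[i] + 1):
            ce = cos_el[r]
            se = sin_el[r]
            for jj in range(j0s[i], j1s[i] + 1):
                j = jj % n_az
                if hit[r, j]:
                    continue
                dx = ce * cos_az[j]
                dy = ce * sin_az[j]
                dz = se
                hx = dy * e2z - dz * e2y
                hy = dz * e2x - dx * e2z
                hz = dx * e2y - dy * e2x
                det = e1x * hx + e1y * hy + e1z * hz
                if det > cutoff or det < -cutoff:
                    inv = 1.0 / det
                    u = (-v0x * hx - v0y * hy - v0z * hz) * inv
                    if u >= 0.0:
                        v = (dx * qx + dy * qy + dz * qz) * inv
                        if v >= 0.0 and u + v <= 1.0 and tdotq * inv > eps_t:
                            hit[r, j] = True


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_panorama(
    world: World,
    vp: Viewpoint,
    az_pixels: int = BASE_AZ_PIXELS,
    supersample: int = 4,
) -> PanoramicImage:
    """Render the panoramic silhouette view of ``world`` from ``vp``.

    Each pixel value is the fraction of its ``supersample x supersample``
    stratified rays that reach the sky.  An empty world renders all-white.
    """
    if az_pixels < 1 or supersample < 1:
        raise ValueError("az_pixels and supersample must be positive")
    el_pixels = BASE_EL_PIXELS if az_pixels == BASE_AZ_PIXELS else max(
        1, round(EL_EXTENT / (360.0 / az_pixels))
    )
    S = supersample
    n_az = az_pixels * S
    n_el = el_pixels * S
    q_az = 360.0 / n_az
    q_el = EL_EXTENT / n_el

    tris = world.triangles if isinstance(world, World) else np.asarray(world)
    tris = tris - vp.origin[None, None, :]
    # Cull triangles that can never intersect an above-horizon ray.
    if len(tris):
        tris = tris[tris[:, :, 2].max(axis=1) >= 0.0]

    hit = np.zeros((n_el, n_az), dtype=np.bool_)
    if len(tris):
        az_lo, az_width, el_lo, el_hi = _triangle_boxes(tris)
        margin = 1.0  # extra supersample steps around each box
        keep = el_hi > 0.0
        # Azimuth column range (may wrap; the kernel wraps indices mod n_az).
        j0 = np.floor((az_lo - vp.heading + 180.0) / q_az - 0.5 - margin).astype(np.int64)
        j1 = np.ceil((az_lo + az_width - vp.heading + 180.0) / q_az - 0.5 + margin).astype(np.int64)
        wide = j1 - j0 + 1 >= n_az
        j0[wide], j1[wide] = 0, n_az - 1
        # Elevation row range (row 0 = top of the view).
        r0 = np.floor((EL_EXTENT - el_hi) / q_el - 0.5 - margin).astype(np.int64)
        r1 = np.ceil((EL_EXTENT - el_lo) / q_el - 0.5 + margin).astype(np.int64)
        r0 = np.maximum(r0, 0)
        r1 = np.minimum(r1, n_el - 1)
        keep &= r1 >= r0
        az = np.radians(vp.heading + (np.arange(n_az) + 0.5) * q_az - 180.0)
        el = np.radians(EL_EXTENT - (np.arange(n_el) + 0.5) * q_el)
        _cast_hits(
            np.ascontiguousarray(tris[keep]),
            r0[keep], r1[keep], j0[keep], j1[keep],
            np.cos(az), np.sin(az), np.cos(el), np.sin(el),
            _EPS_PAR, _EPS_T, hit,
        )

    frac_hit = hit.reshape(el_pixels, S, az_pixels, S).mean(axis=(1, 3))
    return PanoramicImage(pixels=1.0 - frac_hit, centre_heading=vp.heading)


def ray_hits_world(origin, direction, world: World) -> bool:
    """True iff the ray from ``origin`` along ``direction`` hits any triangle.

    ``direction`` need not be normalised; its elevation must be >= 0.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    d = d / norm
    if d[2] < -1e-12:
        raise ValueError("ray elevation must be >= 0")
    tris = world.triangles if isinstance(world, World) else np.asarray(world)
    if len(tris) == 0:
        return False
    tris = tris - np.asarray(origin, dtype=float)[None, None, :]
    v0 = tris[:, 0]
    e1 = tris[:, 1] - v0
    e2 = tris[:, 2] - v0
    h = np.cross(np.broadcast_to(d, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, h)
    scale = np.maximum(
        1.0, np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
    )
    ok = np.abs(det) > _EPS_PAR * scale
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    s = -v0
    q = np.cross(s, e1)
    u = np.einsum("ij,ij->i", s, h) * inv
    v = (q @ d) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    return bool(
        (ok & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t > _EPS_T)).any()
    )


# ---------------------------------------------------------------------------
# PNG I/O (8-bit grey + JSON sidecar with angular metadata)
# ---------------------------------------------------------------------------


def save_png(image: PanoramicImage, path) -> None:
    from PIL import Image

    arr = np.round(np.clip(image.pixels, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    meta = {
        "centre_heading": image.centre_heading,
        "az_extent": image.az_extent,
        "el_extent": EL_EXTENT,
        "az_pixels": image.az_pixels,
        "el_pixels": image.el_pixels,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_png(path) -> PanoramicImage:
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {"centre_heading": 0.0, "az_extent": 360.0}
    return PanoramicImage(
        pixels=arr,
        centre_heading=meta.get("centre_heading", 0.0),
        az_extent=meta.get("az_extent", 360.0),
    )
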