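"""Procedural generation of simulated semi-arid habitats.

Worlds emulate the visually sparse environments of Australian desert ants:
near grass tussocks (three-dimensional objects roughly 1 m tall, built from a
handful of black triangular facets) scattered over a bounded arena, and large
distant trees rendered as flat two-dimensional silhouettes ("billboards")
because, at their distance from the tested region, depth is visually
redundant.  Everything an agent can see is an opaque black triangle against a
white sky.

All distances are in metres.  The coordinate frame is right-handed with z up,
the world centre at the origin, azimuth 0 deg along +x and increasing
counter-clockwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "WORLD_TYPES",
    "WorldConfig",
    "SceneObject",
    "World",
    "generate_world",
    "make_tussock",
    "make_tree",
    "load_world",
    "save_world",
]

WORLD_TYPES = ("tussocks_only", "trees_only", "trees_and_tussocks")


class WorldConfigError(ValueError):
    """Raised for invalid world configurations."""


class PlacementError(ValueError):
    """Raised when an object anchor violates the placement rules."""


# ---------------------------------------------------------------------------
# Templates
#
# The study's objects are "pre-defined black triangles in random
# configurations": what matters for the navigation results is the scale of
# the objects (tussocks ~1 m and proximal, trees 8-15 m and distal), not the
# exact facet geometry, so the templates below are simple canonical shapes
# in a unit frame (height 1, half-width 0.5) that the generator scales,
# rotates and jitters per object.
# ---------------------------------------------------------------------------


def _fan_template(n_planes: int) -> np.ndarray:
    """Vertical triangular facets sharing a central axis (cross/star section)."""
    tris = []
    for i in range(n_planes):
        phi = np.pi * i / n_planes
        d = np.array([np.cos(phi), np.sin(phi), 0.0])
        v0 = -0.5 * d
        v1 = 0.5 * d
        v2 = np.array([0.0, 0.0, 1.0])
        tris.append([v0, v1, v2])
    return np.asarray(tris)


def _tepee_template(n_facets: int) -> np.ndarray:
    """A cone-like clump: base ring of radius 0.5, facets meeting at the top."""
    tris = []
    apex = np.array([0.0, 0.0, 1.0])
    ang = 2.0 * np.pi * np.arange(n_facets + 1) / n_facets
    ring = np.stack([0.5 * np.cos(ang), 0.5 * np.sin(ang), np.zeros_like(ang)], axis=1)
    for i in range(n_facets):
        tris.append([ring[i], ring[i + 1], apex])
    return np.asarray(tris)


#: Tussock templates: 2-6 facets each, at least two distinct orientations.
TUSSOCK_TEMPLATES: tuple[np.ndarray, ...] = (
    _fan_template(2),
    _fan_template(3),
    _tepee_template(6),
)


def _conifer_silhouette() -> np.ndarray:
    """Stacked triangles in the (u, z) plane, unit height."""
    tris = [
        [(-0.38, 0.00), (0.38, 0.00), (0.0, 0.50)],
        [(-0.30, 0.32), (0.30, 0.32), (0.0, 0.75)],
        [(-0.21, 0.60), (0.21, 0.60), (0.0, 1.00)],
    ]
    return np.asarray([[(u, 0.0, z) for u, z in tri] for tri in tris])


def _blob_silhouette(n_seg: int = 8) -> np.ndarray:
    """Trunk plus an elliptical canopy fan, unit height, coplanar."""
    tris = [
        [(-0.04, 0.0, 0.0), (0.04, 0.0, 0.0), (0.04, 0.0, 0.35)],
        [(-0.04, 0.0, 0.0), (0.04, 0.0, 0.35), (-0.04, 0.0, 0.35)],
    ]
    cu, cz, ru, rz = 0.0, 0.62, 0.5, 0.38
    ang = 2.0 * np.pi * np.arange(n_seg + 1) / n_seg
    pts = [(cu + ru * np.cos(a), 0.0, cz + rz * np.sin(a)) for a in ang]
    for i in range(n_seg):
        tris.append([(cu, 0.0, cz), pts[i], pts[i + 1]])
    return np.asarray(tris)


def _umbrella_silhouette(n_seg: int = 6) -> np.ndarray:
    """Trunk plus a flat-bottomed half-disc canopy, unit height, coplanar."""
    tris = [
        [(-0.05, 0.0, 0.0), (0.05, 0.0, 0.0), (0.05, 0.0, 0.55)],
        [(-0.05, 0.0, 0.0), (0.05, 0.0, 0.55), (-0.05, 0.0, 0.55)],
    ]
    cu, cz, ru, rz = 0.0, 0.55, 0.5, 0.45
    ang = np.pi * np.arange(n_seg + 1) / n_seg
    pts = [(cu + ru * np.cos(a), 0.0, cz + rz * np.sin(a)) for a in ang]
    for i in range(n_seg):
        tris.append([(cu, 0.0, cz), pts[i], pts[i + 1]])
    return np.asarray(tris)


#: Tree silhouette templates, all coplanar in the u-z plane.
TREE_TEMPLATES: tuple[np.ndarray, ...] = (
    _conifer_silhouette(),
    _blob_silhouette(),
    _umbrella_silhouette(),
)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a procedurally generated world.

    Defaults place a 45 m tussock arena around the origin: training routes
    are 20 m and the largest tested displacement is 34 m, so the arena holds
    the whole tested region (radius <= 38.5 m).  Trees sit on a ring beyond
    the arena (50-80 m), keeping them distal to every test location so their
    flat two-dimensional rendering is justified.  The tussock density gives a
    mean nearest-neighbour spacing of ~2 m: sparse enough that the sky
    dominates every view, dense enough that each panorama holds several
    mid-range tussocks.
    """

    world_type: str = "trees_and_tussocks"
    arena_radius: float = 45.0
    tussock_density: float = 0.08          # tussocks per square metre
    tree_count: int = 16
    tree_ring: tuple[float, float] = (50.0, 80.0)
    #: Object-free corridor half-width around the training routes (metres).
    #: Routes radiate from the centre, so the zone is the union of
    #: ``exclusion_routes`` segments of length ``exclusion_length``.  A
    #: tussock sitting on the route itself blinds the stored views around it
    #: and its apparent size cannot be matched by rotating the view, so a
    #: cleared corridor keeps training views informative.
    exclusion_radius: float = 2.0
    exclusion_routes: int = 8
    exclusion_length: float = 20.0
    tussock_height: tuple[float, float] = (0.7, 1.3)   # uniform draw, metres
    #: Trees are large distal silhouettes: tall enough that from the tested
    #: region they subtend tens of degrees, dominating the skyline the way
    #: the near-tussock field never can.
    tree_height: tuple[float, float] = (8.0, 30.0)     # uniform draw, metres
    rng_seed: int = 0

    def validate(self) -> None:
        if self.world_type not in WORLD_TYPES:
            raise WorldConfigError(
                f"world_type must be one of {WORLD_TYPES}, got {self.world_type!r}"
            )
        if not self.arena_radius > 0:
            raise WorldConfigError("arena_radius must be positive")
        if self.tussock_density < 0:
            raise WorldConfigError("tussock_density must be non-negative")
        if self.tree_count < 0:
            raise WorldConfigError("tree_count must be non-negative")
        inner, outer = self.tree_ring
        if not (0 < inner <= outer):
            raise WorldConfigError("tree_ring must satisfy 0 < inner <= outer")
        if inner < self.arena_radius - 1e-9:
            # trees must stay distal to the tested region (which lies inside
            # the arena) or their flat-billboard treatment breaks down
            raise WorldConfigError("tree_ring.inner must not be inside the arena")
        if self.exclusion_radius < 0:
            raise WorldConfigError("exclusion_radius must be non-negative")
        if self.exclusion_routes < 0 or self.exclusion_length < 0:
            raise WorldConfigError("route exclusion geometry must be non-negative")


@dataclass(frozen=True)
class SceneObject:
    """A single tussock or tree: a set of opaque black triangles.

    ``triangles`` has shape (n_triangles, 3 vertices, 3 coords) in world
    metres; ``anchor`` is the (x, y) ground position the object was grown at.
    """

    kind: str  # "tussock" | "tree"
    triangles: np.ndarray
    anchor: tuple[float, float]

    def __post_init__(self):
        tri = np.asarray(self.triangles, dtype=float)
        object.__setattr__(self, "triangles", tri)
        if tri.ndim != 3 or tri.shape[1:] != (3, 3):
            raise ValueError("triangles must have shape (n, 3, 3)")

    @property
    def max_height(self) -> float:
        return float(self.triangles[:, :, 2].max())


@dataclass(frozen=True)
class World:
    """A bounded arena of scene objects plus the config that generated it."""

    objects: tuple[SceneObject, ...]
    config: WorldConfig

    @property
    def triangles(self) -> np.ndarray:
        """All triangles stacked, shape (n_total, 3, 3); empty -> (0, 3, 3)."""
        if not self.objects:
            return np.zeros((0, 3, 3))
        return np.concatenate([o.triangles for o in self.objects], axis=0)

    def to_json(self) -> str:
        payload = {
            "config": _config_dict(self.config),
            "objects": [
                {
                    "kind": o.kind,
                    "anchor": list(o.anchor),
                    "triangles": o.triangles.tolist(),
                }
                for o in self.objects
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "World":
        payload = json.loads(text)
        cfg = _config_from_dict(payload["config"])
        objects = tuple(
            SceneObject(
                kind=o["kind"],
                anchor=tuple(o["anchor"]),
                triangles=np.asarray(o["triangles"], dtype=float),
            )
            for o in payload["objects"]
        )
        return cls(objects=objects, config=cfg)


def _config_dict(cfg: WorldConfig) -> dict:
    d = asdict(cfg)
    d["tree_ring"] = list(cfg.tree_ring)
    d["tussock_height"] = list(cfg.tussock_height)
    d["tree_height"] = list(cfg.tree_height)
    return d


def _config_from_dict(d: dict) -> WorldConfig:
    known = set(WorldConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise WorldConfigError(f"unknown world config keys: {sorted(unknown)}")
    kw = dict(d)
    for key in ("tree_ring", "tussock_height", "tree_height"):
        if key in kw:
            kw[key] = tuple(kw[key])
    cfg = WorldConfig(**kw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Object factories
# ---------------------------------------------------------------------------


def _rot_z(yaw: float) -> np.ndarray:
    c, s = np.cos(yaw), np.sin(yaw)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_tussock(
    anchor: tuple[float, float],
    rng: np.random.Generator,
    config: WorldConfig | None = None,
    template: np.ndarray | None = None,
) -> SceneObject:
    """Grow a tussock at ``anchor``: a scaled, yawed copy of a facet template.

    Height is drawn uniformly from ``config.tussock_height`` (default near
    1 m); the footprint scales with height so clumps keep their aspect.
    """
    cfg = config or WorldConfig()
    if template is None:
        template = TUSSOCK_TEMPLATES[rng.integers(len(TUSSOCK_TEMPLATES))]
    height = rng.uniform(*cfg.tussock_height)
    width = height * rng.uniform(0.6, 1.2)
    yaw = rng.uniform(0.0, 2.0 * np.pi)
    tri = np.asarray(template, dtype=float).copy()
    tri[:, :, :2] *= width
    tri[:, :, 2] *= height
    tri = tri @ _rot_z(yaw).T
    tri[:, :, 0] += anchor[0]
    tri[:, :, 1] += anchor[1]
    return SceneObject(kind="tussock", triangles=tri, anchor=(float(anchor[0]), float(anchor[1])))


def make_tree(
    anchor: tuple[float, float],
    rng: np.random.Generator,
    config: WorldConfig | None = None,
    template: np.ndarray | None = None,
) -> SceneObject:
    """Grow a flat tree silhouette at ``anchor``, facing the arena centre.

    The billboard plane contains the vertical axis through the anchor and is
    normal to the anchor's radial direction, so an agent near the centre sees
    the silhouette face-on.  Raises :class:`PlacementError` if the anchor is
    inside the tree ring's inner radius.
    """
    cfg = config or WorldConfig()
    ax, ay = float(anchor[0]), float(anchor[1])
    dist = float(np.hypot(ax, ay))
    if dist < cfg.tree_ring[0] - 1e-9:
        raise PlacementError(
            f"tree anchor at {dist:.2f} m is inside the tree ring "
            f"(inner radius {cfg.tree_ring[0]} m)"
        )
    if template is None:
        template = TREE_TEMPLATES[rng.integers(len(TREE_TEMPLATES))]
    height = rng.uniform(*cfg.tree_height)
    width = height * rng.uniform(0.5, 0.9)
    # In-plane horizontal axis: perpendicular to the radial direction.
    radial = np.array([ax, ay]) / dist
    u_dir = np.array([-radial[1], radial[0], 0.0])
    z_dir = np.array([0.0, 0.0, 1.0])
    tpl = np.asarray(template, dtype=float)
    tri = (
        tpl[:, :, 0:1] * (width * u_dir)
        + tpl[:, :, 2:3] * (height * z_dir)
    )
    tri[:, :, 0] += ax
    tri[:, :, 1] += ay
    return SceneObject(kind="tree", triangles=tri, anchor=(ax, ay))


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------


def _draw_annulus_point(rng: np.random.Generator, r_min: float, r_max: float) -> np.ndarray:
    # Area-uniform in the annulus [r_min, r_max].
    r = np.sqrt(rng.uniform(r_min**2, r_max**2))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([r * np.cos(theta), r * np.sin(theta)])


def _route_corridor_distance(p: np.ndarray, cfg: WorldConfig) -> float:
    """Distance from ``p`` to the nearest radiating route segment."""
    if cfg.exclusion_routes == 0:
        return np.inf
    best = np.inf
    for i in range(cfg.exclusion_routes):
        ang = 2.0 * np.pi * i / cfg.exclusion_routes
        u = np.array([np.cos(ang), np.sin(ang)])
        t = np.clip(p @ u, 0.0, cfg.exclusion_length)
        best = min(best, float(np.linalg.norm(p - t * u)))
    return best


def _draw_tussock_anchor(rng: np.random.Generator, cfg: WorldConfig) -> np.ndarray:
    """Area-uniform in the arena, outside the route corridors."""
    for _ in range(1000):
        p = _draw_annulus_point(rng, 0.0, cfg.arena_radius)
        if _route_corridor_distance(p, cfg) >= cfg.exclusion_radius:
            return p
    raise WorldConfigError(
        "route exclusion zone leaves no room for tussocks in the arena"
    )


def generate_world(config: WorldConfig) -> World:
    """Generate a world deterministically from its config.

    Each object draws from its own child random stream spawned from
    ``config.rng_seed``, so regeneration is reproducible and independent of
    insertion order.
    """
    config.validate()
    has_tussocks = config.world_type in ("tussocks_only", "trees_and_tussocks")
    has_trees = config.world_type in ("trees_only", "trees_and_tussocks")

    area = np.pi * config.arena_radius**2
    n_tussocks = int(round(config.tussock_density * area)) if has_tussocks else 0
    n_trees = config.tree_count if has_trees else 0

    children = np.random.SeedSequence(config.rng_seed).spawn(n_tussocks + n_trees)
    objects: list[SceneObject] = []
    for i in range(n_tussocks):
        rng = np.random.default_rng(children[i])
        anchor = _draw_tussock_anchor(rng, config)
        objects.append(make_tussock(anchor, rng, config))
    for i in range(n_trees):
        rng = np.random.default_rng(children[n_tussocks + i])
        anchor = _draw_annulus_point(rng, config.tree_ring[0], config.tree_ring[1])
        objects.append(make_tree(anchor, rng, config))
    return World(objects=tuple(objects), config=config)


def save_world(world: World, path) -> None:
    with open(path, "w") as fh:
        fh.write(world.to_json())


def load_world(path) -> World:
    with open(path) as fh:
        return World.from_json(fh.read())
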