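"""Study orchestration: training routes, displacement grids, parameter sweeps.

The full protocol: in each bounded world a straight 20 m training route runs
from the centre; the route memory is 200 views stored every 0.1 m facing
along the route.  Heading recovery is tested from 17 positions spaced 1 m
along transects parallel to the route, at nine displacement distances
(0.5-34 m) on both sides: 306 test locations per route, and with 8 routes
radiating at 45 deg steps, 2448 per world.  Eye sweeps cross 10 fields of
view (36-360 deg) with 10 resolutions (2-1024 azimuthal pixels); the
subfield experiment fixes a 300 deg field at 5 deg/pixel and varies the
number of independently matched sectors from 1 to 6.

``reference_study`` runs a deliberately desk-scale subset of the protocol
(one world per type, 2 routes, 5 transect positions, a coarse eye grid) that
preserves the study's qualitative structure while fitting in minutes on one
CPU; problem sizes are documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .eye import EyeModel, subsample, trim_fov
from .navigation import (
    RouteMemory,
    directional_error,
    recover_heading,
    sector_headings,
)
from .render import PanoramicImage, Viewpoint, render_panorama
from .worldgen import World, WorldConfig, generate_world

__all__ = [
    "DISPLACEMENTS",
    "RouteSpec",
    "SweepConfig",
    "RenderCache",
    "build_route_memory",
    "build_test_grid",
    "run_sweep",
    "run_sector_experiment",
    "aggregate",
    "reference_study",
]

log = logging.getLogger("panonav")

#: Lateral displacement distances of the test transects, metres.
DISPLACEMENTS = (0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 13.0, 21.0, 34.0)

#: Default eye grids: 10 fields of view x 10 resolutions.
DEFAULT_FOVS = tuple(range(36, 361, 36))
DEFAULT_PXS = tuple(2**n for n in range(1, 11))


@dataclass(frozen=True)
class RouteSpec:
    """A straight training route sampled half-open: positions i*spacing for
    i = 0..n-1 (start included, endpoint excluded), giving 200 stored views
    for the default 20 m / 0.1 m."""

    direction: float
    origin: tuple[float, float] = (0.0, 0.0)
    length: float = 20.0
    spacing: float = 0.1

    @property
    def n_views(self) -> int:
        return int(round(self.length / self.spacing))

    @property
    def unit(self) -> np.ndarray:
        d = np.radians(self.direction)
        return np.array([np.cos(d), np.sin(d)])

    def positions(self) -> np.ndarray:
        """(n_views, 2) sample points along the route."""
        along = np.arange(self.n_views) * self.spacing
        return np.asarray(self.origin)[None, :] + along[:, None] * self.unit[None, :]

    def point(self, along: float, offset: float = 0.0) -> np.ndarray:
        """World point ``along`` metres down-route, ``offset`` to the left."""
        perp = np.array([-self.unit[1], self.unit[0]])
        return np.asarray(self.origin) + along * self.unit + offset * perp


@dataclass(frozen=True)
class SweepConfig:
    """Parameters of the full factorial experiment."""

    fov_list: tuple = DEFAULT_FOVS
    px_list: tuple = DEFAULT_PXS
    world_types: tuple = ("tussocks_only", "trees_only", "trees_and_tussocks")
    replicates_per_type: int = 2
    routes_per_world: int = 8
    distances: tuple = DISPLACEMENTS
    transect_positions: int = 17
    transect_spacing: float = 1.0
    sector_counts: tuple = (1, 2, 3, 4, 5, 6)
    sector_px: int = 72
    sector_fov: float = 300.0
    eye_height: float = 0.02
    supersample: int = 4
    rng_seed: int = 0
    #: Optional reduction multiplier for desk-scale runs: keeps evenly
    #: strided subsets of the condition lists (at least 2 routes, 2
    #: distances and 4 transect positions), so a scaled run's records are a
    #: strict subset of the full run's.
    scale_factor: float = 1.0

    def validate(self) -> None:
        for px in list(self.px_list) + [self.sector_px]:
            if px < 2 or px % 2:
                raise ValueError(f"azimuthal pixel counts must be even and >= 2, got {px}")
        for fov in list(self.fov_list) + [self.sector_fov]:
            if not 36 <= fov <= 360:
                raise ValueError(f"fields of view must lie in [36, 360] deg, got {fov}")
        for n in self.sector_counts:
            if not 1 <= n <= 6:
                raise ValueError(f"sector counts must lie in 1..6, got {n}")
        if self.routes_per_world < 1 or self.transect_positions < 1:
            raise ValueError("routes_per_world and transect_positions must be >= 1")
        if not 0.0 < self.scale_factor <= 1.0:
            raise ValueError("scale_factor must lie in (0, 1]")

    def route_directions(self) -> tuple:
        step = 360.0 / self.routes_per_world
        directions = tuple(i * step for i in range(self.routes_per_world))
        return _stride_subset(directions, self.scale_factor, minimum=2)

    def scaled_eye_grid(self) -> tuple[tuple, tuple]:
        return (
            _stride_subset(self.fov_list, self.scale_factor, minimum=1),
            _stride_subset(self.px_list, self.scale_factor, minimum=1),
        )

    def world_configs(self) -> list[WorldConfig]:
        ss = np.random.SeedSequence(self.rng_seed)
        seeds = [int(s) for s in ss.generate_state(
            len(self.world_types) * self.replicates_per_type, dtype=np.uint32
        ) >> np.uint32(1)]
        cfgs = []
        i = 0
        for wt in self.world_types:
            for _ in range(self.replicates_per_type):
                cfgs.append(WorldConfig(world_type=wt, rng_seed=seeds[i]))
                i += 1
        return cfgs


def _stride_subset(values, factor: float, minimum: int) -> tuple:
    """An evenly strided subset of ``values`` (kept in order), never fewer
    than ``minimum`` entries; factor 1 returns everything."""
    values = tuple(values)
    if factor >= 1.0:
        return values
    m = min(len(values), max(minimum, int(np.ceil(len(values) * factor))))
    idx = np.unique(np.round(np.linspace(0, len(values) - 1, m)).astype(int))
    return tuple(values[i] for i in idx)


def _scale_grid(grid: pd.DataFrame, config: "SweepConfig") -> pd.DataFrame:
    """Subset a test grid per ``config.scale_factor``: strided distances
    (min 2) and along-route positions (min 4), preserving coordinates."""
    if config.scale_factor >= 1.0:
        return grid
    keep_d = _stride_subset(sorted(grid.displacement_m.unique()), config.scale_factor, 2)
    keep_a = _stride_subset(sorted(grid.along_m.unique()), config.scale_factor, 4)
    sel = grid[grid.displacement_m.isin(keep_d) & grid.along_m.isin(keep_a)]
    return sel.reset_index(drop=True)


class RenderCache:
    """Memoises base-resolution panoramas per (world, pose).

    The study renders every pose once at the base specification and derives
    all eye conditions from that image, so the cache is what lets sweeps over
    many eyes reuse the expensive ray casting.  Pixels are kept as float32
    (grey levels are exact multiples of 1/16, so no precision is lost).
    """

    def __init__(self, eye_height: float = 0.02, supersample: int = 4):
        self.eye_height = eye_height
        self.supersample = supersample
        self._store: dict = {}
        self.misses = 0

    def base(self, world: World, x: float, y: float, heading: float) -> PanoramicImage:
        key = (id(world), round(float(x), 9), round(float(y), 9), round(float(heading), 9))
        px = self._store.get(key)
        if px is None:
            self.misses += 1
            img = render_panorama(
                world,
                Viewpoint(x, y, eye_height=self.eye_height, heading=heading),
                supersample=self.supersample,
            )
            px = img.pixels.astype(np.float32)
            self._store[key] = px
        return PanoramicImage(pixels=px.astype(float), centre_heading=float(heading) % 360.0)

    def clear(self) -> None:
        self._store.clear()


def build_route_memory(
    world: World,
    route: RouteSpec,
    eye: EyeModel,
    cache: RenderCache | None = None,
) -> RouteMemory:
    """Render and store the training views along ``route`` for ``eye``."""
    pos = route.positions()
    radius = np.linalg.norm(pos, axis=1).max()
    if radius > world.config.arena_radius + 1e-9:
        raise ValueError(
            f"route extends to {radius:.1f} m, outside the {world.config.arena_radius} m arena"
        )
    cache = cache or RenderCache()
    views = []
    for x, y in pos:
        base = cache.base(world, x, y, route.direction)
        views.append(trim_fov(subsample(base, eye)).pixels)
    headings = np.full(len(views), route.direction % 360.0)
    return RouteMemory(np.asarray(views), headings, eye)


def build_test_grid(
    route: RouteSpec,
    distances: tuple = DISPLACEMENTS,
    n_positions: int = 17,
    spacing: float = 1.0,
) -> pd.DataFrame:
    """Test locations on transects parallel to the route, both sides.

    Positions are centred on the route's own span (for the defaults: 17
    points at 1 m spacing lie 2..18 m along-route), at each displacement
    distance on the left (+) and right (-) of the route: 306 locations for
    the default protocol.
    """
    start = (route.length - (n_positions - 1) * spacing) / 2.0
    along = start + spacing * np.arange(n_positions)
    rows = []
    for dist in distances:
        for side_name, sign in (("left", 1.0), ("right", -1.0)):
            for a in along:
                x, y = route.point(a, sign * dist)
                rows.append(
                    {
                        "x": x,
                        "y": y,
                        "along_m": a,
                        "displacement_m": dist,
                        "side": side_name,
                    }
                )
    return pd.DataFrame(rows)


def _recover_records(
    world_id, world, route_id, route, grid, memories, cache, ratio="median_over_min"
):
    """Shared inner loop: one record per (test location, memory condition).

    ``memories`` is a list of (condition dict, RouteMemory, n_sectors).
    """
    rows = []
    for loc in grid.itertuples(index=False):
        base = cache.base(world, loc.x, loc.y, route.direction)
        subsampled: dict[int, object] = {}
        for cond, memory, n_sectors in memories:
            eye = memory.eye
            cur = subsampled.get(eye.az_pixels_full)
            if cur is None:
                cur = subsample(base, eye)
                subsampled[eye.az_pixels_full] = cur
            if n_sectors == 1:
                est = recover_heading(cur, memory, ratio=ratio)
            else:
                est = sector_headings(cur, memory, n_sectors, ratio=ratio)
            rows.append(
                {
                    "world_id": world_id,
                    "world_type": world.config.world_type,
                    "route_id": route_id,
                    "route_direction": route.direction,
                    "x": loc.x,
                    "y": loc.y,
                    "along_m": loc.along_m,
                    "displacement_m": loc.displacement_m,
                    "side": loc.side,
                    **cond,
                    "heading": est.heading,
                    "directional_error": directional_error(est.heading, route.direction),
                    "min_value": est.min_value,
                    "signal_strength": est.signal_strength,
                    "best_memory_index": est.best_memory_index,
                }
            )
    return rows


def _checkpointed(checkpoint_dir, tag, compute):
    if checkpoint_dir is None:
        return pd.DataFrame(compute())
    path = Path(checkpoint_dir) / f"{tag}.csv"
    if path.exists():
        log.info("[sweep] resuming %s from checkpoint", tag)
        return pd.read_csv(path)
    df = pd.DataFrame(compute())
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def run_sweep(
    worlds: list[World],
    config: SweepConfig = SweepConfig(),
    cache: RenderCache | None = None,
    grid: pd.DataFrame | None = None,
    checkpoint_dir=None,
) -> pd.DataFrame:
    """FOV x resolution sweep: one record per (world, route, location, eye)."""
    config.validate()
    fovs, pxs = config.scaled_eye_grid()
    parts = []
    for wi, world in enumerate(worlds):
        wcache = cache or RenderCache(config.eye_height, config.supersample)
        for ri, direction in enumerate(config.route_directions()):
            route = RouteSpec(direction=direction)
            g = (
                build_test_grid(
                    route, config.distances, config.transect_positions, config.transect_spacing
                )
                if grid is None
                else grid
            )
            g = _scale_grid(g, config)

            def compute(world=world, wi=wi, ri=ri, route=route, g=g, wcache=wcache):
                log.info("[sweep] world %d route %d (%g deg)", wi, ri, route.direction)
                memories = []
                for fov in fovs:
                    for px in pxs:
                        eye = EyeModel(px, fov)
                        memories.append(
                            (
                                {"fov": fov, "px": px, "n_sectors": 1},
                                build_route_memory(world, route, eye, wcache),
                                1,
                            )
                        )
                return _recover_records(wi, world, ri, route, g, memories, wcache)

            parts.append(_checkpointed(checkpoint_dir, f"sweep_w{wi}_r{ri}", compute))
        if cache is None:
            wcache.clear()
    return pd.concat(parts, ignore_index=True)


def run_sector_experiment(
    worlds: list[World],
    config: SweepConfig = SweepConfig(),
    cache: RenderCache | None = None,
    grid: pd.DataFrame | None = None,
    checkpoint_dir=None,
) -> pd.DataFrame:
    """Subfield experiment at the ant-like eye (300 deg FOV, 5 deg/pixel)."""
    config.validate()
    eye = EyeModel(config.sector_px, config.sector_fov)
    parts = []
    for wi, world in enumerate(worlds):
        wcache = cache or RenderCache(config.eye_height, config.supersample)
        for ri, direction in enumerate(config.route_directions()):
            route = RouteSpec(direction=direction)
            g = (
                build_test_grid(
                    route, config.distances, config.transect_positions, config.transect_spacing
                )
                if grid is None
                else grid
            )
            g = _scale_grid(g, config)

            def compute(world=world, wi=wi, ri=ri, route=route, g=g, wcache=wcache):
                log.info("[sectors] world %d route %d", wi, ri)
                memory = build_route_memory(world, route, eye, wcache)
                memories = [
                    (
                        {"fov": config.sector_fov, "px": config.sector_px, "n_sectors": n},
                        memory,
                        n,
                    )
                    for n in config.sector_counts
                ]
                return _recover_records(wi, world, ri, route, g, memories, wcache)

            parts.append(_checkpointed(checkpoint_dir, f"sectors_w{wi}_r{ri}", compute))
        if cache is None:
            wcache.clear()
    return pd.concat(parts, ignore_index=True)


def aggregate(
    records: pd.DataFrame,
    by,
    value: str = "directional_error",
    ci: str = "normal",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group means with 95% confidence intervals.

    ``ci="normal"`` uses mean +- 1.96 SEM; ``ci="bootstrap"`` a percentile
    bootstrap.  Groups with fewer than two records get NaN interval bounds
    and ``ci_defined=False``.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    by = [by] if isinstance(by, str) else list(by)
    rng = np.random.default_rng(seed)
    rows = []
    for key, grp in records.groupby(by, sort=True):
        vals = grp[value].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update({"mean": mean, "n": n, "ci_defined": n >= 2})
        if n < 2:
            row.update({"sem": np.nan, "ci_low": np.nan, "ci_high": np.nan})
        elif ci == "normal":
            sem = float(vals.std(ddof=1) / np.sqrt(n))
            row.update({"sem": sem, "ci_low": mean - 1.96 * sem, "ci_high": mean + 1.96 * sem})
        elif ci == "bootstrap":
            means = rng.choice(vals, size=(n_boot, n), replace=True).mean(axis=1)
            row.update(
                {
                    "sem": float(vals.std(ddof=1) / np.sqrt(n)),
                    "ci_low": float(np.percentile(means, 2.5)),
                    "ci_high": float(np.percentile(means, 97.5)),
                }
            )
        else:
            raise ValueError(f"unknown ci method {ci!r}")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Desk-scale reference study
# ---------------------------------------------------------------------------

#: Scaled-down conditions: these preserve the protocol's structure (one world
#: per type, two routes, five transect positions both sides) at sizes that
#: run in minutes.
REFERENCE_ROUTE_DIRECTIONS = (0.0, 90.0)
REFERENCE_DISTANCES = (0.5, 2.0, 8.0, 21.0)
REFERENCE_ALONG = (2.0, 6.0, 10.0, 14.0, 18.0)
REFERENCE_FOVS = (72, 216, 360)
REFERENCE_PXS = (8, 64, 512)
REFERENCE_FOV_PX_DISTANCE = 8.0
#: The subfield comparison targets displacements where whole-field error is
#: intermediate (between its near-route ceiling and the chance floor).
REFERENCE_SECTOR_DISTANCES = (8.0, 21.0)


def _grid_subset(route: RouteSpec, distances, along) -> pd.DataFrame:
    full = build_test_grid(route)
    sel = full[full.displacement_m.isin(distances) & full.along_m.isin(along)]
    return sel.reset_index(drop=True)


def reference_study(seed: int = 0, progress: bool = True) -> dict[str, pd.DataFrame]:
    """Run the desk-scale study; returns records per sub-experiment.

    Keys: "distance" (full-resolution 360 deg eye across displacement
    distances), "fov_px" (coarse eye grid at 8 m), "sectors" (1-6 subfields
    at 300 deg / 5 deg per pixel in the trees-only world, intermediate
    distances).  All three share one render cache per world, so every pose is
    ray-cast once.
    """
    ss = np.random.SeedSequence(seed)
    world_seeds = [int(s) for s in ss.generate_state(3, dtype=np.uint32) >> np.uint32(1)]
    worlds = [
        generate_world(WorldConfig(world_type=wt, rng_seed=s))
        for wt, s in zip(("tussocks_only", "trees_only", "trees_and_tussocks"), world_seeds)
    ]
    eye_hi = EyeModel(1024, 360.0)
    eye_sector = EyeModel(72, 300.0)
    out: dict[str, list] = {"distance": [], "fov_px": [], "sectors": []}

    for wi, world in enumerate(worlds):
        cache = RenderCache()
        for ri, direction in enumerate(REFERENCE_ROUTE_DIRECTIONS):
            route = RouteSpec(direction=direction)
            if progress:
                log.info("[study] world %s route %g deg", world.config.world_type, direction)
            grid5 = _grid_subset(route, REFERENCE_DISTANCES, REFERENCE_ALONG)

            mem_hi = build_route_memory(world, route, eye_hi, cache)
            out["distance"] += _recover_records(
                wi, world, ri, route, grid5,
                [({"fov": 360, "px": 1024, "n_sectors": 1}, mem_hi, 1)],
                cache,
            )
            del mem_hi  # free the spectral precompute before the next condition

            # full 17-position transects at one distance: the eye-grid
            # orderings are subtle, so this sub-experiment gets the most
            # replication per rendered pose
            grid_fp = build_test_grid(route, (REFERENCE_FOV_PX_DISTANCE,), 17)
            memories = [
                (
                    {"fov": fov, "px": px, "n_sectors": 1},
                    build_route_memory(world, route, EyeModel(px, fov), cache),
                    1,
                )
                for fov in REFERENCE_FOVS
                for px in REFERENCE_PXS
            ]
            out["fov_px"] += _recover_records(wi, world, ri, route, grid_fp, memories, cache)
            del memories

            if world.config.world_type == "trees_only":
                grid_sec = grid5[
                    grid5.displacement_m.isin(REFERENCE_SECTOR_DISTANCES)
                ].reset_index(drop=True)
                mem_sec = build_route_memory(world, route, eye_sector, cache)
                sector_mems = [
                    ({"fov": 300.0, "px": 72, "n_sectors": n}, mem_sec, n)
                    for n in (1, 2, 3, 4, 5, 6)
                ]
                out["sectors"] += _recover_records(
                    wi, world, ri, route, grid_sec, sector_mems, cache
                )
        cache.clear()

    return {k: pd.DataFrame(v) for k, v in out.items()}
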