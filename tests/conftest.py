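"""Shared fixtures: tiny hand-built worlds and toy view factories."""

from __future__ import annotations

import numpy as np
import pytest

from panonav.eye import EyeModel, SampledView
from panonav.worldgen import SceneObject, World, WorldConfig, generate_world, make_tussock


def world_from_triangles(triangles, kind: str = "tussock", **cfg_kw) -> World:
    """Wrap raw triangles (n, 3, 3) into a World for rendering tests."""
    cfg = WorldConfig(**cfg_kw)
    tri = np.asarray(triangles, dtype=float)
    obj = SceneObject(kind=kind, triangles=tri, anchor=(0.0, 0.0))
    return World(objects=(obj,), config=cfg)


def wall(az0_deg: float, az1_deg: float, radius: float = 5.0, height: float = 50.0):
    """Two triangles forming a tall vertical quad between two azimuths."""
    a0, a1 = np.radians([az0_deg, az1_deg])
    p0 = np.array([radius * np.cos(a0), radius * np.sin(a0)])
    p1 = np.array([radius * np.cos(a1), radius * np.sin(a1)])
    quad = [
        [[*p0, 0.0], [*p1, 0.0], [*p1, height]],
        [[*p0, 0.0], [*p1, height], [*p0, height]],
    ]
    return np.asarray(quad)


def lattice_view(rng, h, w, eye: EyeModel, heading: float = 0.0) -> SampledView:
    """Random toy view with supersample-lattice grey values (k/16)."""
    px = rng.integers(0, 17, size=(h, w)) / 16.0
    return SampledView(pixels=px, eye=eye, centre_heading=heading)


@pytest.fixture(scope="session")
def empty_world() -> World:
    return World(objects=(), config=WorldConfig(world_type="tussocks_only", tussock_density=0.0))


@pytest.fixture(scope="session")
def sparse_world() -> World:
    """A small generated world (few objects) for render-level tests."""
    cfg = WorldConfig(
        world_type="trees_and_tussocks",
        arena_radius=20.0,
        tussock_density=0.004,
        tree_count=2,
        tree_ring=(22.0, 30.0),
        rng_seed=11,
    )
    return generate_world(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
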