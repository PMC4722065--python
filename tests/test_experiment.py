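"""Routes, displacement grids, sweeps and aggregation."""

import numpy as np
import pandas as pd
import pytest

from panonav.experiment import (
    DISPLACEMENTS,
    RenderCache,
    RouteSpec,
    SweepConfig,
    aggregate,
    build_route_memory,
    build_test_grid,
    run_sector_experiment,
    run_sweep,
)
from panonav.eye import EyeModel, subsample
from panonav.navigation import recover_heading
from panonav.worldgen import SceneObject, World, WorldConfig, make_tussock

import conftest


def tiny_world(n_tussocks=3, seed=5) -> World:
    cfg = WorldConfig(world_type="tussocks_only", rng_seed=seed)
    rng = np.random.default_rng(seed)
    objs = tuple(
        make_tussock(rng.uniform(-15, 15, size=2), rng, cfg) for _ in range(n_tussocks)
    )
    return World(objects=objs, config=cfg)


def test_route_spec_samples_half_open():
    route = RouteSpec(direction=0.0)
    assert route.n_views == 200
    pos = route.positions()
    assert pos.shape == (200, 2)
    np.testing.assert_allclose(pos[0], [0.0, 0.0])
    np.testing.assert_allclose(pos[-1], [19.9, 0.0])   # 20 m endpoint excluded


def test_test_grid_counts_and_distances():
    route = RouteSpec(direction=30.0)
    grid = build_test_grid(route)
    assert len(grid) == 306                      # 17 x 9 x 2
    assert len(grid) * 8 == 2448                 # per world with 8 routes
    # perpendicular distance of every location to the route line
    u = route.unit
    rel = grid[["x", "y"]].to_numpy() - np.asarray(route.origin)
    perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    np.testing.assert_allclose(np.sort(np.unique(perp.round(9))), DISPLACEMENTS)
    # transect positions are centred on the route span: 2..18 m along-route
    along = np.unique(grid.along_m)
    np.testing.assert_allclose(along, np.arange(2.0, 19.0))


def test_test_grid_rotates_with_the_route():
    g0 = build_test_grid(RouteSpec(direction=0.0))
    g90 = build_test_grid(RouteSpec(direction=90.0))
    rot = np.stack([-g0.y.to_numpy(), g0.x.to_numpy()], axis=1)
    np.testing.assert_allclose(rot, g90[["x", "y"]].to_numpy(), atol=1e-9)


def test_route_memory_has_two_hundred_aligned_views(empty_world):
    eye = EyeModel(8, 360.0)
    mem = build_route_memory(empty_world, RouteSpec(direction=45.0), eye)
    assert len(mem) == 200
    assert (mem.headings == 45.0).all()
    assert mem.views.shape == (200, eye.el_pixels, 8)
    assert (mem.views == 1.0).all()   # empty world: pure sky


def test_route_must_fit_inside_the_arena(empty_world):
    small = World(objects=(), config=WorldConfig(arena_radius=10.0, tree_ring=(12.0, 15.0)))
    with pytest.raises(ValueError):
        build_route_memory(small, RouteSpec(direction=0.0), EyeModel(8))


def test_aggregate_means_and_confidence_intervals():
    df = pd.DataFrame(
        {"g": ["a"] * 4 + ["b"] + ["c"] * 3,
         "directional_error": [10.0, 20.0, 30.0, 40.0, 7.0, 5.0, 5.0, 5.0]}
    )
    agg = aggregate(df, "g").set_index("g")
    assert agg.loc["a", "mean"] == 25.0
    assert agg.loc["a", "sem"] == pytest.approx(6.455, abs=1e-3)
    assert agg.loc["a", "ci_low"] == pytest.approx(25.0 - 1.96 * 6.455, abs=1e-2)
    assert not agg.loc["b", "ci_defined"]
    assert np.isnan(agg.loc["b", "ci_low"])
    assert agg.loc["c", "sem"] == 0.0                   # constant group
    assert agg.loc["c", "ci_low"] == agg.loc["c", "ci_high"]
    boot = aggregate(df, "g", ci="bootstrap", n_boot=200).set_index("g")
    assert boot.loc["a", "ci_low"] <= 25.0 <= boot.loc["a", "ci_high"]
    with pytest.raises(ValueError):
        aggregate(df.iloc[:0], "g")


def test_sweep_config_validation():
    SweepConfig().validate()
    with pytest.raises(ValueError):
        SweepConfig(px_list=(3,)).validate()
    with pytest.raises(ValueError):
        SweepConfig(fov_list=(400,)).validate()
    with pytest.raises(ValueError):
        SweepConfig(sector_counts=(7,)).validate()
    assert len(SweepConfig().fov_list) == 10
    assert len(SweepConfig().px_list) == 10
    assert SweepConfig().route_directions() == tuple(range(0, 360, 45))
    cfgs = SweepConfig().world_configs()
    assert len(cfgs) == 6 and all(c.rng_seed < 2**31 for c in cfgs)


@pytest.fixture(scope="module")
def tiny_sweep():
    world = tiny_world()
    cfg = SweepConfig(
        fov_list=(360,), px_list=(8,), routes_per_world=1,
        distances=(0.5, 2.0), transect_positions=2,
    )
    route = RouteSpec(direction=0.0)
    grid = build_test_grid(route, cfg.distances, cfg.transect_positions)
    records = run_sweep([world], cfg, grid=grid)
    return world, cfg, grid, records


def test_run_sweep_schema_and_determinism(tiny_sweep):
    world, cfg, grid, records = tiny_sweep
    assert len(records) == len(grid)
    assert records.directional_error.between(0, 180).all()
    assert {"world_type", "fov", "px", "signal_strength", "heading"} <= set(records.columns)
    again = run_sweep([world], cfg, grid=grid)
    pd.testing.assert_frame_equal(records, again)


def test_run_sweep_checkpoint_resume(tiny_sweep, tmp_path):
    world, cfg, grid, records = tiny_sweep
    first = run_sweep([world], cfg, grid=grid, checkpoint_dir=tmp_path)
    assert (tmp_path / "sweep_w0_r0.csv").exists()
    resumed = run_sweep([world], cfg, grid=grid, checkpoint_dir=tmp_path)
    pd.testing.assert_frame_equal(first, resumed)
    np.testing.assert_allclose(
        resumed.directional_error.to_numpy(), records.directional_error.to_numpy()
    )


def test_recovery_is_invariant_to_test_facing(tiny_sweep):
    """The current view's rendering direction cancels out of the estimate
    because recovery searches all rotations."""
    world, cfg, grid, records = tiny_sweep
    cache = RenderCache()
    eye = EyeModel(8, 360.0)
    mem = build_route_memory(world, RouteSpec(direction=0.0), eye, cache)
    x, y = grid.loc[0, "x"], grid.loc[0, "y"]
    est0 = recover_heading(subsample(cache.base(world, x, y, 0.0), eye), mem)
    est90 = recover_heading(subsample(cache.base(world, x, y, 90.0), eye), mem)
    assert est90.heading == pytest.approx(est0.heading)
    assert est90.min_value == pytest.approx(est0.min_value, abs=1e-9)


def test_scaled_run_is_a_strict_subset_of_the_full_run():
    """scale_factor keeps evenly strided conditions (>=2 routes, >=2
    distances, >=4 transect positions) and reproduces exactly the matching
    records of the full run."""
    world = tiny_world(2)
    base = SweepConfig(
        fov_list=(360,), px_list=(8,), routes_per_world=4,
        distances=(0.5, 2.0, 5.0), transect_positions=8,
    )
    full = run_sweep([world], base)
    scaled_cfg = SweepConfig(**{**base.__dict__, "scale_factor": 0.5})
    assert len(scaled_cfg.route_directions()) >= 2
    scaled = run_sweep([world], scaled_cfg)
    assert 0 < len(scaled) < len(full)
    keys = ["route_direction", "x", "y", "fov", "px"]
    merged = scaled.merge(full, on=keys, suffixes=("_s", "_f"))
    assert len(merged) == len(scaled)          # every scaled record exists in full
    np.testing.assert_array_equal(
        merged.directional_error_s.to_numpy(), merged.directional_error_f.to_numpy()
    )
    assert scaled.displacement_m.nunique() >= 2
    assert scaled.along_m.nunique() >= 4


def test_sector_experiment_covers_all_counts():
    world = tiny_world(2)
    cfg = SweepConfig(routes_per_world=1, sector_px=72, sector_fov=300.0)
    route = RouteSpec(direction=0.0)
    grid = build_test_grid(route, (2.0,), 2)
    records = run_sector_experiment([world], cfg, grid=grid)
    assert sorted(records.n_sectors.unique()) == [1, 2, 3, 4, 5, 6]
    assert len(records) == 6 * len(grid)
    # single-sector records coincide with plain whole-field recovery
    cache = RenderCache()
    mem = build_route_memory(world, route, EyeModel(72, 300.0), cache)
    one = records[records.n_sectors == 1].reset_index(drop=True)
    for i, row in one.iterrows():
        est = recover_heading(subsample(cache.base(world, row.x, row.y, 0.0), mem.eye), mem)
        assert row.heading == est.heading
        assert row.min_value == est.min_value
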