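"""Heading recovery: rIDF correctness, perfect memory, signal, sectors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panonav.eye import EyeModel, SampledView, rotate_view, subsample, trim_fov
from panonav.navigation import (
    PerfectMemoryNavigator,
    RouteMemory,
    circular_mean_deg,
    directional_error,
    image_difference,
    recover_heading,
    ridf,
    sector_headings,
    signal_strength,
)
from panonav.ridf import RIDFMatcher

from conftest import lattice_view
from oracles import naive_recover, naive_ridf


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def test_image_difference_examples():
    assert image_difference(np.zeros((3, 4)), np.zeros((3, 4))) == 0.0
    assert image_difference(np.zeros((5, 5)), np.ones((5, 5))) == 1.0
    I = np.array([[0.0, 0.5], [1.0, 1.0]])
    J = np.array([[1.0, 0.5], [0.0, 1.0]])
    assert image_difference(I, J) == 0.5
    with pytest.raises(ValueError):
        image_difference(np.zeros((2, 2)), np.zeros((2, 3)))


@given(
    a=st.lists(st.floats(0, 1), min_size=6, max_size=6),
    b=st.lists(st.floats(0, 1), min_size=6, max_size=6),
    c=st.lists(st.floats(0, 1), min_size=6, max_size=6),
)
@settings(deadline=None, max_examples=50)
def test_image_difference_is_a_metric(a, b, c):
    A, B, C = (np.array(x).reshape(2, 3) for x in (a, b, c))
    assert image_difference(A, B) == image_difference(B, A)
    assert image_difference(A, C) <= image_difference(A, B) + image_difference(B, C) + 1e-12


@pytest.mark.parametrize(
    "est,true,err",
    [(90, 90, 0), (0, 180, 180), (350, 10, 20), (10, 350, 20), (-10, 10, 20)],
)
def test_directional_error_wraps(est, true, err):
    assert directional_error(est, true) == pytest.approx(err)


@given(a=st.floats(-720, 720), b=st.floats(-720, 720))
@settings(deadline=None, max_examples=100)
def test_directional_error_bounds_and_symmetry(a, b):
    e = directional_error(a, b)
    assert 0.0 <= e <= 180.0
    assert e == pytest.approx(directional_error(b, a))


def test_circular_mean_wraps_through_north():
    assert circular_mean_deg([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)
    assert circular_mean_deg([30.0, 30.0]) == pytest.approx(30.0)


def test_signal_strength_conventions():
    flat = [0.3, 0.3, 0.3, 0.3]
    assert signal_strength(flat) == 1.0
    vals = [0.1, 0.4, 0.5, 0.6]
    assert signal_strength(vals) == pytest.approx(4.5)
    assert signal_strength(vals, ratio="min_over_median") == pytest.approx(0.1 / 0.45)
    # stronger minimum, same median -> strictly larger ratio
    assert signal_strength([0.05, 0.4, 0.5, 0.6]) > signal_strength(vals)
    assert signal_strength([0.0, 0.4, 0.5, 0.6]) == np.inf
    with pytest.raises(ValueError):
        signal_strength([0.3])
    with pytest.raises(ValueError):
        signal_strength(vals, ratio="sideways")


# ---------------------------------------------------------------------------
# rIDF and perfect memory vs brute force
# ---------------------------------------------------------------------------


def toy_memory(rng, eye, n_mem):
    views = [lattice_view(rng, eye.el_pixels, eye.az_pixels_full, eye) for _ in range(n_mem)]
    trimmed = np.stack([trim_fov(v, eye).pixels for v in views])
    return RouteMemory(trimmed, np.zeros(n_mem), eye), views


def test_ridf_self_match_is_zero_at_zero_shift(rng):
    eye = EyeModel(8, 360.0)
    mem, views = toy_memory(rng, eye, 1)
    r = ridf(views[0], mem.views[0], eye)
    assert r.values[0] == 0.0
    assert r.best_shift == 0
    assert (r.values >= 0).all()
    assert len(r.values) == 8


def test_rotating_the_panorama_does_not_change_the_estimate(rng):
    eye = EyeModel(16, 360.0)
    mem, views = toy_memory(rng, eye, 3)
    cur = lattice_view(rng, eye.el_pixels, 16, eye)
    est = recover_heading(cur, mem)
    for p in (1, 5, 11):
        est_rot = recover_heading(rotate_view(cur, p), mem)
        assert est_rot.heading == pytest.approx(est.heading)
        assert est_rot.min_value == pytest.approx(est.min_value, abs=1e-12)
        assert est_rot.best_memory_index == est.best_memory_index


@pytest.mark.parametrize("strategy", ["direct", "fft"])
def test_ridf_matches_naive_double_loop(rng, strategy):
    for _ in range(25):
        n_mem = int(rng.integers(1, 6))
        n_az = int(rng.choice([8, 16]))
        h = int(rng.integers(1, 4))
        w = int(rng.choice([n_az, n_az // 2]))
        stored = rng.integers(0, 17, size=(n_mem, h, w)) / 16.0
        cur = rng.integers(0, 17, size=(h, n_az)) / 16.0
        c0 = (n_az - w) // 2
        got = RIDFMatcher(stored, n_az, c0, strategy=strategy).ridf_all(cur)
        np.testing.assert_allclose(got, naive_ridf(stored, cur, c0), atol=1e-12)


def test_recover_heading_matches_exhaustive_search(rng):
    for _ in range(25):
        eye = EyeModel(8, 360.0)
        n_mem = int(rng.integers(1, 6))
        mem, _ = toy_memory(rng, eye, n_mem)
        facing = float(rng.uniform(0, 360))
        cur = SampledView(
            pixels=rng.integers(0, 17, size=(eye.el_pixels, 8)) / 16.0,
            eye=eye,
            centre_heading=facing,
        )
        est = recover_heading(cur, mem)
        s, k, m = naive_recover(mem.views, cur.pixels, 0, eye.resolution)
        assert est.best_memory_index == s
        assert est.rotation_pixels == k
        assert est.min_value == pytest.approx(m, abs=1e-12)
        assert est.heading == pytest.approx((facing + k * eye.resolution) % 360.0)


def test_tie_breaking_prefers_smallest_rotation_then_earliest_view():
    eye = EyeModel(8, 360.0)
    # two identical uniform stored views: every (view, rotation) ties at 0
    views = np.full((2, 1, 8), 0.5)
    mem = RouteMemory(views, np.zeros(2), eye)
    cur = SampledView(pixels=np.full((1, 8), 0.5), eye=eye, centre_heading=0.0)
    est = recover_heading(cur, mem)
    assert est.rotation_pixels == 0
    assert est.best_memory_index == 0


def test_memory_validation_and_archive_round_trip(tmp_path, rng):
    eye = EyeModel(8, 360.0)
    with pytest.raises(ValueError):
        RouteMemory(np.empty((0, 2, 8)), np.empty(0), eye)
    with pytest.raises(ValueError):
        RouteMemory(np.zeros((2, 2, 8)), np.zeros(3), eye)
    with pytest.raises(ValueError):
        RouteMemory(np.zeros((2, 2, 5)), np.zeros(2), eye)
    mem, _ = toy_memory(rng, EyeModel(16, 180.0), 3)
    path = tmp_path / "memory.npz"
    mem.save(path)
    back = RouteMemory.load(path)
    assert back.eye == mem.eye
    np.testing.assert_array_equal(back.views, mem.views)
    np.testing.assert_array_equal(back.headings, mem.headings)


# ---------------------------------------------------------------------------
# sectors
# ---------------------------------------------------------------------------


def test_single_sector_equals_whole_field(rng):
    eye = EyeModel(72, 300.0)
    mem, _ = toy_memory(rng, eye, 4)
    cur = lattice_view(rng, eye.el_pixels, 72, eye, heading=33.0)
    assert sector_headings(cur, mem, 1) == recover_heading(cur, mem)


def test_sector_count_bounds_and_divisibility(rng):
    eye = EyeModel(72, 300.0)
    mem, _ = toy_memory(rng, eye, 2)
    cur = lattice_view(rng, eye.el_pixels, 72, eye)
    for bad in (0, 7):
        with pytest.raises(ValueError):
            sector_headings(cur, mem, bad)
    # 64-pixel FOV does not divide into 3 sectors
    eye2 = EyeModel(64, 360.0)
    mem2, _ = toy_memory(rng, eye2, 2)
    cur2 = lattice_view(rng, eye2.el_pixels, 64, eye2)
    with pytest.raises(ValueError):
        sector_headings(cur2, mem2, 3)


def test_sectors_recover_their_own_shifts(rng):
    """Each sector independently finds a perfect match of the unrotated view,
    so all sector headings agree and the circular mean preserves them."""
    eye = EyeModel(72, 300.0)
    mem, views = toy_memory(rng, eye, 1)
    cur = views[0]
    for n in (2, 3, 4, 6):
        est = sector_headings(cur, mem, n)
        assert est.min_value == pytest.approx(0.0, abs=1e-12)
        assert len(est.sector_headings_deg) == n
        assert est.heading == pytest.approx(cur.centre_heading % 360.0, abs=1e-9)


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------


def test_navigator_fit_predict_score(rng):
    from sklearn.base import clone

    eye = EyeModel(16, 360.0)
    train = [lattice_view(rng, eye.el_pixels, 16, eye, heading=0.0) for _ in range(3)]
    nav = PerfectMemoryNavigator(az_pixels_full=16, fov_degrees=360.0)
    nav.fit(train)
    assert len(nav.memory_) == 3
    # predicting on a training view recovers its own facing exactly
    pred = nav.predict([train[1]])
    assert pred[0] == pytest.approx(0.0)
    info = nav.predict_info([train[1]])
    assert info.loc[0, "min_value"] == 0.0
    assert set(info.columns) >= {"heading", "min_value", "signal_strength"}
    assert nav.score([train[0]], [0.0]) == pytest.approx(0.0)
    cloned = clone(nav)
    assert cloned.get_params()["az_pixels_full"] == 16
    with pytest.raises(RuntimeError):
        cloned.predict([train[0]])


def test_navigator_sector_parameter(rng):
    eye = EyeModel(72, 300.0)
    train = [lattice_view(rng, eye.el_pixels, 72, eye, heading=0.0) for _ in range(2)]
    nav = PerfectMemoryNavigator(az_pixels_full=72, fov_degrees=300.0, n_sectors=4).fit(train)
    assert nav.predict([train[0]])[0] == pytest.approx(0.0, abs=1e-9)


def test_chance_level_is_ninety_degrees():
    rng = np.random.default_rng(2024)
    err = directional_error(rng.uniform(0, 360, 100_000), rng.uniform(0, 360, 100_000))
    assert err.mean() == pytest.approx(90.0, abs=1.0)
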