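"""Geometry kernel against hand arithmetic and independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from remiforest.buffers import (
    BufferSpec,
    buffer_change,
    disc,
    overlap_weights,
    radii_sweep,
    ring_buffer_change,
)
from remiforest.types import RasterPair, ResidentGroup


def random_pair(rng, n=20, cell=30.0):
    return RasterPair(
        (rng.random((n, n)) < 0.5).astype(np.uint8),
        (rng.random((n, n)) < 0.5).astype(np.uint8),
        rng.uniform(0.0, 0.8, (n, n)),
        rng.uniform(0.0, 0.8, (n, n)),
        cell,
    )


def supersample_weights(cx, cy, r, cell, shape, threshold=0.005, k=100):
    """Subcell-counting oracle for fractional circle-cell overlap."""
    offs = (np.arange(k) + 0.5) / k
    out = {}
    for row in range(shape[0]):
        for col in range(shape[1]):
            X, Y = np.meshgrid((col + offs) * cell, (row + offs) * cell)
            f = ((X - cx) ** 2 + (Y - cy) ** 2 <= r * r).mean()
            if f >= threshold:
                out[(row, col)] = f
    return out


def brute_force_change(pair, rows, cols, w):
    k0 = pair.forest_t0[rows, cols]
    k1 = pair.forest_t1[rows, cols]
    return (w * k1).sum() / w.sum() - (w * k0).sum() / w.sum()


# --- overlap weights -------------------------------------------------------

def test_cell_fully_inside_circle_weighs_one():
    pair = random_pair(np.random.default_rng(0), n=10)
    rows, cols, w = overlap_weights(disc(150, 150, 100), pair)
    centre_cell = (4, 4)  # cell centred at (135, 135), well inside
    assert centre_cell in set(zip(rows, cols))
    assert w[list(zip(rows, cols)).index(centre_cell)] == 1.0


def test_tiny_overlap_below_half_percent_excluded():
    pair = random_pair(np.random.default_rng(1), n=10)
    # circle grazing a cell corner: overlap area ~0.4% of the cell
    cx, cy, r = 45.0, 45.0, 15.0
    rows, cols, w = overlap_weights(disc(cx, cy, r), pair)
    oracle = supersample_weights(cx, cy, r, 30.0, (10, 10))
    assert set(zip(rows, cols)) == set(oracle)
    for f in w:
        assert f >= 0.005


@pytest.mark.parametrize("trial", range(6))
def test_weights_match_supersampling_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    pair = random_pair(rng)
    cx, cy = rng.uniform(60, 540, 2)
    r = rng.uniform(35, 130)
    rows, cols, w = overlap_weights(disc(cx, cy, r), pair)
    oracle = supersample_weights(cx, cy, r, 30.0, (20, 20))
    got = dict(zip(zip(rows, cols), w))
    # allow threshold-boundary cells to differ between methods
    for key in set(got) | set(oracle):
        a, b = got.get(key, 0.0), oracle.get(key, 0.0)
        assert abs(a - b) < 1e-3


def test_buffer_outside_raster_warns_and_returns_empty():
    pair = random_pair(np.random.default_rng(2), n=5)
    with pytest.warns(UserWarning, match="outside"):
        rows, cols, w = overlap_weights(disc(10_000, 10_000, 50), pair)
    assert len(w) == 0


# --- change metrics --------------------------------------------------------

def test_hand_examples_two_by_two_grid():
    """ΔForest 0.25 for one extra forest cell of four; ΔEVI 0.2 when the
    forested mean moves from 0.5 to 0.7."""
    k0 = np.array([[1, 0], [0, 0]], np.uint8)
    k1 = np.array([[1, 1], [0, 0]], np.uint8)
    e0 = np.array([[0.5, 0.2], [0.2, 0.2]])
    e1 = np.array([[0.6, 0.8], [0.1, 0.1]])
    pair = RasterPair(k0, k1, e0, e1, 30.0)
    bc = buffer_change(pair, disc(30, 30, 500))
    assert bc.delta_forest == pytest.approx(0.25)
    assert bc.delta_evi == pytest.approx(0.2)


def test_metric_equals_brute_force_summation():
    rng = np.random.default_rng(7)
    for trial in range(10):
        pair = random_pair(rng)
        cx, cy = rng.uniform(100, 500, 2)
        r = rng.uniform(40, 150)
        spec = disc(cx, cy, r)
        rows, cols, w = overlap_weights(spec, pair)
        bc = buffer_change(pair, spec)
        assert bc.delta_forest == pytest.approx(
            brute_force_change(pair, rows, cols, w), abs=1e-12
        )


def test_delta_evi_undefined_without_forest():
    k = np.zeros((4, 4), np.uint8)
    pair = RasterPair(k, k, np.full((4, 4), 0.3), np.full((4, 4), 0.4), 30.0)
    bc = buffer_change(pair, disc(60, 60, 50))
    assert bc.delta_forest == 0.0
    assert bc.delta_evi is None


def test_missing_evi_cells_dropped_from_both_sides():
    k = np.ones((2, 2), np.uint8)
    e0 = np.array([[0.5, np.nan], [0.5, 0.5]])
    e1 = np.array([[0.7, 0.7], [np.nan, 0.7]])
    pair = RasterPair(k, k, e0, e1, 30.0)
    bc = buffer_change(pair, disc(30, 30, 500))
    assert bc.delta_evi == pytest.approx(0.2)


def test_antisymmetry_under_date_swap():
    rng = np.random.default_rng(8)
    pair = random_pair(rng)
    spec = disc(300, 310, 120)
    a = buffer_change(pair, spec).delta_forest
    b = buffer_change(pair.swapped(), spec).delta_forest
    assert a == pytest.approx(-b, abs=1e-15)


def test_translation_invariance():
    rng = np.random.default_rng(9)
    base = random_pair(rng)
    shift = (1234.5, -67.8)
    moved = RasterPair(
        base.forest_t0, base.forest_t1, base.evi_t0, base.evi_t1,
        base.cell_size, origin=shift,
    )
    a = buffer_change(base, disc(300, 300, 100)).delta_forest
    b = buffer_change(
        moved, disc(300 + shift[0], 300 + shift[1], 100)
    ).delta_forest
    assert a == pytest.approx(b, abs=1e-12)


# --- radii sweep -----------------------------------------------------------

def test_radii_sweep_has_eight_default_rows_per_household():
    pair = random_pair(np.random.default_rng(10), n=30)
    hh = pd.DataFrame(
        {"household_id": ["H1", "H2"], "x": [450.0, 430.0], "y": [450.0, 460.0]}
    )
    tab = radii_sweep(pair, hh)
    assert len(tab) == 16
    assert (tab.groupby("unit_id").size() == 8).all()


def test_uniform_raster_gives_equal_proportions_at_all_radii():
    k = np.ones((30, 30), np.uint8)
    pair = RasterPair(k, k, np.full((30, 30), 0.5), np.full((30, 30), 0.5), 30.0)
    hh = pd.DataFrame({"household_id": ["H1"], "x": [450.0], "y": [450.0]})
    tab = radii_sweep(pair, hh)
    assert np.allclose(tab["delta_forest"], 0.0)
    assert np.allclose(tab["delta_evi"], 0.0)


def test_duplicate_radii_rejected():
    pair = random_pair(np.random.default_rng(11))
    hh = pd.DataFrame({"household_id": ["H1"], "x": [300.0], "y": [300.0]})
    with pytest.raises(ValueError, match="duplicate"):
        radii_sweep(pair, hh, [50, 50])


def test_corner_household_warns_partial_coverage():
    pair = random_pair(np.random.default_rng(12))
    hh = pd.DataFrame({"household_id": ["H1"], "x": [5.0], "y": [5.0]})
    with pytest.warns(UserWarning, match="partial"):
        tab = radii_sweep(pair, hh, [100])
    assert tab["delta_forest"].notna().all()


# --- ring buffers ----------------------------------------------------------

def square_group(side=200.0, offset=(400.0, 400.0)):
    x0, y0 = offset
    poly = Polygon(
        [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    )
    return ResidentGroup("G1", "S", poly, ["H1"], 1000.0)


def test_ring_area_matches_minkowski_dilation():
    """0-100 m ring of a 200x200 m square has area 4*200*100 + pi*100^2."""
    n = 40
    k = np.ones((n, n), np.uint8)
    pair = RasterPair(k, k, np.full((n, n), 0.5), np.full((n, n), 0.5), 30.0)
    grp = square_group()
    tab = ring_buffer_change(pair, grp, rings=[(0.0, 100.0)])
    ring_weight = tab.loc[tab["label"] == "ring 0-100", "weight_sum"].iloc[0]
    analytic = 4 * 200.0 * 100.0 + np.pi * 100.0**2
    assert ring_weight * 30.0**2 == pytest.approx(analytic, rel=0.01)


def test_rings_are_disjoint_and_uniform_raster_flat():
    n = 50
    k = np.ones((n, n), np.uint8)
    pair = RasterPair(k, k, np.full((n, n), 0.4), np.full((n, n), 0.4), 30.0)
    grp = square_group(side=150.0, offset=(600.0, 600.0))
    tab = ring_buffer_change(pair, grp)
    assert set(tab["label"]) == {"within", "ring 0-100", "ring 100-200"}
    assert np.allclose(tab["delta_forest"], 0.0)
    # disjointness: summed ring weights do not exceed the union's area
    outer = grp.boundary.buffer(200.0, quad_segs=64)
    total = tab["weight_sum"].sum() * 30.0**2
    assert total <= outer.area * 1.01


def test_invalid_polygon_rejected():
    bow_tie = Polygon([(0, 0), (100, 100), (100, 0), (0, 100)])
    grp = ResidentGroup("G1", "S", bow_tie, [], 0.0)
    pair = random_pair(np.random.default_rng(13))
    with pytest.raises(ValueError, match="invalid"):
        ring_buffer_change(pair, grp)


def test_buffer_spec_validation():
    from shapely.geometry import Point

    with pytest.raises(ValueError):
        BufferSpec(Point(0, 0), outer=50.0, inner=60.0)
    with pytest.raises(ValueError):
        BufferSpec(Point(0, 0), outer=50.0, threshold=1.5)
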