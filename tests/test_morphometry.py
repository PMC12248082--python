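"""Morphometry: hand-computed values, brute-force oracles, invariances."""

from __future__ import annotations

import math

import numpy as np
import pytest
from shapely.geometry import LineString

from sacmorph.errors import DegenerateGeometryError
from sacmorph.morphometry import (
    classify_hypertrophic,
    count_branch_points,
    count_self_crossings,
    field_area_convex_hull,
    normalize_sholl,
    sholl_profile,
    soma_area,
    total_length,
)
from sacmorph.synth import ArborGenParams, gen_arbor
from sacmorph.types import DENDRITE, SOMA, Arbor, make_arbor

from conftest import chain_arbor, grid_arbor, rigid_transform, star_arbor


# ------------------------------------------------------------- total length

def test_total_length_collinear_chain():
    arbor = chain_arbor([(0, 0, 0)] + [(0, float(k), 0) for k in range(1, 10)])
    assert total_length(arbor) == pytest.approx(9.0)


def test_total_length_y_tree(y_tree):
    assert total_length(y_tree) == pytest.approx(10 + 2 * math.sqrt(125))


def test_total_length_invariant_to_node_relabelling(y_tree):
    relabeled = make_arbor([
        (10, -1, 0, 0, 0, 4.0, SOMA),
        (7, 10, 0, 10, 0, 0.4, DENDRITE),
        (99, 7, -5, 20, 0, 0.3, DENDRITE),
        (42, 7, 5, 20, 0, 0.3, DENDRITE),
    ])
    assert total_length(relabeled) == pytest.approx(total_length(y_tree))


# ------------------------------------------------------------ branch points

def test_branch_points_unbranched_path():
    arbor = chain_arbor([(0, 0, 0), (0, 5, 0), (0, 10, 0)])
    assert count_branch_points(arbor) == 0


def test_branch_points_perfect_binary_tree_depth3():
    # one primary dendrite carrying a depth-3 binary tree: 2^3 - 1 = 7 internal nodes
    nodes = [(1, -1, 0.0, 0.0, 0.0, 4.0, SOMA)]
    nid = 2
    frontier = []
    nodes.append((nid, 1, 0.0, 5.0, 0.0, 0.3, DENDRITE))
    frontier = [(nid, 0.0, 5.0)]
    nid += 1
    for depth in range(3):
        nxt = []
        for parent, x, y in frontier:
            for dx in (-1, 1):
                nx = x + dx * 8.0 / (2 ** depth)
                ny = y + 5.0
                nodes.append((nid, parent, nx, ny, 0.0, 0.3, DENDRITE))
                nxt.append((nid, nx, ny))
                nid += 1
        frontier = nxt
    arbor = make_arbor(nodes)
    assert count_branch_points(arbor) == 7


def test_soma_with_many_primaries_is_not_a_branch_point():
    assert count_branch_points(star_arbor(n_rays=5, length=10)) == 0


# --------------------------------------------------------------- field area

def test_field_area_square_and_triangle():
    def tips_arbor(tips):
        nodes = [(1, -1, 30.0, 30.0, 0.0, 4.0, SOMA)]
        for k, (x, y) in enumerate(tips, start=2):
            nodes.append((k, 1, float(x), float(y), 0.0, 0.3, DENDRITE))
        return make_arbor(nodes)

    square = tips_arbor([(0, 0), (100, 0), (100, 100), (0, 100)])
    assert field_area_convex_hull(square) == pytest.approx(10_000.0)
    triangle = tips_arbor([(0, 0), (100, 0), (0, 100)])
    assert field_area_convex_hull(triangle) == pytest.approx(5_000.0)
    with_interior = tips_arbor([(0, 0), (100, 0), (0, 100), (20, 20), (10, 30)])
    assert field_area_convex_hull(with_interior) == pytest.approx(5_000.0)


def test_field_area_collinear_is_degenerate():
    arbor = chain_arbor([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
    with pytest.raises(DegenerateGeometryError):
        field_area_convex_hull(arbor)


# -------------------------------------------------------------------- Sholl

def test_sholl_star_geometry_constant_four():
    profile = sholl_profile(star_arbor(n_rays=4, length=50), step=1.0)
    mask = (profile.radii >= 1) & (profile.radii <= 49)
    assert np.all(profile.intersections[mask] == 4)


def test_sholl_bifurcation_step():
    arbor = make_arbor([
        (1, -1, 0, 0, 0, 2.0, SOMA),
        (2, 1, 0, 5, 0, 0.3, DENDRITE),
        (3, 2, -3, 9, 0, 0.3, DENDRITE),   # |(-3, 9)| ~ 9.49
        (4, 2, 3, 9, 0, 0.3, DENDRITE),
    ])
    profile = sholl_profile(arbor, step=1.0)
    for r, n in zip(profile.radii, profile.intersections):
        expected = 1 if r <= 5 else 2
        assert n == expected, f"radius {r}"


def _sholl_oracle(arbor: Arbor, radii: np.ndarray) -> np.ndarray:
    """Walk every segment for every radius; endpoint at r counts as outside."""
    center = arbor.soma_center
    parent, child = arbor.dendrite_segments()
    out = []
    for r in radii:
        count = 0
        for p, c in zip(parent, child):
            dp = np.linalg.norm(arbor.xyz[p] - center)
            dc = np.linalg.norm(arbor.xyz[c] - center)
            if (dp < r) != (dc < r):
                count += 1
        out.append(count)
    return np.array(out)


def test_sholl_matches_bruteforce_on_random_arbors():
    rng = np.random.default_rng(11)
    for _ in range(20):
        params = ArborGenParams(
            n_primary=int(rng.integers(2, 5)), target_radius=20.0,
            branch_rate=0.06, step_len=2.0, radial_bias=0.7,
            z_jitter_sd=0.5, seed=int(rng.integers(2 ** 31)),
        )
        arbor = gen_arbor(params)
        assert arbor.n_nodes <= 200
        profile = sholl_profile(arbor, step=1.0)
        np.testing.assert_array_equal(profile.intersections,
                                      _sholl_oracle(arbor, profile.radii))


def test_normalize_sholl_constant_and_deciles():
    radii = np.arange(1.0, 101.0)
    assert np.allclose(normalize_sholl(radii, np.full(100, 4.0), 100.0), 4.0)
    bins = normalize_sholl(radii, radii.copy(), 100.0)
    assert np.allclose(bins, np.arange(5.5, 100, 10.0))


def test_normalize_sholl_scale_invariance():
    radii_a = np.arange(1.0, 51.0)
    profile = np.sin(radii_a / 7.0) ** 2 * 10
    radii_b = radii_a * 2.0  # same profile stretched to twice the extent
    bins_a = normalize_sholl(radii_a, profile, 50.0)
    bins_b = normalize_sholl(radii_b, profile, 100.0)
    assert np.allclose(bins_a, bins_b)


# ----------------------------------------------------------- self-crossings

def test_crossing_x_in_plane_and_out_of_plane():
    def x_arbor(z2: float) -> Arbor:
        return make_arbor([
            (1, -1, -5, 0, 0, 1.0, SOMA),
            (2, 1, 0, -1, 0, 0.3, DENDRITE),
            (3, 2, 2, 1, 0, 0.3, DENDRITE),
            (4, 1, 0, 1, z2, 0.3, DENDRITE),
            (5, 4, 2, -1, z2, 0.3, DENDRITE),
        ])

    assert count_self_crossings(x_arbor(0.0), z_tol=0.5) == 1
    assert count_self_crossings(x_arbor(5.0), z_tol=0.5) == 0


@pytest.mark.parametrize("m,n", [(1, 1), (3, 4), (5, 7)])
def test_crossing_grid_closed_form(m, n):
    assert count_self_crossings(grid_arbor(m, n), z_tol=0.1) == m * n


def _crossing_oracle(arbor: Arbor, z_tol: float) -> int:
    """All-pairs shapely crossing check with the same z interpolation rule."""
    parent, child = arbor.dendrite_segments()
    segs = [(arbor.xyz[p], arbor.xyz[c], {int(p), int(c)})
            for p, c in zip(parent, child)]
    count = 0
    for i in range(len(segs)):
        a1, b1, n1 = segs[i]
        l1 = LineString([a1[:2], b1[:2]])
        for j in range(i + 1, len(segs)):
            a2, b2, n2 = segs[j]
            if n1 & n2:
                continue
            l2 = LineString([a2[:2], b2[:2]])
            if not l1.crosses(l2):
                continue
            pt = l1.intersection(l2)
            if pt.geom_type != "Point":
                continue
            t = l1.project(pt) / l1.length
            u = l2.project(pt) / l2.length
            z1 = a1[2] + t * (b1[2] - a1[2])
            z2 = a2[2] + u * (b2[2] - a2[2])
            if abs(z1 - z2) <= z_tol:
                count += 1
    return count


def test_crossings_match_shapely_oracle_on_random_arbors():
    rng = np.random.default_rng(5)
    for _ in range(6):
        arbor = gen_arbor(ArborGenParams(
            n_primary=3, target_radius=25.0, branch_rate=0.08, step_len=2.0,
            radial_bias=0.55, z_jitter_sd=0.4,
            seed=int(rng.integers(2 ** 31)),
        ))
        parent, child = arbor.dendrite_segments()
        assert len(child) <= 500
        for z_tol in (0.2, 1.0):
            assert count_self_crossings(arbor, z_tol=z_tol) == \
                _crossing_oracle(arbor, z_tol)


# ------------------------------------------------- caliber / hypertrophy

def test_hypertrophic_classification_boundaries():
    def uniform_diam_arbor(diam: float) -> Arbor:
        return chain_arbor([(0, 0, 0)] + [(0, float(k), 0) for k in range(2, 40, 2)],
                           radius=diam / 2)

    assert classify_hypertrophic(uniform_diam_arbor(0.6)) == (pytest.approx(0.6), False)
    # caliber of exactly 1.0 um is NOT hypertrophic: the rule is strictly greater
    assert classify_hypertrophic(uniform_diam_arbor(1.0)) == (pytest.approx(1.0), False)

    nodes = [(1, -1, 0, 0, 0, 4.0, SOMA)]
    for k in range(1, 20):
        r = 0.75 if k == 10 else 0.3  # one mid-arbor node at diameter 1.5
        nodes.append((k + 1, k, 0.0, 2.0 * k, 0.0, r, DENDRITE))
    max_cal, hyper = classify_hypertrophic(make_arbor(nodes))
    assert (max_cal, hyper) == (pytest.approx(1.5), True)


def test_hypertrophic_ignores_proximal_taper():
    # a fat node inside the 5 um exclusion zone must not trigger the call
    nodes = [(1, -1, 0, 0, 0, 4.0, SOMA),
             (2, 1, 0, 2, 0, 1.5, DENDRITE)]
    for k in range(3, 12):
        nodes.append((k, k - 1, 0.0, 2.0 * (k - 1), 0.0, 0.3, DENDRITE))
    max_cal, hyper = classify_hypertrophic(make_arbor(nodes))
    assert not hyper and max_cal == pytest.approx(0.6)


# ---------------------------------------------------------------- soma area

def test_soma_area_disc_ring_and_two_node_fallback():
    disc = star_arbor(n_rays=3, length=10, soma_radius=5.0)
    assert soma_area(disc) == pytest.approx(25 * math.pi)

    nodes = []
    for k in range(8):
        ang = 2 * math.pi * k / 8
        nodes.append((k + 1, -1 if k == 0 else 1,
                      6 * math.cos(ang), 6 * math.sin(ang), 0.0, 1.0, SOMA))
    nodes.append((9, 1, 20.0, 0.0, 0.0, 0.3, DENDRITE))
    ring = make_arbor(nodes)
    assert soma_area(ring) == pytest.approx(2 * math.sqrt(2) * 36, rel=1e-6)

    two = make_arbor([
        (1, -1, 0, 0, 0, 5.0, SOMA),
        (2, 1, 1, 0, 0, 3.0, SOMA),
        (3, 2, 10, 0, 0, 0.3, DENDRITE),
    ])
    assert soma_area(two) == pytest.approx(25 * math.pi)


# ------------------------------------------------------- rigid invariance

@pytest.mark.parametrize("angle,shift", [(0.7, (12.0, -3.0, 4.0)),
                                         (2.4, (-50.0, 8.0, 0.0))])
def test_metrics_invariant_under_rigid_motion(angle, shift):
    arbor = gen_arbor(ArborGenParams(n_primary=3, target_radius=30.0,
                                     branch_rate=0.05, step_len=2.0,
                                     radial_bias=0.7, seed=21))
    moved = rigid_transform(arbor, angle, shift)
    assert total_length(moved) == pytest.approx(total_length(arbor))
    assert count_branch_points(moved) == count_branch_points(arbor)
    assert field_area_convex_hull(moved) == pytest.approx(
        field_area_convex_hull(arbor), rel=1e-9)
    a = sholl_profile(arbor, step=1.0)
    b = sholl_profile(moved, step=1.0)
    np.testing.assert_array_equal(a.intersections, b.intersections)
    assert count_self_crossings(moved) == count_self_crossings(arbor)
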