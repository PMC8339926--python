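"""Fixed-point finding, classification, nullclines, slow points, topology."""

import numpy as np
import pytest
from scipy.optimize import brentq
from shapely.geometry import LineString

from grudyn import (GRUParams, classify_fixed_point, find_fixed_points,
                    homoclinic_family, nullclines, rotation_family,
                    slow_points, topology_signature)
from grudyn.phase import (find_clusters, scalar_stability_structures,
                          update_gate_slow_directions)

from conftest import random_params, scalar_gru


def bistable_level():
    """Nonzero root of tanh(1.5 x) = x by bisection (independent oracle)."""
    return brentq(lambda x: np.tanh(1.5 * x) - x, 0.5, 0.999, xtol=1e-12)


class TestFindFixedPoints:
    def test_zero_params_single_sink_at_origin(self):
        fps = find_fixed_points(GRUParams.zeros(2))
        assert len(fps) == 1
        assert np.allclose(fps[0].location, 0.0)
        assert fps[0].stability == "sink"

    def test_two_bistable_units_nine_points(self, bistable_pair):
        fps = find_fixed_points(bistable_pair)
        assert len(fps) == 9
        counts = {c: sum(fp.stability == c for fp in fps)
                  for c in ("sink", "source", "saddle", "marginal")}
        assert counts == {"sink": 4, "source": 1, "saddle": 4, "marginal": 0}
        # locations are the tensor grid {0, +/-x*}^2 of the scalar roots
        x = bistable_level()
        expected = sorted((a, b) for a in (-x, 0.0, x) for b in (-x, 0.0, x))
        found = sorted(tuple(fp.location) for fp in fps)
        assert np.allclose(found, expected, atol=1e-9)

    def test_rotation_family_single_spiral_sink(self):
        fps = find_fixed_points(rotation_family(np.pi / 3, 3.0, 0.0))
        assert len(fps) == 1
        assert fps[0].stability == "sink" and fps[0].spiral

    def test_all_points_verified_and_inside_open_cube(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            fps = find_fixed_points(random_params(rng))
            for fp in fps:
                assert fp.residual_speed < 1e-10
                assert np.all(np.abs(fp.location) < 1.0)

    def test_odd_symmetric_family_has_symmetric_fixed_points(self):
        rng = np.random.default_rng(15)
        z = np.zeros((2, 2))
        for _ in range(5):
            params = GRUParams(z, z, rng.normal(0, 2, (2, 2)),
                               np.zeros(2), np.zeros(2), np.zeros(2))
            locs = sorted(tuple(fp.location) for fp in find_fixed_points(params))
            mirrored = sorted(tuple(-np.asarray(l)) for l in locs)
            assert np.allclose(locs, mirrored, atol=1e-9)

    def test_matches_nullcline_intersection_oracle(self):
        # independent geometric oracle: intersect the marching-squares
        # polylines of the two nullcline families on a fine grid
        rng = np.random.default_rng(11)
        for _ in range(10):
            params = random_params(rng, rec_scale=1.8)
            fps = find_fixed_points(params)
            locs = np.stack([fp.location for fp in fps])
            if len(fps) > 1:
                dmin = min(np.linalg.norm(a - b)
                           for i, a in enumerate(locs) for b in locs[i + 1:])
                if dmin < 5e-2:  # conditioning guard for the geometric oracle
                    continue
            pts = []
            for a in nullclines(params, 0, grid_n=400):
                la = LineString(a)
                for b in nullclines(params, 1, grid_n=400):
                    inter = la.intersection(LineString(b))
                    if inter.is_empty:
                        continue
                    for geom in getattr(inter, "geoms", [inter]):
                        pts.extend(np.asarray(geom.coords))
            uniq = []
            for q in pts:
                if not any(np.hypot(*(np.asarray(q) - u)) < 1e-2 for u in uniq):
                    uniq.append(np.asarray(q))
            assert len(uniq) == len(fps)

    def test_index_parity_of_planar_portraits(self):
        # Poincare-index bookkeeping: sinks + sources - saddles = 1 for the
        # portraits with only simple fixed points
        rng = np.random.default_rng(21)
        for _ in range(10):
            fps = find_fixed_points(random_params(rng, rec_scale=2.0))
            counts = {c: sum(fp.stability == c for fp in fps)
                      for c in ("sink", "source", "saddle", "marginal")}
            if counts["marginal"]:
                continue
            assert counts["sink"] + counts["source"] - counts["saddle"] == 1


class TestClassification:
    def test_bistable_origin_is_source_with_quarter_eigenvalues(self, bistable_pair):
        assert classify_fixed_point(bistable_pair, np.zeros(2)) == "source"
        from grudyn import jacobian

        eig = np.linalg.eigvals(jacobian(bistable_pair, np.zeros(2)))
        # closed form (1/2)(1.5 sech^2(0) - 1) = 1/4
        assert np.allclose(eig, 0.25, atol=1e-12)

    def test_bistable_corner_is_sink(self, bistable_pair):
        x = bistable_level()
        assert classify_fixed_point(bistable_pair, np.array([x, x])) == "sink"

    def test_hopf_point_is_marginal(self):
        params = rotation_family(np.arccos(2.0 / 3.0), 3.0, 0.0)
        assert classify_fixed_point(params, np.zeros(2)) == "marginal"

    def test_non_fixed_point_rejected(self, bistable_pair):
        with pytest.raises(ValueError, match="not a fixed point"):
            classify_fixed_point(bistable_pair, np.array([0.3, 0.3]))


class TestNullclines:
    def test_zero_params_vertical_line(self):
        curves = nullclines(GRUParams.zeros(2), 0)
        assert len(curves) == 1
        assert np.max(np.abs(curves[0][:, 0])) < 1e-9

    def test_bistable_pair_three_parallel_lines(self, bistable_pair):
        curves = nullclines(bistable_pair, 0)
        assert len(curves) == 3
        x = bistable_level()
        means = sorted(float(np.mean(c[:, 0])) for c in curves)
        assert np.allclose(means, [-x, 0.0, x], atol=1e-3)
        for c in curves:  # each branch is a vertical line
            assert np.ptp(c[:, 0]) < 1e-6

    def test_rotation_family_s_curve_crosses_vertical_lines_thrice(self):
        curves = nullclines(rotation_family(0.6, 3.0, 0.0), 1)
        assert len(curves) == 1
        curve = curves[0]
        crossings = []
        for xq in np.linspace(-0.9, 0.9, 37):
            sgn = np.sign(curve[:, 0] - xq)
            crossings.append(int(np.sum(sgn[:-1] * sgn[1:] < 0)))
        assert max(crossings) == 3

    def test_requires_planar_system(self):
        with pytest.raises(ValueError, match="d = 2"):
            nullclines(GRUParams.zeros(3), 0)


class TestSlowPoints:
    def test_zero_params_have_no_slow_points(self):
        assert slow_points(GRUParams.zeros(2), 1e-3) == []

    def test_rotation_fold_ghosts_near_each_incipient_pair(self):
        # just above the saddle-node cascade the four annihilated pairs leave
        # four symmetric slow ghosts
        from grudyn.bifurcations import ParameterFamily, locate_saddle_node

        family = ParameterFamily(lambda a: rotation_family(a, 3.0, 0.0), "alpha")
        fold = locate_saddle_node(family, (0.1, 0.6), tol=1e-3).critical_value
        ghosts = slow_points(rotation_family(fold + 0.005, 3.0, 0.0), 1e-2,
                             grid_n=15)
        assert len(ghosts) == 4
        assert all(speed < 1e-2 for _, speed in ghosts)
        locs = np.stack([loc for loc, _ in ghosts])
        assert np.allclose(sorted(map(tuple, locs)),
                           sorted(map(tuple, -locs)), atol=1e-6)

    def test_ghost_speed_decreases_toward_homoclinic_family_fold(self):
        # the pair creation in the gamma family is at the fold located by
        # count bisection; the ghost slows monotonically approaching it
        from grudyn.bifurcations import ParameterFamily, locate_saddle_node

        family = ParameterFamily(homoclinic_family, "gamma")
        fold = locate_saddle_node(family, (0.02, 0.03), tol=1e-6).critical_value
        speeds = []
        for dg in (0.006, 0.003, 0.001):
            ghosts = slow_points(homoclinic_family(fold - dg), 5e-2, grid_n=15)
            assert ghosts, f"no ghost at fold - {dg}"
            speeds.append(ghosts[0][1])
        assert speeds[0] > speeds[1] > speeds[2]


class TestUpdateGateSlowDirections:
    def test_unparameterized_gate_flags_nothing(self):
        assert update_gate_slow_directions(GRUParams.zeros(2)) == {}

    def test_saturated_bias_flags_dimension_everywhere(self):
        params = GRUParams(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)),
                           np.array([20.0, 0.0]), np.zeros(2), np.zeros(2))
        flags = update_gate_slow_directions(params, grid_n=10)
        assert len(flags) == 100
        assert all(dims == frozenset({0}) for dims in flags.values())

    def test_state_dependent_gate_flags_half_plane(self):
        params = GRUParams(np.array([[10.0, 0.0], [0.0, 0.0]]), np.zeros((2, 2)),
                           np.zeros((2, 2)), np.zeros(2), np.zeros(2), np.zeros(2))
        thr = 0.9
        flags = update_gate_slow_directions(params, z_threshold=thr, grid_n=25)
        cut = np.log(thr / (1 - thr)) / 10.0  # logistic inverse
        for (x, _), dims in flags.items():
            assert 0 in dims and x > cut
        # every grid x beyond the cut is flagged
        xs = np.linspace(-1.2, 1.2, 25)
        n_expected = int(np.sum(xs > cut)) * 25
        assert len(flags) == n_expected


class TestTopologySignature:
    def test_zero_params(self):
        sig = topology_signature(GRUParams.zeros(2))
        assert (sig.n_sink, sig.n_source, sig.n_saddle, sig.n_marginal) == (1, 0, 0, 0)
        assert not sig.has_limit_cycle

    def test_bistable_pair(self, bistable_pair):
        sig = topology_signature(bistable_pair)
        assert (sig.n_sink, sig.n_source, sig.n_saddle) == (4, 1, 4)
        assert sig.n_fixed_points == 9
        assert not sig.has_limit_cycle

    def test_homoclinic_family_cycle_flag(self):
        sig = topology_signature(homoclinic_family(0.0535))
        assert sig.has_limit_cycle


def test_cluster_detection_groups_tight_points():
    from grudyn.phase import FixedPoint

    def fp(loc):
        return FixedPoint(np.asarray(loc), np.array([-0.1, -0.2]), "sink",
                          False, 0.0)

    tight = [fp([0.0, 0.0]), fp([0.0, 5e-9]), fp([5e-9, 0.0]), fp([1.0, 1.0])]
    clusters = find_clusters(tight, threshold=1e-8)
    assert len(clusters) == 1
    assert len(clusters[0].members) == 3
    assert clusters[0].diameter < 1e-8


def test_scalar_gru_has_exactly_three_stability_structures():
    structures = scalar_stability_structures()
    assert structures == {("sink",), ("sink", "sink", "source"),
                          ("marginal", "sink")}


def test_scalar_fold_location_matches_closed_form():
    # fold of tanh(u x / 2 + b) = x at b = 0.1: solve the tangency system
    # analytically via a = cosh^2(a) tanh(a) + b, u* = 2 cosh^2(a)
    from grudyn.bifurcations import ParameterFamily, locate_saddle_node

    a = brentq(lambda a: np.cosh(a) ** 2 * np.tanh(a) + 0.1 - a, -2.0, -0.2,
               xtol=1e-14)
    u_star = 2.0 * np.cosh(a) ** 2
    family = ParameterFamily(lambda u: scalar_gru(u, 0.1), "u")
    result = locate_saddle_node(family, (1.5, 3.5), tol=1e-8, grid_n=200)
    assert result.evidence["count_low_side"] == 1
    assert result.evidence["count_high_side"] == 3
    assert abs(result.critical_value - u_star) < 1e-6
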