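import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringmix import (ChainSpec, Confinement, Topology, count_short_chains,
                     linking_number, place_rings_in_sphere, verify_topology)
from ringmix.builder import (INIT_BOND_LENGTH, PlacementError,
                             maxwell_velocities, regular_polygon)
from ringmix.fixtures import circle_polyline, hopf_pair

from conftest import rigid_rotation


class TestLinkingNumber:
    def test_hopf_pair_is_exactly_one(self):
        a, b = hopf_pair()
        assert abs(linking_number(a, b)) == pytest.approx(1.0, abs=1e-9)

    def test_separated_circles_are_exactly_zero(self):
        a = circle_polyline(80, 1.0, (0, 0, 0))
        b = circle_polyline(80, 1.0, (5.0, 0, 0))
        assert linking_number(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetric_under_orientation_reversal(self):
        a, b = hopf_pair()
        lk = linking_number(a, b)
        assert linking_number(a, b[::-1]) == pytest.approx(-lk, abs=1e-9)
        assert linking_number(b, a) == pytest.approx(lk, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi),
           shift=st.floats(-3.0, 3.0),
           ax=st.sampled_from([(1, 0, 0), (0, 1, 0), (1, 1, 1)]))
    def test_rigid_motion_invariance(self, angle, shift, ax):
        # the same rotation + translation applied to BOTH rings (moving a
        # single ring may sweep it through the other and change Lk)
        a, b = hopf_pair(60)
        lk0 = linking_number(a, b)
        a2 = rigid_rotation(a, ax, angle, about=(1.0, 0.0, 0.0)) + shift
        b2 = rigid_rotation(b, ax, angle, about=(1.0, 0.0, 0.0)) + shift
        assert linking_number(a2, b2) == pytest.approx(lk0, abs=1e-8)

    @pytest.mark.parametrize("n", [12, 48, 300])
    def test_refinement_invariance(self, n):
        a, b = hopf_pair(n)
        assert abs(linking_number(a, b)) == pytest.approx(1.0, abs=1e-9)

    def test_self_pair_and_degenerate_input_rejected(self):
        a, _ = hopf_pair(20)
        with pytest.raises(ValueError, match="itself"):
            linking_number(a, a)
        bad = a.copy()
        bad[3] = bad[4]
        with pytest.raises(ValueError, match="zero-length"):
            linking_number(a, bad)
        with pytest.raises(ValueError):
            linking_number(a[:2], a)


class TestGeometry:
    def test_regular_polygon_bond_lengths_and_orientation(self):
        pts = regular_polygon(17, 0.97, center=(1.0, -2.0, 3.0),
                              normal=(1.0, 2.0, -1.0))
        bonds = np.roll(pts, -1, axis=0) - pts
        assert np.linalg.norm(bonds, axis=1) == pytest.approx(
            np.full(17, 0.97), abs=1e-12)
        com = pts.mean(axis=0)
        assert com == pytest.approx([1.0, -2.0, 3.0], abs=1e-12)
        n = np.array([1.0, 2.0, -1.0]) / np.sqrt(6.0)
        # all monomers lie in the plane through com with that normal
        assert (pts - com) @ n == pytest.approx(np.zeros(17), abs=1e-12)

    def test_polygon_needs_three_vertices(self):
        with pytest.raises(ValueError):
            regular_polygon(2)

    def test_maxwell_velocities_momentum_and_temperature(self):
        rng = np.random.default_rng(11)
        v = maxwell_velocities(4000, 1.0, rng)
        assert v.mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-12)
        assert np.mean(v ** 2) == pytest.approx(1.0, abs=0.05)


class TestComposition:
    def test_count_short_chains_matches_density_formula(self):
        conf = Confinement(mode="sphere", radius=20.0)
        m = count_short_chains(0.4, conf, 10, 50, 10)
        v = conf.volume
        assert m == math.floor((0.4 * v - 500) / 10)
        achieved = (500 + m * 10) / v
        assert 0.4 - 10 / v < achieved <= 0.4

    def test_infeasible_composition_rejected(self):
        conf = Confinement(mode="sphere", radius=3.0)
        with pytest.raises(ValueError, match="infeasible"):
            count_short_chains(0.4, conf, 10, 50, 10)


class TestPlacement:
    def test_sphere_placement_invariants(self, two_ring_state, ff):
        two_ring_state.validate(ff)
        # all monomers strictly inside the accessible region
        r = np.linalg.norm(two_ring_state.positions, axis=1)
        assert r.max() < two_ring_state.confinement.radius - ff.lj_sigma
        # no hard overlaps after push-off
        d = two_ring_state.positions[:, None] - two_ring_state.positions[None]
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 0.9

    def test_bond_lengths_near_template_spacing(self, two_ring_state):
        top = two_ring_state.topology
        bv = (two_ring_state.positions[top.bonds[:, 1]]
              - two_ring_state.positions[top.bonds[:, 0]])
        blen = np.linalg.norm(bv, axis=1)
        assert np.all(np.abs(blen - INIT_BOND_LENGTH) < 0.15)

    def test_dense_state_unlinked_and_valid(self, dense_small_state, ff):
        dense_small_state.validate(ff)
        report = verify_topology(dense_small_state)
        assert report.all_unlinked
        assert report.n_ring_pairs == 19 * 18 // 2
        assert report.max_residual < 0.05

    def test_periodic_state_min_image_separation(self, periodic_state, ff):
        periodic_state.validate(ff)
        L = periodic_state.confinement.box_edge
        d = periodic_state.positions[:, None] - periodic_state.positions[None]
        d -= L * np.round(d / L)
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 0.9
        assert verify_topology(periodic_state).all_unlinked

    def test_same_seed_is_deterministic(self, ff):
        top = Topology([ChainSpec("ring", 8, 10.0, "long")] * 3)
        conf = Confinement(mode="sphere", radius=8.0)
        s1 = place_rings_in_sphere(top, conf, ff, seed=4)
        s2 = place_rings_in_sphere(top, conf, ff, seed=4)
        np.testing.assert_array_equal(s1.positions, s2.positions)
        np.testing.assert_array_equal(s1.velocities, s2.velocities)
        s3 = place_rings_in_sphere(top, conf, ff, seed=5)
        assert not np.array_equal(s1.positions, s3.positions)

    def test_mixed_linear_chains_supported(self, ff):
        top = Topology([ChainSpec("ring", 8, 10.0, "long")] * 2
                       + [ChainSpec("linear", 5, 0.0, "short")] * 4)
        conf = Confinement(mode="sphere", radius=8.0)
        state = place_rings_in_sphere(top, conf, ff, seed=0)
        state.validate(ff)

    def test_overpacked_request_fails_with_clear_error(self, ff):
        top = Topology([ChainSpec("ring", 30, 10.0, "long")] * 20)
        conf = Confinement(mode="sphere", radius=4.0)
        with pytest.raises(PlacementError, match="packing fraction"):
            place_rings_in_sphere(top, conf, ff, seed=0)

    def test_chain_too_large_for_sphere_fails(self, ff):
        top = Topology([ChainSpec("ring", 60, 10.0, "long")])
        conf = Confinement(mode="sphere", radius=5.0)
        with pytest.raises(PlacementError):
            place_rings_in_sphere(top, conf, ff, seed=0)
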