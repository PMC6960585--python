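import numpy as np
import pytest

from ringmix import (ChainSpec, Confinement, ForceFieldParams, SystemState,
                     Topology, forces, total_energy)
from ringmix import forcefield
from ringmix.fixtures import perfect_rigid_ring


class TestScalarPotentials:
    def test_fene_reference_value(self, ff):
        # -0.5 * 30 * 1.5^2 * ln(1 - (0.97/1.5)^2)
        assert forcefield.fene_energy(0.97, ff) == pytest.approx(18.28,
                                                                 abs=0.01)

    def test_fene_diverges_at_maximum_extension(self, ff):
        with pytest.raises(ValueError):
            forcefield.fene_energy(1.5, ff)
        with pytest.raises(ValueError):
            forcefield.fene_energy(1.7, ff)

    def test_wca_reference_values(self, ff):
        assert forcefield.wca_energy(1.0, ff) == pytest.approx(1.0, abs=1e-12)
        # exactly zero at and beyond the cutoff
        assert forcefield.wca_energy(ff.lj_cutoff, ff) == pytest.approx(
            0.0, abs=1e-12)
        assert forcefield.wca_energy(2.0, ff) == 0.0
        with pytest.raises(ValueError):
            forcefield.wca_energy(0.0, ff)

    def test_bending_zero_when_collinear(self):
        # theta is the interior angle: pi for a straight chain
        assert forcefield.bending_energy(np.pi, 50.0) == pytest.approx(
            0.0, abs=1e-12)
        assert forcefield.bending_energy(np.pi / 2, 7.0) == pytest.approx(
            7.0, abs=1e-12)

    def test_ring_bending_reference_value(self, ff):
        # regular 50-gon with Kb = 50: 50 angles of Kb*(1 - cos(2 pi/50))
        pos = perfect_rigid_ring(50, 1.0)
        top = Topology([ChainSpec("ring", 50, 50.0, "long")])
        conf = Confinement(mode="sphere", radius=20.0)
        state = SystemState(pos, np.zeros_like(pos), 0.0, top, conf)
        e = total_energy(state, ff, method="brute")
        assert e.bending == pytest.approx(19.71, abs=0.01)
        assert e.fene == pytest.approx(
            50 * forcefield.fene_energy(1.0, ff), rel=1e-10)
        assert e.pair == pytest.approx(
            50 * forcefield.wca_energy(1.0, ff), rel=1e-10)

    def test_equilibrium_bond_length(self, ff):
        b = forcefield.equilibrium_bond_length(ff)
        assert b == pytest.approx(0.961, abs=0.001)

    def test_breakdown_total_is_sum(self):
        e = forcefield.EnergyBreakdown(1.0, 2.0, 3.0, 4.0)
        assert e.total == 10.0


class TestWall:
    def test_smooth_wall_energy_and_inward_force(self, ff):
        conf = Confinement(mode="sphere", radius=10.0)
        # gap exactly sigma: WCA at r = sigma is epsilon
        assert forcefield.wall_energy([9.0, 0.0, 0.0], conf, ff) == \
            pytest.approx(1.0, abs=1e-12)
        # outside the cutoff shell the wall is exactly zero
        assert forcefield.wall_energy([5.0, 0.0, 0.0], conf, ff) == 0.0
        with pytest.raises(ValueError):
            forcefield.wall_energy([10.5, 0.0, 0.0], conf, ff)
        # force on a near-wall monomer points toward the centre
        top = Topology([ChainSpec("ring", 3, 0.0, "long")])
        pos = perfect_rigid_ring(3, 1.0, center=(9.2, 0.0, 0.0),
                                 normal=(1.0, 0.0, 0.0))
        state = SystemState(pos, np.zeros_like(pos), 0.0, top, conf)
        f = forces(state, ff, method="brute")
        assert np.dot(f.sum(axis=0), [1.0, 0.0, 0.0]) < 0.0

    def test_particulate_wall_agrees_with_smooth_in_sign_and_reach(self, ff):
        smooth = Confinement(mode="sphere", radius=10.0)
        beads = Confinement(mode="sphere", radius=10.0,
                            wall_style="particulate")
        near = [9.2, 0.0, 0.0]
        far = [4.0, 0.0, 0.0]
        assert forcefield.wall_energy(near, beads, ff) > 0.0
        assert forcefield.wall_energy(far, beads, ff) == 0.0
        assert forcefield.wall_energy(near, smooth, ff) > 0.0

    def test_fibonacci_sphere_radius_and_coverage(self):
        pts = forcefield.fibonacci_sphere(5.0, spacing=1.0)
        assert np.linalg.norm(pts, axis=1) == pytest.approx(
            np.full(len(pts), 5.0), abs=1e-12)
        assert len(pts) == pytest.approx(4 * np.pi * 25, rel=0.01)


class TestSystemEvaluation:
    def test_cell_matches_brute_in_sphere(self, dense_small_state, ff):
        fb = forces(dense_small_state, ff, method="brute")
        fc = forces(dense_small_state, ff, method="cell")
        assert np.max(np.abs(fb - fc)) < 1e-9
        eb = total_energy(dense_small_state, ff, method="brute")
        ec = total_energy(dense_small_state, ff, method="cell")
        for term in ("fene", "pair", "bending", "wall"):
            assert getattr(ec, term) == pytest.approx(getattr(eb, term),
                                                      abs=1e-9)

    def test_cell_matches_brute_in_periodic_box(self, periodic_state, ff):
        fb = forces(periodic_state, ff, method="brute")
        fc = forces(periodic_state, ff, method="cell")
        assert np.max(np.abs(fb - fc)) < 1e-9
        eb = total_energy(periodic_state, ff, method="brute")
        ec = total_energy(periodic_state, ff, method="cell")
        assert ec.total == pytest.approx(eb.total, abs=1e-9)
        assert ec.wall == 0.0

    def test_forces_are_minus_gradient(self, two_ring_state, ff):
        state = two_ring_state.copy()
        f = forces(state, ff, method="brute")
        h = 1e-6
        num = np.zeros_like(f)
        for i in range(len(state.positions)):
            for k in range(3):
                p = state.positions.copy()
                p[i, k] += h
                up = total_energy(
                    SystemState(p, state.velocities, 0.0, state.topology,
                                state.confinement), ff).total
                p[i, k] -= 2 * h
                um = total_energy(
                    SystemState(p, state.velocities, 0.0, state.topology,
                                state.confinement), ff).total
                num[i, k] = -(up - um) / (2 * h)
        scale = max(np.abs(f).max(), 1.0)
        assert np.max(np.abs(f - num)) / scale < 1e-6

    def test_net_force_is_zero_without_wall(self, periodic_state, ff):
        f = forces(periodic_state, ff, method="cell")
        assert f.sum(axis=0) == pytest.approx(np.zeros(3), abs=1e-9)

    def test_overstretched_bond_reported_by_both_paths(self, ff):
        top = Topology([ChainSpec("linear", 2, 0.0, "long")])
        conf = Confinement(mode="periodic_box", box_edge=20.0)
        pos = np.array([[1.0, 1.0, 1.0], [2.6, 1.0, 1.0]])
        state = SystemState(pos, np.zeros_like(pos), 0.0, top, conf)
        with pytest.raises(ValueError):
            forces(state, ff, method="brute")
        with pytest.raises(ValueError):
            forces(state, ff, method="cell")
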