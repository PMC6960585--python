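import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringmix import (ChainSpec, Confinement, SystemState, Topology,
                     Trajectory, observables)
from ringmix.fixtures import (boltzmann_radial_sampler, circumradius,
                              isotropic_ring_ensemble, perfect_rigid_ring,
                              tangential_slide_trajectory,
                              wall_attached_ensemble)

from conftest import rigid_rotation


def _ring_state(m, n, centers, normals, radius=20.0, kb=100.0):
    top = Topology([ChainSpec("ring", n, kb, "long") for _ in range(m)])
    pos = np.concatenate([perfect_rigid_ring(n, 1.0, c, u)
                          for c, u in zip(centers, normals)])
    return SystemState(pos, np.zeros_like(pos), 0.0, top,
                       Confinement(mode="sphere", radius=radius))


class TestRingGeometry:
    def test_gyration_radius_of_regular_polygon_is_circumradius(self):
        pts = perfect_rigid_ring(50, 1.0)
        assert observables.gyration_radius(pts) == pytest.approx(
            circumradius(50, 1.0), abs=1e-12)

    def test_ring_normal_matches_construction(self):
        u = np.array([1.0, -2.0, 0.5])
        u /= np.linalg.norm(u)
        pts = perfect_rigid_ring(20, 1.0, (3.0, 0.0, 0.0), u)
        n = observables.ring_normal(pts)
        assert abs(float(np.dot(n, u))) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_ring_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            observables.ring_normal(line)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi),
           ax=st.sampled_from([(1, 0, 0), (0, 0, 1), (1, -1, 2)]))
    def test_gyration_radius_rotation_invariant(self, angle, ax):
        pts = perfect_rigid_ring(17, 1.0, (2.0, 1.0, 0.0), (0.0, 1.0, 0.0))
        rot = rigid_rotation(pts, ax, angle)
        assert observables.gyration_radius(rot) == pytest.approx(
            observables.gyration_radius(pts), abs=1e-10)


class TestOrientationOrder:
    def test_wall_attached_rings_give_exactly_one(self):
        state = wall_attached_ensemble(m=100, n=20, reach=15.0, seed=0)
        assert observables.orientation_order(state) == pytest.approx(
            1.0, abs=1e-10)

    def test_tangential_normals_give_minus_half(self):
        rng = np.random.default_rng(2)
        centers, normals = [], []
        for _ in range(100):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            t = np.cross(u, rng.normal(size=3))
            t /= np.linalg.norm(t)
            centers.append(10.0 * u)
            normals.append(t)
        state = _ring_state(100, 12, centers, normals)
        assert observables.orientation_order(state) == pytest.approx(
            -0.5, abs=1e-10)

    def test_isotropic_rings_give_zero(self):
        state = isotropic_ring_ensemble(m=3000, n=10, sphere_radius=50.0,
                                        seed=0)
        assert observables.orientation_order(state) == pytest.approx(
            0.0, abs=0.03)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_p2_is_bounded(self, seed):
        state = isotropic_ring_ensemble(m=10, n=8, sphere_radius=20.0,
                                        seed=seed)
        p2 = observables.orientation_order(state)
        assert -0.5 - 1e-12 <= p2 <= 1.0 + 1e-12

    def test_ring_at_centre_skipped(self, caplog):
        state = _ring_state(1, 10, [(0.0, 0.0, 0.0)], [(0.0, 0.0, 1.0)])
        with pytest.raises(ValueError, match="no ring chains"):
            observables.orientation_order(state)

    def test_species_filter(self):
        top = Topology([ChainSpec("ring", 10, 1.0, "long"),
                        ChainSpec("ring", 10, 1.0, "short")])
        # long ring wall-attached (P2 = 1), short ring tangential (-0.5)
        pos = np.concatenate([
            perfect_rigid_ring(10, 1.0, (8.0, 0, 0), (1.0, 0, 0)),
            perfect_rigid_ring(10, 1.0, (0, 8.0, 0), (1.0, 0, 0)),
        ])
        state = SystemState(pos, np.zeros_like(pos), 0.0, top,
                            Confinement(mode="sphere", radius=12.0))
        assert observables.orientation_order(state, "long") == pytest.approx(
            1.0, abs=1e-10)
        assert observables.orientation_order(state, "short") == pytest.approx(
            -0.5, abs=1e-10)


class TestRadialProfiles:
    def test_uniform_samples_give_flat_reduced_density(self):
        pts = boltzmann_radial_sampler(lambda r: np.zeros_like(r), 5.0,
                                       200_000, seed=0)
        radii = np.linalg.norm(pts, axis=1)
        rho = len(radii) / (4.0 / 3.0 * np.pi * 5.0 ** 3)
        prof = observables.density_profile_from_points(
            radii, 1, rho, 5.0, bin_width=1.0)
        assert prof.values == pytest.approx(np.ones(5), abs=0.03)
        assert prof.counts.sum() == 200_000

    def test_mean_radial_distance_monomer_vs_com(self):
        state = wall_attached_ensemble(m=50, n=20, reach=15.0, seed=1)
        assert observables.mean_radial_distance(state, "long") == \
            pytest.approx(15.0, abs=1e-10)
        expected_com = math.sqrt(15.0 ** 2 - circumradius(20, 1.0) ** 2)
        assert observables.mean_radial_distance(
            state, "long", per="chain_com") == pytest.approx(expected_com,
                                                             abs=1e-10)
        with pytest.raises(ValueError):
            observables.mean_radial_distance(state, "long", per="atom")

    def test_profile_requires_sphere(self, periodic_state):
        with pytest.raises(ValueError, match="sphere"):
            observables.radial_density_profile(periodic_state)


class TestPMF:
    def test_round_trip_recovers_known_potential(self):
        k, r0 = 0.5, 6.0

        def U(r):
            return k * (r - r0) ** 2

        pts = boltzmann_radial_sampler(U, 10.0, 300_000, seed=3)
        prof = observables.pmf_from_points(np.linalg.norm(pts, axis=1), 10.0,
                                           bin_width=0.25)
        centers = prof.centers
        ok = ~np.isnan(prof.values) & (prof.counts > 200)
        expected = U(centers[ok])
        expected -= expected[0]
        got = prof.values[ok] - prof.values[ok][0]
        rms = math.sqrt(np.mean((got - expected) ** 2))
        assert rms < 0.15

    def test_empty_bins_are_nan_and_anchor_at_innermost(self):
        radii = np.concatenate([np.full(500, 4.1), np.full(1000, 7.6)])
        prof = observables.pmf_from_points(radii, 10.0, bin_width=1.0)
        assert prof.values[4] == pytest.approx(0.0)       # innermost -> 0
        assert np.isnan(prof.values[0])
        assert np.isnan(prof.values[9])
        assert np.isfinite(prof.values[7])

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            observables.pmf_from_points(np.array([]), 5.0)


class TestVelocityDecomposition:
    def test_tangential_slide_has_divergent_ratio(self):
        traj = tangential_slide_trajectory(40, 10.0, 20.0, n=50,
                                           angular_speed=0.002)
        vd = observables.velocity_decomposition(traj, "long", delta_t=10.0)
        assert vd.v_perp > 0.0
        assert vd.ratio > 50.0

    def test_normal_motion_has_zero_perp(self):
        # a ring translating along its own (fixed) normal
        top = Topology([ChainSpec("ring", 10, 1.0, "long")])
        conf = Confinement(mode="sphere", radius=30.0)
        frames = []
        for kf in range(10):
            pos = perfect_rigid_ring(10, 1.0, (0.0, 0.0, 2.0 + 0.1 * kf),
                                     (0.0, 0.0, 1.0))
            frames.append(SystemState(pos, np.zeros_like(pos), 5.0 * kf,
                                      top, conf))
        traj = Trajectory(frames, 5.0)
        vd = observables.velocity_decomposition(traj, "long", delta_t=5.0)
        assert vd.v_perp == pytest.approx(0.0, abs=1e-10)
        assert vd.v_par == pytest.approx(0.1 / 5.0, abs=1e-10)

    def test_lag_must_divide_sampling_grid(self):
        traj = tangential_slide_trajectory(5, 10.0, 20.0)
        with pytest.raises(ValueError, match="integer multiple"):
            observables.velocity_decomposition(traj, "long", delta_t=15.0)
        with pytest.raises(ValueError, match="too short"):
            observables.velocity_decomposition(traj, "long", delta_t=50.0)


class TestCriticalDensity:
    def test_parabola_vertex_recovered(self):
        rho = np.array([0.2, 0.3, 0.4, 0.5, 0.6])
        ratio = -(rho - 0.42) ** 2 + 3.0
        rc = observables.critical_density(list(zip(rho, ratio)))
        assert rc == pytest.approx(0.42, abs=1e-10)

    def test_boundary_maximum_warns(self):
        samples = [(0.2, 3.0), (0.3, 2.0), (0.4, 1.0)]
        with pytest.warns(UserWarning, match="edge"):
            assert observables.critical_density(samples) == 0.2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            observables.critical_density([(0.2, 1.0), (0.3, 2.0)])


class TestEnergyEntropyDecomposition:
    @staticmethod
    def _rigid_bulk_traj(seed, n_frames=6):
        """Rigid rings teleporting around a periodic box: bending energy is
        identical for every chain and frame."""
        rng = np.random.default_rng(seed)
        top = Topology([ChainSpec("ring", 8, 5.0, "long") for _ in range(3)])
        conf = Confinement(mode="periodic_box", box_edge=20.0)
        frames = []
        for kf in range(n_frames):
            pos = np.concatenate([
                perfect_rigid_ring(8, 1.0, rng.uniform(3, 17, 3),
                                   rng.normal(size=3))
                for _ in range(3)])
            frames.append(SystemState(pos, np.zeros_like(pos), float(kf),
                                      top, conf))
        return Trajectory(frames, 1.0)

    def test_bulk_against_itself_has_zero_energy_term(self):
        traj = self._rigid_bulk_traj(0)
        du, tds = observables.energy_entropy_decomposition(traj, traj,
                                                           "long",
                                                           bin_width=2.0)
        pop = ~np.isnan(du.values)
        assert pop.any()
        assert du.values[pop] == pytest.approx(np.zeros(pop.sum()),
                                               abs=1e-10)
        # with delta U = 0, T delta S = -delta F (the chain-COM PMF)
        assert np.nanmax(np.abs(tds.values[pop])) > 0 or pop.sum() == 1
        assert du.bin_edges == pytest.approx(tds.bin_edges)

    def test_entropy_is_energy_minus_free_energy(self):
        traj = self._rigid_bulk_traj(1)
        du, tds = observables.energy_entropy_decomposition(traj, traj,
                                                           "long",
                                                           bin_width=2.0)
        pop = ~np.isnan(du.values)
        # reconstruct delta F from the two returned profiles
        dF = du.values[pop] - tds.values[pop]
        assert np.isfinite(dF).all()

    def test_composition_mismatch_rejected(self):
        a = self._rigid_bulk_traj(0)
        top = Topology([ChainSpec("ring", 6, 5.0, "long") for _ in range(3)])
        conf = Confinement(mode="periodic_box", box_edge=20.0)
        pos = np.concatenate([perfect_rigid_ring(6, 1.0, (5.0 * i, 5, 5))
                              for i in range(3)])
        other = Trajectory([SystemState(pos, np.zeros_like(pos), 0.0, top,
                                        conf)], 1.0)
        with pytest.raises(ValueError, match="composition"):
            observables.energy_entropy_decomposition(a, other, "long")

    def test_bulk_reference_must_be_periodic(self, two_ring_state):
        traj = Trajectory([two_ring_state], 1.0)
        with pytest.raises(ValueError, match="periodic_box"):
            observables.energy_entropy_decomposition(traj, traj, "long")
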