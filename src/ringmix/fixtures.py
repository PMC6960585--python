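"""Synthetic configurations and trajectories with known structure.

These idealized inputs probe both limits of every observable without
running long simulations: perfectly wall-attached rigid rings (maximal
nematic order, COM distance sqrt(reach^2 - R_ring^2)), isotropic ring
gases (zero order), Hopf-linked pairs (the linking-number positive
control — deliberately violating the non-concatenation invariant),
Boltzmann radial samples from a known potential (PMF round-trip oracle)
and a tangentially sliding ring (velocity-decomposition kinematics).

Every generator is deterministic given its arguments and seed, and its
output is indistinguishable from simulation output to the analysis code.
"""

from __future__ import annotations

import math

import numpy as np

from .builder import maxwell_velocities, regular_polygon
from .core import ChainSpec, Confinement, SystemState, Topology, Trajectory

__all__ = [
    "DEFAULT_BOND_LENGTH",
    "perfect_rigid_ring",
    "wall_attached_ensemble",
    "isotropic_ring_ensemble",
    "hopf_pair",
    "circle_polyline",
    "boltzmann_radial_sampler",
    "tangential_slide_trajectory",
]

#: Bond length of an ideal rigid ring of touching beads (diameter sigma).
#: The model's printed geometric anchors (gyration radius 7.95 of the
#: N = 50 ring, wall-attached COM distance 17.25) correspond to this
#: bead-contact spacing.
DEFAULT_BOND_LENGTH = 1.0


def circumradius(n: int, bond_length: float = DEFAULT_BOND_LENGTH) -> float:
    return bond_length / (2.0 * math.sin(math.pi / n))


def perfect_rigid_ring(n: int, bond_length: float = DEFAULT_BOND_LENGTH,
                       center=(0.0, 0.0, 0.0),
                       normal=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Planar regular n-gon: the zero-temperature limit of a rigid ring."""
    return regular_polygon(n, bond_length, center, normal)


def _ring_topology(m: int, n: int, kb: float = 100.0,
                   species: str = "long") -> Topology:
    return Topology([ChainSpec("ring", n, kb, species) for _ in range(m)])


def wall_attached_ensemble(m: int, n: int, reach: float, seed: int = 0,
                           bond_length: float = DEFAULT_BOND_LENGTH,
                           sphere_radius: float | None = None) -> SystemState:
    """m rigid rings lying flat on the shell of radius ``reach``.

    Every monomer sits at radial distance ``reach``, normals are radial
    and azimuths random, so each chain COM is at
    sqrt(reach^2 - circumradius^2) and the orientation order is exactly 1.
    """
    rc = circumradius(n, bond_length)
    if reach <= rc:
        raise ValueError(
            f"reach {reach} must exceed the ring circumradius {rc:.3f}")
    com_dist = math.sqrt(reach ** 2 - rc ** 2)
    rng = np.random.default_rng(seed)
    R = sphere_radius if sphere_radius is not None else reach + 1.0
    top = _ring_topology(m, n)
    pos = np.empty((top.n_monomers, 3))
    for i in range(m):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos[top.chain_slice(i)] = perfect_rigid_ring(
            n, bond_length, center=com_dist * u, normal=u)
    vel = maxwell_velocities(top.n_monomers, 1.0, rng)
    return SystemState(pos, vel, 0.0, top,
                       Confinement(mode="sphere", radius=R))


def isotropic_ring_ensemble(m: int, n: int, sphere_radius: float,
                            seed: int = 0,
                            bond_length: float = DEFAULT_BOND_LENGTH
                            ) -> SystemState:
    """Rigid rings with uniform COM positions and isotropic normals.

    COMs are rejection-sampled inside radius - circumradius - sigma so all
    monomers stay in the accessible region; chain overlap is NOT excluded
    (an ideal-gas fixture for orientation statistics).
    """
    rc = circumradius(n, bond_length)
    r_allow = sphere_radius - rc - 1.0
    if r_allow <= 0:
        raise ValueError("rings do not fit inside the sphere")
    rng = np.random.default_rng(seed)
    top = _ring_topology(m, n)
    pos = np.empty((top.n_monomers, 3))
    for i in range(m):
        while True:
            c = rng.uniform(-r_allow, r_allow, size=3)
            if np.linalg.norm(c) <= r_allow:
                break
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos[top.chain_slice(i)] = perfect_rigid_ring(n, bond_length, c, u)
    vel = maxwell_velocities(top.n_monomers, 1.0, rng)
    return SystemState(pos, vel, 0.0, top,
                       Confinement(mode="sphere", radius=sphere_radius))


def circle_polyline(n_segments: int = 100, radius: float = 1.0,
                    center=(0.0, 0.0, 0.0),
                    normal=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Closed circular polyline (vertices only, last edge implied)."""
    phi = 2.0 * np.pi * np.arange(n_segments) / n_segments
    pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                           np.zeros(n_segments)])
    from .builder import _orient
    return _orient(pts, center, normal)


def hopf_pair(n_segments: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Minimal linked pair: unit circle in the xy-plane at the origin and
    a unit circle in the xz-plane centred at (1, 0, 0); |Lk| = 1."""
    a = circle_polyline(n_segments, 1.0, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
    b = circle_polyline(n_segments, 1.0, (1.0, 0.0, 0.0), (0.0, 1.0, 0.0))
    return a, b


def boltzmann_radial_sampler(potential, sphere_radius: float,
                             n_samples: int, seed: int = 0) -> np.ndarray:
    """Rejection samples from density proportional to exp(-U(r)) inside
    the sphere (so the radial marginal carries the 4 pi r^2 factor).

    ``potential`` is a vectorised callable U(r) in k_B*T, or a tabulated
    (r, U) pair interpolated linearly; np.inf excludes a region outright.
    """
    if callable(potential):
        U = potential
    else:
        r_tab, u_tab = (np.asarray(a, float) for a in potential)

        def U(r):
            return np.interp(r, r_tab, u_tab)

    rng = np.random.default_rng(seed)
    probe = U(np.linspace(0.0, sphere_radius, 2049))
    finite = probe[np.isfinite(probe)]
    if finite.size == 0:
        raise ValueError("potential is infinite everywhere in the sphere")
    u_min = float(finite.min())

    out = np.empty((n_samples, 3))
    got = 0
    while got < n_samples:
        m = max(4 * (n_samples - got), 1024)
        pts = rng.uniform(-sphere_radius, sphere_radius, size=(m, 3))
        r = np.linalg.norm(pts, axis=1)
        pts = pts[r <= sphere_radius]
        r = r[r <= sphere_radius]
        u = np.asarray(U(r), float)
        acc = np.log(rng.uniform(size=len(r))) < -(u - u_min)
        pts = pts[acc]
        take = min(len(pts), n_samples - got)
        out[got:got + take] = pts[:take]
        got += take
    return out


def tangential_slide_trajectory(n_frames: int, delta_t: float,
                                sphere_radius: float, n: int = 50,
                                bond_length: float = DEFAULT_BOND_LENGTH,
                                angular_speed: float = 0.01) -> Trajectory:
    """A rigid wall-attached ring sliding along the sphere surface.

    The COM moves on its shell of constant |r_com| at constant angular
    speed while the ring normal stays locked radial, so the COM
    displacement is (in the small-step limit) perpendicular to the
    normal: V_par -> 0 and V_perp/V_par diverges.
    """
    rc = circumradius(n, bond_length)
    reach = sphere_radius - 1.0
    com_dist = math.sqrt(reach ** 2 - rc ** 2)
    top = _ring_topology(1, n)
    conf = Confinement(mode="sphere", radius=sphere_radius)
    frames = []
    for k in range(n_frames):
        phi = angular_speed * delta_t * k
        u = np.array([math.cos(phi), math.sin(phi), 0.0])
        pos = perfect_rigid_ring(n, bond_length, com_dist * u, u)
        frames.append(SystemState(pos, np.zeros_like(pos),
                                  k * delta_t, top, conf))
    return Trajectory(frames, delta_t)
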