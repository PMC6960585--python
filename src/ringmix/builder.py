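"""Initial-state construction.

Rings start as rigid planar regular polygons (unknotted by construction)
and linear chains as straight rods, placed by rejection sampling at
non-overlapping slots inside the sphere or periodic box.  Every candidate
ring is checked for a zero Gauss linking number against nearby placed
rings, so the start is non-concatenated as well; the FENE maximum
extension then prevents chain crossing during dynamics.  A short
overdamped push-off with a force-capped WCA ramp removes residual
overlaps before Maxwell-Boltzmann velocities are drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (Confinement, ForceFieldParams, SystemState, Topology)

__all__ = [
    "TopologyReport",
    "count_short_chains",
    "linking_number",
    "verify_topology",
    "place_rings_in_sphere",
    "regular_polygon",
    "maxwell_velocities",
]

#: Initial bond length for freshly built chains (near the FENE+WCA minimum).
INIT_BOND_LENGTH = 0.97

#: Rounded-linking-number residual above which a pair is flagged; well
#: below the 0.5 rounding boundary.
LK_RESIDUAL_TOL = 0.05


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all chains."""


# ---------------------------------------------------------------------------
# Composition bookkeeping
# ---------------------------------------------------------------------------

def count_short_chains(rho: float, confinement: Confinement,
                       m_long: int, n_long: int, n_short: int) -> int:
    """Number of short chains filling the cavity to total density rho.

    rho = (M_long*N_long + M_short*N_short)/V  =>  M_short is the floor of
    (rho*V - M_long*N_long)/N_short.  The achieved density is therefore at
    most one short chain below the requested one.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    v = confinement.volume
    m_short = math.floor((rho * v - m_long * n_long) / n_short)
    if m_short < 1:
        raise ValueError(
            f"composition infeasible: rho*V = {rho * v:.2f} leaves no room "
            f"for short chains beyond {m_long}x{n_long} long monomers")
    return m_short


# ---------------------------------------------------------------------------
# Gauss linking number (exact for polylines)
# ---------------------------------------------------------------------------

def linking_number(ring_a: np.ndarray, ring_b: np.ndarray) -> float:
    """Gauss linking number of two closed polylines (raw, unrounded).

    Evaluates the Gauss double integral segment pair by segment pair using
    the signed solid angle subtended by each pair of straight segments,
    which is exact for polygons: 0 for unlinked rings, +-1 for a Hopf
    link.  Rigid motions of either ring and refinement of the
    discretization leave the value unchanged.
    """
    ring_a = np.asarray(ring_a, float)
    ring_b = np.asarray(ring_b, float)
    if ring_a is ring_b or (ring_a.shape == ring_b.shape
                            and np.array_equal(ring_a, ring_b)):
        raise ValueError("linking number of a ring with itself is undefined")
    for name, ring in (("ring_a", ring_a), ("ring_b", ring_b)):
        if ring.ndim != 2 or ring.shape[0] < 3 or ring.shape[1] != 3:
            raise ValueError(f"{name} must be a closed polyline of >= 3 vertices")
        seg = np.roll(ring, -1, axis=0) - ring
        if np.any(np.linalg.norm(seg, axis=1) < 1e-12):
            raise ValueError(f"{name} has a zero-length segment")

    p1 = ring_a[:, None, :]                        # (Na, 1, 3)
    p2 = np.roll(ring_a, -1, axis=0)[:, None, :]
    p3 = ring_b[None, :, :]                        # (1, Nb, 3)
    p4 = np.roll(ring_b, -1, axis=0)[None, :, :]

    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    r12 = p2 - p1
    r34 = p4 - p3

    def unit(v):
        n = np.linalg.norm(v, axis=-1, keepdims=True)
        return np.divide(v, n, out=np.zeros_like(v), where=n > 1e-14)

    n1 = unit(np.cross(r13, r14))
    n2 = unit(np.cross(r14, r24))
    n3 = unit(np.cross(r24, r23))
    n4 = unit(np.cross(r23, r13))

    def asin_dot(a, b):
        return np.arcsin(np.clip(np.sum(a * b, axis=-1), -1.0, 1.0))

    omega = (asin_dot(n1, n2) + asin_dot(n2, n3)
             + asin_dot(n3, n4) + asin_dot(n4, n1))
    sign = np.sign(np.sum(np.cross(r34, r12) * r13, axis=-1))
    return float(np.sum(omega * sign) / (4.0 * np.pi))


@dataclass
class TopologyReport:
    """Pairwise linking numbers of the rings in a state.

    Only ring pairs whose bounding spheres overlap are evaluated; pairs
    with disjoint bounding spheres are unlinked by geometry and omitted.
    """

    pair_linking_numbers: dict[tuple[int, int], int] = field(default_factory=dict)
    max_residual: float = 0.0
    flagged_pairs: list[tuple[int, int]] = field(default_factory=list)
    n_ring_pairs: int = 0

    @property
    def all_unlinked(self) -> bool:
        return not self.flagged_pairs


def verify_topology(state: SystemState) -> TopologyReport:
    """Evaluate the linking number of every (geometrically close) ring pair.

    A pair is flagged when its rounded linking number is non-zero or the
    residual |raw - rounded| exceeds ``LK_RESIDUAL_TOL``.
    """
    top = state.topology
    rings = top.chain_indices(kind="ring")
    report = TopologyReport()
    if len(rings) < 2:
        return report
    periodic = state.confinement.mode == "periodic_box"
    L = state.confinement.box_edge if periodic else 0.0

    coords = [state.chain_positions(i) for i in rings]
    coms = np.array([c.mean(axis=0) for c in coords])
    radii = np.array([np.linalg.norm(c - com, axis=1).max()
                      for c, com in zip(coords, coms)])

    for a in range(len(rings)):
        for b in range(a + 1, len(rings)):
            report.n_ring_pairs += 1
            dv = coms[b] - coms[a]
            if periodic:
                dv = dv - L * np.round(dv / L)
            if np.linalg.norm(dv) > radii[a] + radii[b] + 1e-9:
                continue  # disjoint bounding spheres: unlinked
            cb = coords[b]
            if periodic:
                # bring ring b into ring a's image
                shift = dv - (cb.mean(axis=0) - coms[a])
                cb = cb + shift
            raw = linking_number(coords[a], cb)
            lk = int(round(raw))
            resid = abs(raw - lk)
            key = (rings[a], rings[b])
            report.pair_linking_numbers[key] = lk
            report.max_residual = max(report.max_residual, resid)
            if lk != 0 or resid > LK_RESIDUAL_TOL:
                report.flagged_pairs.append(key)
    return report


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def regular_polygon(n: int, bond_length: float = INIT_BOND_LENGTH,
                    center=(0.0, 0.0, 0.0),
                    normal=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Planar regular n-gon with the given bond length, center and normal."""
    if n < 3:
        raise ValueError("a ring needs at least 3 monomers")
    radius = bond_length / (2.0 * math.sin(math.pi / n))
    phi = 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                           np.zeros(n)])
    return _orient(pts, center, normal)


def _orient(pts: np.ndarray, center, normal) -> np.ndarray:
    """Rotate template points (built in the xy-plane, normal +z) so their
    normal becomes ``normal``, then translate to ``center``."""
    nx, ny, nz = (float(x) for x in normal)
    s = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / s, ny / s, nz / s
    if nz < -1.0 + 1e-12:
        rot = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
    else:
        # Rodrigues rotation taking z_hat to n, v = z_hat x n = (-ny, nx, 0)
        k = 1.0 / (1.0 + nz)
        rot = np.array([
            [1.0 - nx * nx * k, -nx * ny * k, nx],
            [-nx * ny * k, 1.0 - ny * ny * k, ny],
            [-nx, -ny, nz],
        ])
    return pts @ rot.T + np.asarray(center, float)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def maxwell_velocities(n: int, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities (m = 1) with total momentum zeroed."""
    v = rng.normal(scale=math.sqrt(temperature), size=(n, 3))
    return v - v.mean(axis=0)


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def _chain_template(kind: str, n: int, bond_length: float) -> np.ndarray:
    if kind == "ring":
        return regular_polygon(n, bond_length)
    # straight rod centred on the origin along +z
    z = (np.arange(n) - 0.5 * (n - 1)) * bond_length
    return np.column_stack([np.zeros(n), np.zeros(n), z])


def place_rings_in_sphere(topology: Topology, confinement: Confinement,
                          ff: ForceFieldParams = ForceFieldParams(),
                          seed: int = 0,
                          max_attempts: int = 20_000) -> SystemState:
    """Random, unlinked, overlap-free initial state.

    Each chain is dropped as a rigid template (planar polygon or rod) at a
    rejection-sampled random center + orientation: monomers must stay
    inside the accessible region, keep a minimum distance from already
    placed monomers, and (rings only) have zero linking number with every
    nearby placed ring.  A 500-step capped-WCA push-off then opens any
    sub-0.9 sigma contact before velocities are drawn at T* = 1.
    """
    rng = np.random.default_rng(seed)
    periodic = confinement.mode == "periodic_box"
    L = float(confinement.box_edge) if periodic else 0.0
    R = float(confinement.radius) if not periodic else 0.0

    # feasibility: monomer excluded volume must fit the cavity
    vol = confinement.volume
    packing = topology.n_monomers * (math.pi / 6.0) * ff.lj_sigma ** 3 / vol
    if packing > 0.45:
        raise PlacementError(
            f"requested composition implies packing fraction {packing:.2f}; "
            "rejection placement is infeasible above ~0.45")

    positions = np.empty((topology.n_monomers, 3))
    placed_rings: list[tuple[np.ndarray, np.ndarray, float]] = []  # pts, com, rad
    tree: cKDTree | None = None
    tree_pts: np.ndarray | None = None
    recent: list[np.ndarray] = []
    n_recent = 0

    # slot criterion: looser than the final 0.9 sigma contact distance —
    # the capped-WCA push-off ramp opens the remaining soft overlaps
    dmin = 0.85 * ff.lj_sigma
    n_placed_pts = 0

    for ci, ch in enumerate(topology.chains):
        template = _chain_template(ch.kind, ch.n_monomers, INIT_BOND_LENGTH)
        circ = float(np.linalg.norm(template, axis=1).max())
        placed = False
        local_dmin = dmin
        for attempt in range(max_attempts):
            if attempt and attempt % 4000 == 0:
                local_dmin = max(0.75 * ff.lj_sigma, local_dmin - 0.05)
            normal = _random_unit(rng)
            if periodic:
                center = rng.uniform(0.0, L, size=3)
            else:
                # center uniform in the sphere that keeps all monomers inside
                r_allow = R - ff.lj_sigma - 0.05 - circ
                if r_allow <= 0:
                    raise PlacementError(
                        f"chain {ci} (extent {circ:.2f}) cannot fit inside "
                        f"radius {R}")
                center = (_random_unit(rng)
                          * r_allow * rng.uniform() ** (1.0 / 3.0))
            cand = _orient(template, center, normal)

            # distance check against already placed monomers
            if n_placed_pts:
                if n_recent > 1500:
                    stack = [np.concatenate(recent)]
                    if tree_pts is not None:
                        stack.append(tree_pts)
                    tree_pts = np.concatenate(stack)
                    if periodic:
                        tree = cKDTree(np.mod(tree_pts, L), boxsize=L)
                    else:
                        tree = cKDTree(tree_pts)
                    recent = []
                    n_recent = 0
                ok = True
                if tree is not None:
                    q = np.mod(cand, L) if periodic else cand
                    if tree.query(q, k=1)[0].min() < local_dmin:
                        ok = False
                if ok and recent:
                    rec = np.concatenate(recent)
                    d = cand[:, None, :] - rec[None, :, :]
                    if periodic:
                        d -= L * np.round(d / L)
                    if np.min(np.linalg.norm(d, axis=-1)) < local_dmin:
                        ok = False
                if not ok:
                    continue

            # linking check against nearby placed rings
            if ch.kind == "ring":
                com = cand.mean(axis=0)
                linked = False
                for rpts, rcom, rrad in placed_rings:
                    dv = rcom - com
                    if periodic:
                        dv -= L * np.round(dv / L)
                    if np.linalg.norm(dv) > circ + rrad:
                        continue
                    other = rpts
                    if periodic:
                        other = rpts + (dv - (rcom - com))
                    if round(linking_number(cand, other)) != 0:
                        linked = True
                        break
                if linked:
                    continue

            sl = topology.chain_slice(ci)
            positions[sl] = cand
            recent.append(cand)
            n_recent += ch.n_monomers
            n_placed_pts += ch.n_monomers
            if ch.kind == "ring":
                placed_rings.append((cand, cand.mean(axis=0), circ))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"placement failed at chain {ci}/{len(topology.chains)} "
                f"({ci / len(topology.chains):.0%} placed) after "
                f"{max_attempts} attempts; density too high for rejection "
                "placement")

    positions = _pushoff(positions, topology, confinement, ff)

    velocities = maxwell_velocities(topology.n_monomers, 1.0, rng)
    state = SystemState(positions, velocities, 0.0, topology, confinement)
    return state


def _pushoff(positions: np.ndarray, topology: Topology,
             confinement: Confinement, ff: ForceFieldParams,
             n_steps: int = 500) -> np.ndarray:
    """Overdamped capped-WCA ramp removing residual overlaps."""
    from . import _kernels

    periodic = confinement.mode == "periodic_box"
    L = float(confinement.box_edge) if periodic else 0.0
    sphere = not periodic
    R = float(confinement.radius) if sphere else 0.0
    pos = np.ascontiguousarray(positions, float)
    mobile = np.ones(len(pos), np.uint8)
    for _ in range(4):
        status = _kernels.pushoff(
            pos, mobile, topology.bonds, topology.angles, topology.angle_k,
            periodic, L, sphere, R, ff.wall_epsilon,
            ff.fene_k, ff.fene_r0, ff.lj_epsilon, ff.lj_sigma, ff.lj_cutoff,
            n_steps, 20.0, 2000.0, 5e-4, 0.05)
        if status != _kernels.OK:
            raise PlacementError(f"push-off failed with status {status}")
        if _kernels.min_pair_distance(pos, periodic, L, R, mobile) >= 0.9:
            break
    return pos
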