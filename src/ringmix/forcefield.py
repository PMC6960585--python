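"""Energies and forces of the bead-spring model.

Three bonded/non-bonded terms plus the confining wall:

* FENE backbone springs, U(r) = -K R0^2/2 * ln(1 - (r/R0)^2),
* WCA excluded volume, U(r) = 4 eps [ (s/r)^12 - (s/r)^6 + 1/4 ] for
  r <= 2^(1/6) s, applied to bonded *and* non-bonded pairs,
* bending, U(theta) = K_b (1 + cos theta), with theta the interior angle
  at the middle monomer (pi for a straight chain, so stiff chains stay
  straight),
* a purely repulsive wall: the same WCA form on the radial gap R - |r|
  (smooth mode), or summed over explicit wall beads on a Fibonacci lattice
  of the confining sphere (particulate mode).

This module holds the readable NumPy reference path.  ``method="brute"``
evaluates all pairs directly; ``method="cell"`` routes through the
compiled cell-list kernels and must agree with brute force exactly
(asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Confinement, ForceFieldParams, SystemState

__all__ = [
    "EnergyBreakdown",
    "fene_energy",
    "wca_energy",
    "bending_energy",
    "wall_energy",
    "total_energy",
    "forces",
    "fibonacci_sphere",
    "equilibrium_bond_length",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term potential energies; ``total`` is their (fixed-order) sum."""

    fene: float
    pair: float
    bending: float
    wall: float

    @property
    def total(self) -> float:
        return self.fene + self.pair + self.bending + self.wall


# ---------------------------------------------------------------------------
# Scalar potentials
# ---------------------------------------------------------------------------

def fene_energy(r, ff: ForceFieldParams = ForceFieldParams()) -> float:
    """FENE bond energy; diverges (domain error) at r >= fene_r0."""
    r = np.asarray(r, float)
    x = (r / ff.fene_r0) ** 2
    if np.any(x >= 1.0):
        raise ValueError(
            f"bond length {float(np.max(r)):.4f} >= FENE maximum "
            f"extension {ff.fene_r0}")
    return -0.5 * ff.fene_k * ff.fene_r0 ** 2 * np.log(1.0 - x)


def wca_energy(r, ff: ForceFieldParams = ForceFieldParams(),
               epsilon: float | None = None) -> float:
    """Shifted, truncated LJ repulsion; exactly zero beyond the cutoff."""
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    eps = ff.lj_epsilon if epsilon is None else epsilon
    s6 = (ff.lj_sigma / r) ** 6
    u = 4.0 * eps * (s6 * s6 - s6 + 0.25)
    return np.where(r <= ff.lj_cutoff, u, 0.0)


def bending_energy(theta, kb: float) -> float:
    """K_b (1 + cos theta): zero when the two bonds are collinear."""
    theta = np.asarray(theta, float)
    return kb * (1.0 + np.cos(theta))


def fibonacci_sphere(radius: float, spacing: float = 1.0) -> np.ndarray:
    """Near-uniform bead lattice on a sphere (particulate wall surface)."""
    n = max(int(round(4.0 * np.pi * radius ** 2 / spacing ** 2)), 8)
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + 5.0 ** 0.5)
    theta = golden * i
    return radius * np.column_stack([np.sin(phi) * np.cos(theta),
                                     np.sin(phi) * np.sin(theta),
                                     np.cos(phi)])


def wall_energy(position, confinement: Confinement,
                ff: ForceFieldParams = ForceFieldParams(),
                wall_points: np.ndarray | None = None) -> float:
    """Repulsive wall energy for one monomer position.

    Smooth mode evaluates the WCA form on the gap d = R - |r| so monomer
    centers are confined to |r| <= R - sigma at thermal energies;
    particulate mode sums the WCA pair term over explicit wall beads.
    """
    if confinement.mode != "sphere":
        return 0.0
    position = np.asarray(position, float)
    r = float(np.linalg.norm(position))
    if r >= confinement.radius:
        raise ValueError(f"monomer at |r| = {r:.4f} outside the sphere "
                         f"R = {confinement.radius}")
    if confinement.wall_style == "smooth":
        gap = confinement.radius - r
        if gap > ff.lj_cutoff:
            return 0.0
        return float(wca_energy(gap, ff, epsilon=ff.wall_epsilon))
    if wall_points is None:
        wall_points = fibonacci_sphere(confinement.radius, ff.lj_sigma)
    d = np.linalg.norm(wall_points - position, axis=1)
    d = d[d <= ff.lj_cutoff]
    if d.size == 0:
        return 0.0
    return float(np.sum(wca_energy(d, ff, epsilon=ff.wall_epsilon)))


# ---------------------------------------------------------------------------
# System-level evaluation
# ---------------------------------------------------------------------------

def _pair_displacements(state: SystemState):
    """All-pairs displacement matrix with minimum image when periodic."""
    pos = state.positions
    d = pos[:, None, :] - pos[None, :, :]
    if state.confinement.mode == "periodic_box":
        L = state.confinement.box_edge
        d -= L * np.round(d / L)
    return d


def _bond_vectors(state: SystemState) -> np.ndarray:
    top = state.topology
    d = state.positions[top.bonds[:, 1]] - state.positions[top.bonds[:, 0]]
    if state.confinement.mode == "periodic_box":
        L = state.confinement.box_edge
        d -= L * np.round(d / L)
    return d


def total_energy(state: SystemState,
                 ff: ForceFieldParams = ForceFieldParams(),
                 method: str = "brute") -> EnergyBreakdown:
    """Per-term potential energy of a state.

    The WCA pair term runs over *all* monomer pairs within the cutoff,
    including bonded neighbours (which therefore feel FENE + WCA and sit
    near r = 0.97 sigma at equilibrium).
    """
    if method == "cell":
        from . import _kernels
        periodic = state.confinement.mode == "periodic_box"
        L = float(state.confinement.box_edge or 0.0) if periodic else 0.0
        sphere = state.confinement.mode == "sphere"
        pos, mobile = _kernel_arrays(state, ff)
        top = state.topology
        status, _, e = _kernels.evaluate(
            pos, top.bonds, top.angles, top.angle_k,
            ff.fene_k, ff.fene_r0, ff.lj_epsilon, ff.lj_sigma, ff.lj_cutoff,
            periodic, L, sphere and state.confinement.wall_style == "smooth",
            float(state.confinement.radius if sphere else 0.0),
            ff.wall_epsilon, mobile)
        _raise_status(status, e)
        wall = e[3]
        if sphere and state.confinement.wall_style == "particulate":
            wall = sum(wall_energy(p, state.confinement, ff)
                       for p in state.positions)
        return EnergyBreakdown(e[0], e[1], e[2], wall)

    top = state.topology
    # FENE
    blen = np.linalg.norm(_bond_vectors(state), axis=1)
    e_fene = float(np.sum(fene_energy(blen, ff))) if blen.size else 0.0
    # WCA over all pairs
    d = _pair_displacements(state)
    dist = np.linalg.norm(d, axis=-1)
    iu = np.triu_indices(len(dist), k=1)
    pd = dist[iu]
    within = pd <= ff.lj_cutoff
    e_pair = float(np.sum(wca_energy(pd[within], ff))) if within.any() else 0.0
    # bending
    e_bend = 0.0
    if top.angles.size:
        pos = state.positions
        b1 = pos[top.angles[:, 1]] - pos[top.angles[:, 0]]
        b2 = pos[top.angles[:, 2]] - pos[top.angles[:, 1]]
        if state.confinement.mode == "periodic_box":
            L = state.confinement.box_edge
            b1 -= L * np.round(b1 / L)
            b2 -= L * np.round(b2 / L)
        c = np.sum(b1 * b2, axis=1) / (np.linalg.norm(b1, axis=1)
                                       * np.linalg.norm(b2, axis=1))
        e_bend = float(np.sum(top.angle_k * (1.0 - c)))
    # wall
    e_wall = 0.0
    if state.confinement.mode == "sphere":
        wp = (fibonacci_sphere(state.confinement.radius, ff.lj_sigma)
              if state.confinement.wall_style == "particulate" else None)
        e_wall = float(sum(wall_energy(p, state.confinement, ff, wp)
                           for p in state.positions))
    return EnergyBreakdown(e_fene, e_pair, e_bend, e_wall)


def _kernel_arrays(state: SystemState, ff: ForceFieldParams):
    """Positions + mobility mask, appending wall beads in particulate mode."""
    pos = np.ascontiguousarray(state.positions)
    mobile = np.ones(len(pos), np.uint8)
    return pos, mobile


def _raise_status(status: int, energies) -> None:
    from . import _kernels as K
    if status == K.OK:
        return
    if status == K.FENE_OVERSTRETCH:
        raise ValueError(f"FENE bond {int(energies[4])} overstretched")
    if status == K.ESCAPED:
        raise ValueError(f"monomer {int(energies[4])} escaped the sphere")
    raise RuntimeError("neighbor list overflow")


def forces(state: SystemState, ff: ForceFieldParams = ForceFieldParams(),
           method: str = "cell") -> np.ndarray:
    """Analytic forces F = -grad U for every monomer.

    ``method="cell"`` uses the compiled cell-list kernels (the engine's
    path); ``method="brute"`` differentiates the same potentials over all
    pairs in NumPy and serves as the oracle for the kernel path.
    """
    top = state.topology
    conf = state.confinement
    periodic = conf.mode == "periodic_box"
    sphere = conf.mode == "sphere"

    if method == "cell":
        from . import _kernels
        pos, mobile = _kernel_arrays(state, ff)
        status, f, e = _kernels.evaluate(
            pos, top.bonds, top.angles, top.angle_k,
            ff.fene_k, ff.fene_r0, ff.lj_epsilon, ff.lj_sigma, ff.lj_cutoff,
            periodic, float(conf.box_edge or 0.0) if periodic else 0.0,
            sphere and conf.wall_style == "smooth",
            float(conf.radius if sphere else 0.0), ff.wall_epsilon, mobile)
        _raise_status(status, e)
        if sphere and conf.wall_style == "particulate":
            f = f + _particulate_wall_forces(state, ff)
        return f

    pos = state.positions
    n = len(pos)
    f = np.zeros((n, 3))
    # WCA pairs
    d = _pair_displacements(state)          # d[i,j] = r_i - r_j
    dist = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(dist, np.inf)
    mask = dist <= ff.lj_cutoff
    s6 = np.where(mask, (ff.lj_sigma / np.where(mask, dist, 1.0)) ** 6, 0.0)
    fmag = np.where(mask,
                    24.0 * ff.lj_epsilon * (2.0 * s6 * s6 - s6)
                    / np.where(mask, dist, 1.0) ** 2, 0.0)
    f += np.einsum("ij,ijk->ik", fmag, d)
    # FENE
    if top.bonds.size:
        bv = _bond_vectors(state)           # r_j - r_i for bond (i, j)
        r2 = np.sum(bv * bv, axis=1)
        x = r2 / ff.fene_r0 ** 2
        if np.any(x >= 1.0):
            raise ValueError("FENE bond overstretched")
        g = (ff.fene_k / (1.0 - x))[:, None] * bv
        np.add.at(f, top.bonds[:, 0], g)
        np.add.at(f, top.bonds[:, 1], -g)
    # bending
    if top.angles.size:
        b1 = pos[top.angles[:, 1]] - pos[top.angles[:, 0]]
        b2 = pos[top.angles[:, 2]] - pos[top.angles[:, 1]]
        if periodic:
            L = conf.box_edge
            b1 -= L * np.round(b1 / L)
            b2 -= L * np.round(b2 / L)
        n1 = np.linalg.norm(b1, axis=1, keepdims=True)
        n2 = np.linalg.norm(b2, axis=1, keepdims=True)
        u, v = b1 / n1, b2 / n2
        c = np.sum(u * v, axis=1, keepdims=True)
        kb = top.angle_k[:, None]
        fi = -kb * (v - c * u) / n1
        fk = kb * (u - c * v) / n2
        np.add.at(f, top.angles[:, 0], fi)
        np.add.at(f, top.angles[:, 2], fk)
        np.add.at(f, top.angles[:, 1], -(fi + fk))
    # wall
    if sphere:
        if conf.wall_style == "smooth":
            r = np.linalg.norm(pos, axis=1)
            if np.any(r >= conf.radius):
                raise ValueError("monomer escaped the sphere")
            gap = conf.radius - r
            act = (gap <= ff.lj_cutoff) & (r > 0)
            if act.any():
                s6w = (ff.lj_sigma / gap[act]) ** 6
                dudg = -24.0 * ff.wall_epsilon * (2.0 * s6w ** 2 - s6w) / gap[act]
                f[act] += (dudg / r[act])[:, None] * pos[act]
        else:
            f += _particulate_wall_forces(state, ff)
    return f


def _particulate_wall_forces(state: SystemState,
                             ff: ForceFieldParams) -> np.ndarray:
    wp = fibonacci_sphere(state.confinement.radius, ff.lj_sigma)
    pos = state.positions
    f = np.zeros_like(pos)
    for i, p in enumerate(pos):
        d = p - wp
        dist = np.linalg.norm(d, axis=1)
        m = dist <= ff.lj_cutoff
        if m.any():
            s6 = (ff.lj_sigma / dist[m]) ** 6
            fmag = 24.0 * ff.wall_epsilon * (2.0 * s6 ** 2 - s6) / dist[m] ** 2
            f[i] = np.sum(fmag[:, None] * d[m], axis=0)
    return f


def equilibrium_bond_length(ff: ForceFieldParams = ForceFieldParams()) -> float:
    """Bond length minimising FENE + WCA for an isolated bonded pair."""
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(
        lambda r: float(fene_energy(r, ff) + wca_energy(r, ff)),
        bounds=(0.5 * ff.lj_sigma, 0.999 * ff.fene_r0), method="bounded")
    return float(res.x)
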