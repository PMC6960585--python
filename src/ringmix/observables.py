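"""Analysis quantities for confined ring-polymer mixtures.

Radial density profiles, mean radial distances, the ring-normal nematic
order parameter P2, the tangential/radial velocity decomposition and its
peak density, the radial potential of mean force (PMF), and the
energy/entropy decomposition of the confinement free energy against a
bulk reference.

Conventions (reduced units, k_B*T = 1):

* The ring normal is n = sum_i b_i x b_{i+1} over consecutive bond
  vectors (wrap-around included), normalised — the director of a nearly
  planar ring.
* P2 = < (3 cos^2 theta' - 1)/2 > with cos theta' = |n . r_hat|, where
  r_hat points from the sphere centre to the chain's centre of mass.
  The absolute value reflects the nematic (sign-free) symmetry of the
  normal: 1 for wall-attached rings (normals radial), 0 isotropic, -0.5
  for normals tangential.
* PMF: V(r) = -ln p(r) with p the shell-normalised radial probability,
  shifted to zero at the innermost populated bin; empty bins are NaN.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import RadialProfile, SystemState, Trajectory

__all__ = [
    "RingGeometry",
    "VelocityDecomposition",
    "ring_normal",
    "ring_geometry",
    "gyration_radius",
    "orientation_order",
    "radial_density_profile",
    "density_profile_from_points",
    "mean_radial_distance",
    "velocity_decomposition",
    "critical_density",
    "pmf",
    "pmf_from_points",
    "energy_entropy_decomposition",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.25


@dataclass(frozen=True)
class RingGeometry:
    center_of_mass: np.ndarray
    normal: np.ndarray
    gyration_radius: float


@dataclass(frozen=True)
class VelocityDecomposition:
    """Mean speeds perpendicular and parallel to the ring normal."""

    v_perp: float
    v_par: float

    @property
    def ratio(self) -> float:
        if self.v_par == 0.0:
            return math.inf
        return self.v_perp / self.v_par


# ---------------------------------------------------------------------------
# Per-ring geometry
# ---------------------------------------------------------------------------

def ring_normal(ring_positions: np.ndarray) -> np.ndarray:
    """Unit normal of a closed polyline: normalised sum of cross products
    of consecutive bond vectors (orientation follows monomer order)."""
    pts = np.asarray(ring_positions, float)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("a ring needs at least 3 monomers")
    bonds = np.roll(pts, -1, axis=0) - pts
    n = np.sum(np.cross(bonds, np.roll(bonds, -1, axis=0)), axis=0)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("degenerate (collinear) ring: normal undefined")
    return n / norm


def gyration_radius(positions: np.ndarray) -> float:
    """Root-mean-square distance from the centroid of a point set."""
    pts = np.atleast_2d(np.asarray(positions, float))
    d = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def ring_geometry(ring_positions: np.ndarray) -> RingGeometry:
    pts = np.asarray(ring_positions, float)
    return RingGeometry(pts.mean(axis=0), ring_normal(pts),
                        gyration_radius(pts))


# ---------------------------------------------------------------------------
# Orientation order
# ---------------------------------------------------------------------------

def _frames(traj) -> list[SystemState]:
    if isinstance(traj, SystemState):
        return [traj]
    return list(traj)


def orientation_order(traj, species: str = "long") -> float:
    """Nematic order of ring normals relative to the radial direction.

    Second Legendre polynomial (3 cos^2 theta' - 1)/2 averaged over all
    ring chains of the species and all frames, with cos theta' =
    |n . r_hat| and r_hat the unit vector between sphere centre and chain
    centre of mass.  Chains whose centre of mass sits at the sphere
    centre have no radial direction and are skipped (logged).
    """
    vals = []
    for frame in _frames(traj):
        top = frame.topology
        for ci in top.chain_indices(species=species, kind="ring"):
            pts = frame.chain_positions(ci)
            com = pts.mean(axis=0)
            rnorm = np.linalg.norm(com)
            if rnorm < 1e-9:
                logger.warning("chain %d COM at sphere centre in frame "
                               "t=%.3f: skipped", ci, frame.time)
                continue
            c = abs(float(np.dot(ring_normal(pts), com / rnorm)))
            vals.append(1.5 * c * c - 0.5)
    if not vals:
        raise ValueError("no ring chains of the requested species")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Radial profiles
# ---------------------------------------------------------------------------

def _bin_edges(r_max: float, bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n = max(int(math.ceil(r_max / bin_width)), 1)
    return bin_width * np.arange(n + 1)


def _shell_volumes(edges: np.ndarray) -> np.ndarray:
    return 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)


def density_profile_from_points(radii: np.ndarray, n_frames: int,
                                mean_density: float, r_max: float,
                                bin_width: float = DEFAULT_BIN_WIDTH
                                ) -> RadialProfile:
    """Shell-normalised density of radial samples, reduced by
    ``mean_density`` so a uniform distribution reads 1 in every bin."""
    edges = _bin_edges(r_max, bin_width)
    counts, _ = np.histogram(radii, bins=edges)
    dens = counts / (_shell_volumes(edges) * n_frames)
    return RadialProfile(edges, dens / mean_density, "shell_density",
                         counts=counts)


def radial_density_profile(traj, species: str = "long",
                           bin_width: float = DEFAULT_BIN_WIDTH
                           ) -> RadialProfile:
    """Reduced monomer density rho(r)/rho_species of one species.

    The per-bin monomer count is divided by the shell volume and the
    number of frames, then by the species mean density (species monomer
    count over cavity volume): a uniformly spread species gives ~1.
    """
    frames = _frames(traj)
    conf = frames[0].confinement
    if conf.mode != "sphere":
        raise ValueError("radial profiles require sphere confinement")
    mask = frames[0].topology.species_mask(species)
    radii = np.concatenate([np.linalg.norm(f.positions[mask], axis=1)
                            for f in frames])
    rho_sp = mask.sum() / conf.volume
    return density_profile_from_points(radii, len(frames), rho_sp,
                                       conf.radius, bin_width)


def mean_radial_distance(traj, species: str = "long",
                         per: str = "monomer") -> float:
    """Time + ensemble mean distance from the sphere centre, over the
    species' monomers (``per="monomer"``) or chain centres of mass
    (``per="chain_com"``)."""
    frames = _frames(traj)
    vals = []
    for f in frames:
        top = f.topology
        if per == "monomer":
            pts = f.positions[top.species_mask(species)]
            vals.append(np.linalg.norm(pts, axis=1))
        elif per == "chain_com":
            coms = [f.chain_positions(ci).mean(axis=0)
                    for ci in top.chain_indices(species=species)]
            vals.append(np.linalg.norm(np.asarray(coms), axis=1))
        else:
            raise ValueError("per must be 'monomer' or 'chain_com'")
    return float(np.mean(np.concatenate(vals)))


# ---------------------------------------------------------------------------
# Velocity decomposition
# ---------------------------------------------------------------------------

def velocity_decomposition(traj: Trajectory, species: str = "long",
                           delta_t: float = 200.0) -> VelocityDecomposition:
    """Speed components of chain centre-of-mass motion relative to the
    ring normal, over lag delta_t (tau0).

    For each ring chain and frame pair (t, t + delta_t): d is the COM
    displacement, beta the angle between d and the chain normal at t;
    V_perp = |d| sin(beta)/delta_t and V_par = |d| cos(beta)/delta_t are
    averaged over chains and intervals (ratio of means, not mean of
    ratios).  delta_t must be an integer multiple of the trajectory's
    sampling interval.
    """
    lag = delta_t / traj.sampling_interval
    k = int(round(lag))
    if k < 1 or abs(lag - k) > 1e-8:
        raise ValueError(
            f"delta_t = {delta_t} is not a positive integer multiple of "
            f"the sampling interval {traj.sampling_interval}")
    if len(traj) <= k:
        raise ValueError("trajectory too short for the requested lag")
    top = traj.topology
    chains = top.chain_indices(species=species, kind="ring")
    if not chains:
        raise ValueError("no ring chains of the requested species")
    perp, par = [], []
    for t0 in range(len(traj) - k):
        f0, f1 = traj[t0], traj[t0 + k]
        for ci in chains:
            p0 = f0.chain_positions(ci)
            d = f1.chain_positions(ci).mean(axis=0) - p0.mean(axis=0)
            dn = np.linalg.norm(d)
            if dn == 0.0:
                perp.append(0.0)
                par.append(0.0)
                continue
            n = ring_normal(p0)
            c = abs(float(np.dot(d, n))) / dn
            c = min(c, 1.0)
            par.append(dn * c / delta_t)
            perp.append(dn * math.sqrt(1.0 - c * c) / delta_t)
    return VelocityDecomposition(float(np.mean(perp)), float(np.mean(par)))


def critical_density(samples) -> float:
    """Density at the maximum of the V_perp/V_par ratio.

    ``samples`` is a sequence of (rho, ratio) pairs.  An interior maximum
    is refined by the vertex of the parabola through the peak and its two
    neighbours; a boundary maximum is returned as-is with a warning.
    """
    pts = sorted(samples)
    if len(pts) < 3:
        raise ValueError("need at least 3 (rho, ratio) samples")
    rho = np.array([p[0] for p in pts], float)
    ratio = np.array([p[1] for p in pts], float)
    if len(np.unique(rho)) != len(rho):
        raise ValueError("rho values must be unique")
    i = int(np.argmax(ratio))
    if i == 0 or i == len(pts) - 1:
        warnings.warn("ratio maximum at the edge of the sampled density "
                      "range; no interior peak", stacklevel=2)
        return float(rho[i])
    x0, x1, x2 = rho[i - 1:i + 2]
    y0, y1, y2 = ratio[i - 1:i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate curvature: fall back to the grid maximum
        return float(rho[i])
    return float(-b / (2.0 * a))


# ---------------------------------------------------------------------------
# Potential of mean force
# ---------------------------------------------------------------------------

def pmf_from_points(radii: np.ndarray, r_max: float,
                    bin_width: float = DEFAULT_BIN_WIDTH) -> RadialProfile:
    """V(r) = -ln p(r) from radial samples (k_B*T = 1).

    p(r) is the histogram normalised by shell volume; the profile is
    shifted so the innermost populated bin is zero (the r -> 0 reference)
    and empty bins are NaN.
    """
    edges = _bin_edges(r_max, bin_width)
    counts, _ = np.histogram(radii, bins=edges)
    if counts.sum() == 0:
        raise ValueError("no samples: PMF undefined")
    p = counts / (_shell_volumes(edges) * counts.sum())
    v = np.full(len(counts), np.nan)
    pop = counts > 0
    v[pop] = -np.log(p[pop])
    v -= v[np.argmax(pop)]  # anchor at innermost populated bin
    return RadialProfile(edges, v, "pmf", counts=counts)


def pmf(traj, species: str = "long",
        bin_width: float = DEFAULT_BIN_WIDTH) -> RadialProfile:
    """Monomer potential of mean force of one species versus r."""
    frames = _frames(traj)
    conf = frames[0].confinement
    if conf.mode != "sphere":
        raise ValueError("PMF requires sphere confinement")
    mask = frames[0].topology.species_mask(species)
    radii = np.concatenate([np.linalg.norm(f.positions[mask], axis=1)
                            for f in frames])
    return pmf_from_points(radii, conf.radius, bin_width)


# ---------------------------------------------------------------------------
# Energy / entropy decomposition
# ---------------------------------------------------------------------------

def _chain_bending_energies(frame: SystemState, chains) -> np.ndarray:
    """Bending energy of each listed chain in one frame."""
    top = frame.topology
    pos = frame.positions
    periodic = frame.confinement.mode == "periodic_box"
    L = frame.confinement.box_edge if periodic else 0.0
    out = np.empty(len(chains))
    for k, ci in enumerate(chains):
        ch = top.chains[ci]
        pts = pos[top.chain_slice(ci)]
        b = np.roll(pts, -1, axis=0) - pts
        if periodic:
            b -= L * np.round(b / L)
        if ch.kind == "ring":
            b1, b2 = b, np.roll(b, -1, axis=0)
        else:
            b1, b2 = b[:-1], b[1:]
        c = np.sum(b1 * b2, axis=1) / (np.linalg.norm(b1, axis=1)
                                       * np.linalg.norm(b2, axis=1))
        out[k] = ch.bending_k * float(np.sum(1.0 - c))
    return out


def energy_entropy_decomposition(confined_traj: Trajectory,
                                 bulk_traj: Trajectory,
                                 species: str = "long",
                                 bin_width: float = DEFAULT_BIN_WIDTH
                                 ) -> tuple[RadialProfile, RadialProfile]:
    """Bending-energy and entropy contributions to the confinement free
    energy, versus chain-COM radial distance.

    delta_U_bend(r) = <U_bend | r>_confined - <U_bend>_bulk, binning each
    confined chain's bending energy by its centre-of-mass distance; the
    bulk reference is the mean over an unconfined (periodic) run at the
    same density and composition.  With delta_F(r) the chain-COM PMF of
    the confined run, T*delta_S(r) = delta_U_bend(r) - delta_F(r).
    """
    conf = confined_traj.confinement
    if bulk_traj.confinement.mode != "periodic_box":
        raise ValueError("bulk trajectory must be in periodic_box mode")
    # degenerate but well-defined case: a periodic "confined" input (e.g.
    # the bulk compared against itself) is binned by |COM| all the same
    r_max = (conf.radius if conf.mode == "sphere"
             else conf.box_edge * math.sqrt(3.0))
    ch_c = confined_traj.topology.chain_indices(species=species)
    ch_b = bulk_traj.topology.chain_indices(species=species)
    sig_c = [(confined_traj.topology.chains[i].kind,
              confined_traj.topology.chains[i].n_monomers,
              confined_traj.topology.chains[i].bending_k) for i in ch_c]
    sig_b = [(bulk_traj.topology.chains[i].kind,
              bulk_traj.topology.chains[i].n_monomers,
              bulk_traj.topology.chains[i].bending_k) for i in ch_b]
    if sorted(sig_c) != sorted(sig_b):
        raise ValueError("confined and bulk species compositions differ")

    edges = _bin_edges(r_max, bin_width)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, int)
    com_radii = []
    for frame in confined_traj:
        ub = _chain_bending_energies(frame, ch_c)
        coms = np.array([frame.chain_positions(ci).mean(axis=0)
                         for ci in ch_c])
        r = np.linalg.norm(coms, axis=1)
        com_radii.append(r)
        idx = np.clip(np.digitize(r, edges) - 1, 0, len(sums) - 1)
        np.add.at(sums, idx, ub)
        np.add.at(counts, idx, 1)

    bulk_mean = float(np.mean([_chain_bending_energies(f, ch_b).mean()
                               for f in bulk_traj]))

    du = np.full(len(sums), np.nan)
    pop = counts > 0
    du[pop] = sums[pop] / counts[pop] - bulk_mean
    du_profile = RadialProfile(edges, du, "energy", counts=counts)

    dF = pmf_from_points(np.concatenate(com_radii), r_max, bin_width)
    tds = du - dF.values
    tds_profile = RadialProfile(edges, tds, "entropy", counts=counts)
    return du_profile, tds_profile
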