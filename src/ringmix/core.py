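"""Domain types and configuration handling for ring-polymer mixture simulations.

All quantities are expressed in reduced Lennard-Jones units: the monomer
diameter sigma, the thermal energy k_B*T and the monomer mass m are all 1,
and the intrinsic time unit is tau0 = sqrt(m*sigma^2 / (k_B*T)) = 1.  No
conversion layer to physical units is provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ForceFieldParams",
    "ChainSpec",
    "Topology",
    "Confinement",
    "SystemState",
    "Trajectory",
    "RadialProfile",
    "ConfigError",
    "validate_config",
    "serialize_config",
]

#: WCA cutoff in units of sigma: the minimum of the 12-6 potential.
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

#: Radial tolerance allowed beyond the nominal accessible radius R - sigma
#: (thermal penetration into the soft repulsive wall).
WALL_TOLERANCE = 0.1


class ConfigError(ValueError):
    """Raised when a run configuration is missing or inconsistent."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Interaction constants of the bead-spring model.

    The bonded backbone uses a FENE spring (spring constant ``fene_k``,
    maximum extension ``fene_r0``); excluded volume between all monomer
    pairs — bonded and non-bonded alike — is the purely repulsive,
    shifted-and-truncated Lennard-Jones (WCA) potential; the confining
    wall repels monomers through the same WCA form with ``wall_epsilon``.
    """

    fene_k: float = 30.0        # k_BT / sigma^2
    fene_r0: float = 1.5        # sigma
    lj_epsilon: float = 1.0     # k_BT
    lj_sigma: float = 1.0       # sigma
    lj_cutoff: float = WCA_CUTOFF  # sigma; 2^(1/6)*lj_sigma for WCA
    wall_epsilon: float = 1.0   # k_BT

    def __post_init__(self) -> None:
        for name in ("fene_k", "fene_r0", "lj_epsilon", "lj_sigma",
                     "lj_cutoff", "wall_epsilon"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fene_r0 <= self.lj_sigma:
            raise ConfigError("fene_r0 must exceed lj_sigma")


@dataclass(frozen=True)
class ChainSpec:
    """One chain: closed ring or open linear, with its own stiffness."""

    kind: Literal["ring", "linear"]
    n_monomers: int
    bending_k: float
    species: Literal["long", "short"]

    def __post_init__(self) -> None:
        if self.kind not in ("ring", "linear"):
            raise ConfigError(f"unknown chain kind {self.kind!r}")
        if self.species not in ("long", "short"):
            raise ConfigError(f"unknown species {self.species!r}")
        if self.kind == "ring" and self.n_monomers < 3:
            raise ConfigError("rings need at least 3 monomers")
        if self.kind == "linear" and self.n_monomers < 2:
            raise ConfigError("linear chains need at least 2 monomers")
        if self.bending_k < 0:
            raise ConfigError("bending_k must be non-negative")


class Topology:
    """Ordered list of chains plus derived per-monomer index arrays.

    Bond and angle lists are derived from the chain kinds: a ring of N
    monomers closes with the bond (N-1, 0) and carries N bending angles;
    a linear chain of N monomers has N-1 bonds and N-2 angles.
    """

    def __init__(self, chains: Sequence[ChainSpec]):
        self.chains: tuple[ChainSpec, ...] = tuple(chains)
        if not self.chains:
            raise ConfigError("topology needs at least one chain")
        self._build()

    def _build(self) -> None:
        starts, bonds, angles, angle_k = [], [], [], []
        chain_id = []
        species = []
        offset = 0
        for ci, ch in enumerate(self.chains):
            starts.append(offset)
            n = ch.n_monomers
            idx = np.arange(offset, offset + n)
            if ch.kind == "ring":
                bonds.append(np.column_stack([idx, np.roll(idx, -1)]))
                angles.append(np.column_stack(
                    [np.roll(idx, 1), idx, np.roll(idx, -1)]))
                angle_k.append(np.full(n, ch.bending_k))
            else:
                bonds.append(np.column_stack([idx[:-1], idx[1:]]))
                if n >= 3:
                    angles.append(np.column_stack([idx[:-2], idx[1:-1], idx[2:]]))
                    angle_k.append(np.full(n - 2, ch.bending_k))
            chain_id.append(np.full(n, ci))
            species.append(np.full(n, 0 if ch.species == "long" else 1,
                                   dtype=np.int8))
            offset += n
        self.n_monomers: int = offset
        self.chain_starts = np.asarray(starts, dtype=np.int64)
        self.bonds = (np.concatenate(bonds).astype(np.int64)
                      if bonds else np.empty((0, 2), np.int64))
        if angles:
            self.angles = np.concatenate(angles).astype(np.int64)
            self.angle_k = np.concatenate(angle_k).astype(np.float64)
        else:
            self.angles = np.empty((0, 3), np.int64)
            self.angle_k = np.empty(0, np.float64)
        self.chain_id = np.concatenate(chain_id).astype(np.int64)
        self.species_code = np.concatenate(species)  # 0 = long, 1 = short

    # -- convenience views -------------------------------------------------
    def chain_slice(self, i: int) -> slice:
        start = self.chain_starts[i]
        return slice(start, start + self.chains[i].n_monomers)

    def chain_indices(self, species: str | None = None,
                      kind: str | None = None) -> list[int]:
        out = []
        for i, ch in enumerate(self.chains):
            if species is not None and ch.species != species:
                continue
            if kind is not None and ch.kind != kind:
                continue
            out.append(i)
        return out

    def species_mask(self, species: str) -> np.ndarray:
        if species == "all":
            return np.ones(self.n_monomers, bool)
        code = 0 if species == "long" else 1
        return self.species_code == code

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Topology) and self.chains == other.chains

    def __repr__(self) -> str:
        n_ring = sum(c.kind == "ring" for c in self.chains)
        return (f"Topology({len(self.chains)} chains, {n_ring} rings, "
                f"{self.n_monomers} monomers)")


@dataclass(frozen=True)
class Confinement:
    """Hard-sphere cavity (soft repulsive wall) or periodic cubic box."""

    mode: Literal["sphere", "periodic_box"] = "sphere"
    radius: float = 20.0            # sphere mode, sigma
    box_edge: float | None = None   # periodic_box mode, sigma
    wall_style: Literal["smooth", "particulate"] = "smooth"

    def __post_init__(self) -> None:
        if self.mode == "sphere":
            if self.radius <= 0:
                raise ConfigError("sphere radius must be positive")
        elif self.mode == "periodic_box":
            if not self.box_edge or self.box_edge <= 0:
                raise ConfigError("periodic_box requires positive box_edge")
        else:
            raise ConfigError(f"unknown confinement mode {self.mode!r}")

    @property
    def volume(self) -> float:
        if self.mode == "sphere":
            return 4.0 / 3.0 * math.pi * self.radius ** 3
        return float(self.box_edge) ** 3


@dataclass
class SystemState:
    """Monomer coordinates and velocities of one instant.

    Invariants (checked by :meth:`validate`): finite coordinates, every
    bond shorter than the FENE maximum extension, and, in sphere mode,
    every monomer inside the accessible radius R - sigma (plus a small
    thermal tolerance for penetration into the soft wall).
    """

    positions: np.ndarray      # (N, 3)
    velocities: np.ndarray     # (N, 3)
    time: float
    topology: Topology
    confinement: Confinement

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        n = self.topology.n_monomers
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions/velocities shape does not match topology")

    def chain_positions(self, i: int) -> np.ndarray:
        return self.positions[self.topology.chain_slice(i)]

    def validate(self, ff: ForceFieldParams | None = None) -> None:
        """Raise ValueError if any state invariant is violated."""
        ff = ff or ForceFieldParams()
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("non-finite velocities")
        if self.topology.bonds.size:
            d = self.positions[self.topology.bonds[:, 1]] - \
                self.positions[self.topology.bonds[:, 0]]
            if self.confinement.mode == "periodic_box":
                L = self.confinement.box_edge
                d -= L * np.round(d / L)
            blen = np.linalg.norm(d, axis=1)
            if np.any(blen >= ff.fene_r0):
                worst = int(np.argmax(blen))
                raise ValueError(
                    f"bond {worst} overstretched: {blen[worst]:.4f} >= "
                    f"{ff.fene_r0}")
        if self.confinement.mode == "sphere":
            r = np.linalg.norm(self.positions, axis=1)
            limit = self.confinement.radius - ff.lj_sigma + WALL_TOLERANCE
            if np.any(r > limit):
                raise ValueError(
                    f"monomer outside accessible radius: max |r| = "
                    f"{r.max():.4f} > {limit:.4f}")

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.time, self.topology, self.confinement)


class Trajectory:
    """Time-ordered frames at a constant sampling interval (in tau0)."""

    def __init__(self, frames: Sequence[SystemState],
                 sampling_interval: float):
        self.frames: list[SystemState] = list(frames)
        self.sampling_interval = float(sampling_interval)
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8):
                raise ValueError("frame times must increase with constant spacing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> SystemState:
        return self.frames[i]

    @property
    def topology(self) -> Topology:
        return self.frames[0].topology

    @property
    def confinement(self) -> Confinement:
        return self.frames[0].confinement

    def positions_array(self) -> np.ndarray:
        """All frame coordinates stacked as (n_frames, N, 3)."""
        return np.stack([f.positions for f in self.frames])


@dataclass
class RadialProfile:
    """Per-shell values of a radial observable.

    ``normalization`` tags the meaning of ``values``: reduced shell
    density, potential of mean force, bending-energy difference or
    entropy difference.  Masked (undefined) bins hold NaN.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    normalization: Literal["shell_density", "pmf", "energy", "entropy"]
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.values = np.asarray(self.values, float)
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values must have one entry per bin")
        if self.bin_edges[0] < 0 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must start at >= 0 and increase")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_SYSTEM = dict(
    rho=0.4, n_long=50, m_long=10, n_short=10,
    kb_long=50.0, kb_short=50.0, long_kind="ring",
)

#: Highest total number density the model is meant for; beyond this the
#: excluded-volume pressure starts deforming the rings.
RHO_MAX = 0.6


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ConfigError(f"missing field {where}.{key}")
    return d[key]


def validate_config(raw: dict) -> tuple[ForceFieldParams, Topology,
                                        Confinement, dict]:
    """Turn a raw config document into typed objects.

    The document has top-level keys ``system``, ``forcefield``,
    ``schedule`` and (optionally) ``output`` and ``seed``.  The number of
    short chains is derived from the requested total number density
    rho = (M_long*N_long + M_short*N_short)/V unless given explicitly.

    Returns ``(forcefield, topology, confinement, schedule_dict)``; the
    schedule dict retains the seed and output section so a run can be
    reproduced from it alone.
    """
    from . import builder  # local import: builder depends on core

    if "system" not in raw:
        raise ConfigError("missing field system")
    sys_d = {**_DEFAULT_SYSTEM, **raw["system"]}

    conf_d = sys_d.get("confinement", {"mode": "sphere", "radius": 20.0})
    mode = conf_d.get("mode", "sphere")
    if mode == "sphere":
        confinement = Confinement(mode="sphere",
                                  radius=float(conf_d.get("radius", 20.0)),
                                  wall_style=conf_d.get("wall_style", "smooth"))
    else:
        confinement = Confinement(mode="periodic_box",
                                  box_edge=float(_require(conf_d, "box_edge",
                                                          "confinement")))

    rho = float(_require(sys_d, "rho", "system"))
    if rho <= 0:
        raise ConfigError("system.rho must be positive")
    if rho > RHO_MAX:
        warnings.warn(
            f"rho = {rho} exceeds {RHO_MAX}, the highest density the model "
            "is intended for; rings may deform", stacklevel=2)

    n_long = int(sys_d["n_long"])
    m_long = int(sys_d["m_long"])
    n_short = int(sys_d["n_short"])
    for name, v in (("n_long", n_long), ("m_long", m_long),
                    ("n_short", n_short)):
        if v <= 0:
            raise ConfigError(f"system.{name} must be positive")

    if "m_short" in sys_d:
        m_short = int(sys_d["m_short"])
    else:
        m_short = builder.count_short_chains(rho, confinement, m_long,
                                             n_long, n_short)

    long_kind = sys_d.get("long_kind", "ring")
    chains = [ChainSpec(long_kind, n_long, float(sys_d["kb_long"]), "long")
              for _ in range(m_long)]
    chains += [ChainSpec("ring", n_short, float(sys_d["kb_short"]), "short")
               for _ in range(m_short)]
    topology = Topology(chains)

    ff_d = raw.get("forcefield", {})
    ff = ForceFieldParams(
        fene_k=float(ff_d.get("fene_k", 30.0)),
        fene_r0=float(ff_d.get("fene_r0", 1.5)),
        lj_epsilon=float(ff_d.get("lj_epsilon", 1.0)),
        lj_sigma=float(ff_d.get("lj_sigma", 1.0)),
        lj_cutoff=float(ff_d.get("lj_cutoff",
                                 WCA_CUTOFF * float(ff_d.get("lj_sigma", 1.0)))),
        wall_epsilon=float(ff_d.get("wall_epsilon", 1.0)),
    )

    schedule = dict(raw.get("schedule", {}))
    schedule.setdefault("timestep", 0.006)
    schedule.setdefault("equilibration_time", 0.0)
    schedule.setdefault("production_time", 0.0)
    schedule.setdefault("sample_interval", 10_000)
    schedule["seed"] = int(raw.get("seed", 0))
    schedule["rho"] = rho
    achieved = (m_long * n_long + m_short * n_short) / confinement.volume
    schedule["achieved_rho"] = achieved
    if "output" in raw:
        schedule["output"] = raw["output"]
    return ff, topology, confinement, schedule


def serialize_config(ff: ForceFieldParams, topology: Topology,
                     confinement: Confinement, schedule: dict) -> dict:
    """Inverse of :func:`validate_config` (round-trips to the same objects)."""
    longs = topology.chain_indices(species="long")
    shorts = topology.chain_indices(species="short")
    first_long = topology.chains[longs[0]]
    system = dict(
        rho=schedule.get("rho"),
        n_long=first_long.n_monomers,
        m_long=len(longs),
        kb_long=first_long.bending_k,
        long_kind=first_long.kind,
    )
    if shorts:
        first_short = topology.chains[shorts[0]]
        system.update(n_short=first_short.n_monomers, m_short=len(shorts),
                      kb_short=first_short.bending_k)
    if confinement.mode == "sphere":
        system["confinement"] = dict(mode="sphere", radius=confinement.radius,
                                     wall_style=confinement.wall_style)
    else:
        system["confinement"] = dict(mode="periodic_box",
                                     box_edge=confinement.box_edge)
    doc = dict(
        system=system,
        forcefield=dict(fene_k=ff.fene_k, fene_r0=ff.fene_r0,
                        lj_epsilon=ff.lj_epsilon, lj_sigma=ff.lj_sigma,
                        lj_cutoff=ff.lj_cutoff, wall_epsilon=ff.wall_epsilon),
        schedule={k: v for k, v in schedule.items()
                  if k not in ("seed", "rho", "achieved_rho", "output")},
        seed=schedule.get("seed", 0),
    )
    if "output" in schedule:
        doc["output"] = schedule["output"]
    return doc
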