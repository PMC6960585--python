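"""Trajectory, profile and config file formats.

Trajectories are plain-text XYZ (one block per frame) or LAMMPS dump
("ITEM:" headers, ``id mol type x y z vx vy vz`` columns, molecule id =
chain index + 1, type 1/2 = long/short species); restart states go to
LAMMPS data files.  Coordinates are written with 17 significant digits so
a write -> read round trip is bit-faithful.  Radial profiles export to
CSV with columns r_lo, r_hi, value, count; run manifests to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import (Confinement, ForceFieldParams, RadialProfile, SystemState,
                   Topology, Trajectory)

__all__ = [
    "ResultsManifest",
    "write_trajectory",
    "read_trajectory",
    "write_lammps_data",
    "write_profile_csv",
    "read_profile_csv",
    "load_config",
    "save_config",
]

_F = "%.17g"


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj, path, format: str = "lammps_dump") -> Path:
    """Write a Trajectory (or a single state) as XYZ or LAMMPS dump."""
    frames = [traj] if isinstance(traj, SystemState) else list(traj)
    interval = (traj.sampling_interval
                if isinstance(traj, Trajectory) else 0.0)
    path = Path(path)
    with open(path, "w") as fh:
        if format == "xyz":
            if not frames:
                fh.write("0\nempty trajectory\n")
            for f in frames:
                fh.write(f"{len(f.positions)}\n")
                fh.write(f"time={f.time!r} sampling_interval={interval!r}\n")
                for code, p in zip(f.topology.species_code, f.positions):
                    el = "C" if code == 0 else "O"  # long / short species
                    fh.write(("%s " + _F + " " + _F + " " + _F + "\n")
                             % (el, p[0], p[1], p[2]))
        elif format == "lammps_dump":
            if not frames:
                fh.write("ITEM: TIMESTEP\n0\nITEM: NUMBER OF ATOMS\n0\n")
            for k, f in enumerate(frames):
                conf = f.confinement
                if conf.mode == "sphere":
                    lo, hi = -conf.radius, conf.radius
                else:
                    lo, hi = 0.0, conf.box_edge
                fh.write("ITEM: TIMESTEP\n%d\n" % k)
                fh.write("ITEM: TIME\n" + (_F % f.time) + "\n")
                fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % len(f.positions))
                fh.write("ITEM: BOX BOUNDS pp pp pp\n")
                for _ in range(3):
                    fh.write((_F + " " + _F + "\n") % (lo, hi))
                fh.write("ITEM: ATOMS id mol type x y z vx vy vz\n")
                top = f.topology
                for i, (p, v) in enumerate(zip(f.positions, f.velocities)):
                    fh.write(("%d %d %d " + " ".join([_F] * 6) + "\n")
                             % (i + 1, top.chain_id[i] + 1,
                                top.species_code[i] + 1,
                                p[0], p[1], p[2], v[0], v[1], v[2]))
        else:
            raise ValueError(f"unknown trajectory format {format!r}")
    return path


def read_trajectory(path, topology: Topology, confinement: Confinement,
                    format: str | None = None,
                    sampling_interval: float | None = None) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Topology and confinement are not stored in either format and must be
    supplied; molecule ids in dumps are checked against the topology.
    """
    path = Path(path)
    if format is None:
        format = "xyz" if path.suffix == ".xyz" else "lammps_dump"
    text = path.read_text().splitlines()
    frames: list[SystemState] = []
    n = topology.n_monomers
    interval = sampling_interval

    if format == "xyz":
        i = 0
        while i < len(text):
            count = int(text[i])
            comment = text[i + 1]
            t = 0.0
            for tok in comment.split():
                if tok.startswith("time="):
                    t = float(tok[5:])
                if interval is None and tok.startswith("sampling_interval="):
                    interval = float(tok.split("=")[1])
            if count == 0:
                i += 2
                continue
            if count != n:
                raise ValueError(f"frame has {count} atoms, topology {n}")
            block = text[i + 2:i + 2 + count]
            pos = np.array([[float(x) for x in ln.split()[1:4]]
                            for ln in block])
            frames.append(SystemState(pos, np.zeros_like(pos), t,
                                      topology, confinement))
            i += 2 + count
    elif format == "lammps_dump":
        i = 0
        t = 0.0
        while i < len(text):
            line = text[i]
            if line.startswith("ITEM: TIME") and "TIMESTEP" not in line:
                t = float(text[i + 1])
                i += 2
            elif line.startswith("ITEM: NUMBER OF ATOMS"):
                count = int(text[i + 1])
                i += 2
            elif line.startswith("ITEM: ATOMS"):
                cols = line.split()[2:]
                if count == 0:
                    i += 1
                    continue
                if count != n:
                    raise ValueError(
                        f"frame has {count} atoms, topology {n}")
                rows = [text[i + 1 + k].split() for k in range(count)]
                i += 1 + count
                data = {c: np.array([float(r[j]) for r in rows])
                        for j, c in enumerate(cols)}
                order = np.argsort(data["id"])
                pos = np.column_stack([data["x"], data["y"],
                                       data["z"]])[order]
                if "vx" in data:
                    vel = np.column_stack([data["vx"], data["vy"],
                                           data["vz"]])[order]
                else:
                    vel = np.zeros_like(pos)
                mol = data["mol"].astype(int)[order] - 1
                if not np.array_equal(mol, topology.chain_id):
                    raise ValueError("molecule ids do not match topology")
                frames.append(SystemState(pos, vel, t, topology,
                                          confinement))
                t += 1.0  # placeholder cadence if no TIME items present
            else:
                i += 1
    else:
        raise ValueError(f"unknown trajectory format {format!r}")

    if interval is None:
        times = [f.time for f in frames]
        interval = times[1] - times[0] if len(times) > 1 else 1.0
    return Trajectory(frames, interval)


def write_lammps_data(state: SystemState, path,
                      ff: ForceFieldParams = ForceFieldParams()) -> Path:
    """Restart file in LAMMPS data format (atom style: angle)."""
    top = state.topology
    conf = state.confinement
    if conf.mode == "sphere":
        lo, hi = -conf.radius, conf.radius
    else:
        lo, hi = 0.0, conf.box_edge
    path = Path(path)
    kbs = sorted({c.bending_k for c in top.chains})
    angle_type = {kb: i + 1 for i, kb in enumerate(kbs)}
    with open(path, "w") as fh:
        fh.write("ring-polymer mixture restart\n\n")
        fh.write(f"{top.n_monomers} atoms\n{len(top.bonds)} bonds\n"
                 f"{len(top.angles)} angles\n\n")
        fh.write(f"2 atom types\n1 bond types\n{len(kbs)} angle types\n\n")
        for ax in "xyz":
            fh.write((_F + " " + _F + f" {ax}lo {ax}hi\n") % (lo, hi))
        fh.write("\nMasses\n\n1 1.0\n2 1.0\n\nAtoms\n\n")
        for i, p in enumerate(state.positions):
            fh.write(("%d %d %d " + " ".join([_F] * 3) + "\n")
                     % (i + 1, top.chain_id[i] + 1,
                        top.species_code[i] + 1, p[0], p[1], p[2]))
        fh.write("\nVelocities\n\n")
        for i, v in enumerate(state.velocities):
            fh.write(("%d " + " ".join([_F] * 3) + "\n")
                     % (i + 1, v[0], v[1], v[2]))
        fh.write("\nBonds\n\n")
        for b, (i, j) in enumerate(top.bonds):
            fh.write("%d 1 %d %d\n" % (b + 1, i + 1, j + 1))
        if len(top.angles):
            fh.write("\nAngles\n\n")
            for a, (i, j, k) in enumerate(top.angles):
                fh.write("%d %d %d %d %d\n"
                         % (a + 1, angle_type[top.angle_k[a]],
                            i + 1, j + 1, k + 1))
    return path


# ---------------------------------------------------------------------------
# Profiles, configs, manifests
# ---------------------------------------------------------------------------

def write_profile_csv(profile: RadialProfile, path) -> Path:
    path = Path(path)
    counts = (profile.counts if profile.counts is not None
              else np.zeros(len(profile.values), int))
    with open(path, "w") as fh:
        fh.write(f"# normalization={profile.normalization}\n")
        fh.write("r_lo,r_hi,value,count\n")
        for lo, hi, v, c in zip(profile.bin_edges[:-1], profile.bin_edges[1:],
                                profile.values, counts):
            fh.write((_F + "," + _F + "," + _F + ",%d\n") % (lo, hi, v, int(c)))
    return path


def read_profile_csv(path) -> RadialProfile:
    lines = Path(path).read_text().splitlines()
    norm = "shell_density"
    if lines[0].startswith("#"):
        norm = lines[0].split("=", 1)[1].strip()
        lines = lines[1:]
    rows = [ln.split(",") for ln in lines[1:] if ln.strip()]
    lo = np.array([float(r[0]) for r in rows])
    hi = np.array([float(r[1]) for r in rows])
    vals = np.array([float(r[2]) for r in rows])
    counts = np.array([int(r[3]) for r in rows])
    edges = np.append(lo, hi[-1])
    return RadialProfile(edges, vals, norm, counts=counts)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(doc: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


@dataclass
class ResultsManifest:
    """Everything needed to regenerate a set of outputs: the resolved
    config, the seed(s) and the per-observable output files/values."""

    config: dict
    seed: int
    entries: dict = field(default_factory=dict)
    software_version: str = ""
    wall_clock_s: float | None = None

    def add(self, name: str, **info) -> None:
        self.entries[name] = info

    def save(self, path) -> Path:
        path = Path(path)
        from . import __version__
        payload = dict(config=self.config, seed=self.seed,
                       entries=self.entries,
                       software_version=self.software_version or __version__,
                       wall_clock_s=self.wall_clock_s)
        path.write_text(json.dumps(payload, indent=2, default=_jsonify))
        return path

    @classmethod
    def load(cls, path) -> "ResultsManifest":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], seed=d["seed"], entries=d["entries"],
                   software_version=d.get("software_version", ""),
                   wall_clock_s=d.get("wall_clock_s"))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)
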