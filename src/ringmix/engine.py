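"""NVT / NVE integration.

Velocity-Verlet with an optional single-variable Nose-Hoover thermostat
targeting the reduced temperature T* (default 1.0).  The thermostat
coupling mass is Q = 3N * T* * (100 dt)^2, i.e. a damping period of about
100 timesteps.  Reheat-annealing is expressed as a ladder of (T*,
duration) stages run before the equilibration segment.

Production trajectories are sampled at a fixed step interval; the Gauss
linking numbers of all ring pairs are verified on the final frame, since
the FENE maximum extension forbids chain crossing in between — a
topology violation there means the timestep was too large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .builder import verify_topology
from .core import (Confinement, ForceFieldParams, SystemState, Trajectory)

__all__ = ["RunSchedule", "instantaneous_temperature", "step", "run",
           "is_equilibrated", "TopologyViolation"]


class TopologyViolation(RuntimeError):
    """A ring pair became linked during a run (chain crossing)."""


@dataclass
class RunSchedule:
    """Timestep, durations (in tau0) and sampling cadence of one run."""

    timestep: float = 0.006
    equilibration_time: float = 0.0
    production_time: float = 0.0
    sample_interval: int = 10_000          # steps between samples
    anneal: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0
    temperature: float = 1.0
    thermostat: bool = True

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.equilibration_time < 0 or self.production_time < 0:
            raise ValueError("durations must be non-negative")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")

    def steps(self, duration: float) -> int:
        return int(round(duration / self.timestep))


def instantaneous_temperature(state: SystemState) -> float:
    """Kinetic temperature sum(m v^2) / (3N - 3), momentum modes removed."""
    v = state.velocities
    n = len(v)
    if n < 2:
        raise ValueError("temperature undefined for fewer than 2 monomers")
    return float(np.sum(v * v) / (3 * n - 3))


def _geometry(conf: Confinement):
    periodic = conf.mode == "periodic_box"
    L = float(conf.box_edge) if periodic else 0.0
    sphere = (not periodic) and conf.wall_style == "smooth"
    R = float(conf.radius) if not periodic else 0.0
    return periodic, L, sphere, R


def _with_wall_beads(state: SystemState, ff: ForceFieldParams):
    """Positions/velocities with frozen wall beads appended (particulate)."""
    from .forcefield import fibonacci_sphere
    wall = fibonacci_sphere(state.confinement.radius, ff.lj_sigma)
    pos = np.concatenate([state.positions, wall])
    vel = np.concatenate([state.velocities, np.zeros_like(wall)])
    mobile = np.concatenate([np.ones(len(state.positions), np.uint8),
                             np.zeros(len(wall), np.uint8)])
    return pos, vel, mobile


def _nh_mass(n: int, temperature: float, dt: float) -> float:
    return 3.0 * n * temperature * (100.0 * dt) ** 2


def _raise_md_status(status: int, diag: float, step_no: int | None = None):
    from . import _kernels as K
    where = "" if step_no is None else f" near step {step_no}"
    if status == K.FENE_OVERSTRETCH:
        raise ValueError(
            f"FENE bond {int(diag)} overstretched{where}: integration "
            "blow-up, reduce the timestep")
    if status == K.ESCAPED:
        raise ValueError(f"monomer {int(diag)} escaped the sphere{where}")
    if status == K.NEIGHBOR_OVERFLOW:
        raise RuntimeError("neighbor-list buffer overflow")


def step(state: SystemState, ff: ForceFieldParams, dt: float = 0.006,
         thermostat: bool = False, temperature: float = 1.0,
         xi: float = 0.0) -> SystemState:
    """Advance one velocity-Verlet step; returns a new state.

    With ``thermostat`` a Nose-Hoover friction starting at ``xi`` is
    applied (the updated friction is discarded — use :func:`run` for
    sustained thermostatted dynamics).
    """
    from . import _kernels
    periodic, L, sphere, R = _geometry(state.confinement)
    if state.confinement.mode == "sphere" and \
            state.confinement.wall_style == "particulate":
        pos, vel, mobile = _with_wall_beads(state, ff)
        sphere = False
    else:
        pos = state.positions.copy()
        vel = state.velocities.copy()
        mobile = np.ones(len(pos), np.uint8)
    top = state.topology
    n_mob = int(mobile.sum())
    empty = np.empty((0, len(pos), 3))
    status, _, _, diag = _kernels.md_run(
        pos, vel, mobile, top.bonds, top.angles, top.angle_k,
        periodic, L, sphere, R, ff.wall_epsilon,
        ff.fene_k, ff.fene_r0, ff.lj_epsilon, ff.lj_sigma, ff.lj_cutoff,
        dt, 1, thermostat, temperature,
        _nh_mass(n_mob, temperature, dt), xi,
        0.4, 0, empty, empty)
    _raise_md_status(status, diag)
    n = state.topology.n_monomers
    return SystemState(pos[:n], vel[:n], state.time + dt,
                       state.topology, state.confinement)


def run(initial: SystemState, ff: ForceFieldParams,
        schedule: RunSchedule, check_topology: bool = True) -> Trajectory:
    """Annealing + equilibration + sampled production run.

    Frames are recorded every ``sample_interval`` steps of the production
    segment.  Metadata (schedule, seed, achieved mean temperature,
    topology report) is attached to the trajectory as ``traj.metadata``.
    """
    from . import _kernels

    state = initial
    periodic, L, sphere, R = _geometry(state.confinement)
    particulate = (state.confinement.mode == "sphere"
                   and state.confinement.wall_style == "particulate")
    if particulate:
        pos, vel, mobile = _with_wall_beads(state, ff)
        sphere = False
    else:
        pos = state.positions.copy()
        vel = state.velocities.copy()
        mobile = np.ones(len(pos), np.uint8)
    top = state.topology
    n = top.n_monomers
    n_mob = int(mobile.sum())
    dt = schedule.timestep
    xi = 0.0
    empty = np.empty((0, len(pos), 3))

    def _segment(n_steps, thermostat, T, sample_every, sp, sv):
        nonlocal xi
        status, xi, n_samp, diag = _kernels.md_run(
            pos, vel, mobile, top.bonds, top.angles, top.angle_k,
            periodic, L, sphere, R, ff.wall_epsilon,
            ff.fene_k, ff.fene_r0, ff.lj_epsilon, ff.lj_sigma, ff.lj_cutoff,
            dt, n_steps, thermostat, T, _nh_mass(n_mob, T, dt), xi,
            0.4, sample_every, sp, sv)
        _raise_md_status(status, diag)
        return n_samp

    # annealing ladder
    for T_stage, duration in schedule.anneal:
        _segment(schedule.steps(duration), schedule.thermostat, T_stage,
                 0, empty, empty)
        xi = 0.0  # re-zero friction between target changes

    # equilibration
    eq_steps = schedule.steps(schedule.equilibration_time)
    if eq_steps:
        _segment(eq_steps, schedule.thermostat, schedule.temperature,
                 0, empty, empty)

    # production with sampling
    prod_steps = schedule.steps(schedule.production_time)
    n_samples = prod_steps // schedule.sample_interval
    sample_pos = np.empty((n_samples, len(pos), 3))
    sample_vel = np.empty((n_samples, len(pos), 3))
    got = 0
    if prod_steps:
        got = _segment(prod_steps, schedule.thermostat,
                       schedule.temperature, schedule.sample_interval,
                       sample_pos, sample_vel)

    t0 = state.time + dt * (sum(schedule.steps(d) for _, d in schedule.anneal)
                            + eq_steps)
    interval_tau = schedule.sample_interval * dt
    frames = [SystemState(sample_pos[k, :n], sample_vel[k, :n],
                          t0 + (k + 1) * interval_tau,
                          top, state.confinement)
              for k in range(got)]
    traj = Trajectory(frames, interval_tau)

    temps = [instantaneous_temperature(f) for f in frames] or [
        float(np.sum(vel[mobile.astype(bool)] ** 2) / (3 * n_mob - 3))]
    report = None
    if check_topology and frames and top.chain_indices(kind="ring"):
        report = verify_topology(frames[-1])
        if not report.all_unlinked:
            raise TopologyViolation(
                f"linked ring pairs on final frame: {report.flagged_pairs}; "
                "a chain crossing occurred (timestep too large)")
    traj.metadata = {
        "schedule": schedule,
        "seed": schedule.seed,
        "mean_temperature": float(np.mean(temps)),
        "topology_report": report,
        "final_state": SystemState(pos[:n].copy(), vel[:n].copy(),
                                   t0 + prod_steps * dt, top,
                                   state.confinement),
    }
    return traj


def is_equilibrated(series: np.ndarray, confidence: float = 0.95) -> bool:
    """Plateau test: zero slope of a linear fit to the last half of a
    time series (e.g. the long-species mean radial distance) at the given
    confidence level."""
    from scipy import stats
    series = np.asarray(series, float)
    half = series[len(series) // 2:]
    if len(half) < 3:
        return False
    x = np.arange(len(half), dtype=float)
    res = stats.linregress(x, half)
    if res.stderr == 0:
        return True
    t = abs(res.slope) / res.stderr
    crit = stats.t.ppf(0.5 + confidence / 2.0, len(half) - 2)
    return bool(t < crit)
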