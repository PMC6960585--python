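# ringmix

Coarse-grained molecular dynamics and analysis of binary semiflexible
**ring-polymer mixtures in spherical confinement**, in reduced
Lennard-Jones units (k\_BT = σ = m = τ₀ = 1).

Long and short bead-spring rings (FENE bonds, WCA excluded volume, cosine
bending stiffness) are built unknotted and non-concatenated inside a
repulsive spherical cavity (or a periodic box for bulk references),
integrated under NVT with a Nosé–Hoover thermostat, and analysed for the
observables that characterise entropy-driven segregation of stiff long
rings to the wall: radial density profiles, the nematic orientation order
of ring normals, tangential/radial velocity decomposition, radial
potentials of mean force, and a bending-energy/entropy decomposition
against a bulk reference.

## Quick start (library)

```python
from ringmix import (ChainSpec, Confinement, ForceFieldParams, RunSchedule,
                     Topology, place_rings_in_sphere, run, observables)

ff = ForceFieldParams()                       # FENE K=30, R0=1.5; WCA; wall
top = Topology([ChainSpec("ring", 20, 50.0, "long")] * 3
               + [ChainSpec("ring", 5, 50.0, "short")] * 100)
conf = Confinement(mode="sphere", radius=10.0)

state = place_rings_in_sphere(top, conf, ff, seed=1)   # unlinked start
sched = RunSchedule(timestep=0.006, equilibration_time=600.0,
                    production_time=2400.0, sample_interval=2000)
traj = run(state, ff, sched)                  # NVT, topology-checked

print(observables.mean_radial_distance(traj, "long"))
print(observables.orientation_order(traj, "long"))     # P2 of ring normals
profile = observables.radial_density_profile(traj, "long")
```

## Quick start (CLI)

```bash
ringmix build   --config run.yaml --out init.dump     # initial state
ringmix run     --config run.yaml --out traj.dump     # build + simulate
ringmix analyze p2      --traj traj.dump --config run.yaml
ringmix analyze density --traj traj.dump --config run.yaml --out rho.csv
ringmix sweep   --config run.yaml --axis kb_long --values 0,25,50,100 \
                --seeds 1,2,3 --out sweep_out/
ringmix fixtures wall-attached --m 10 --n 50 --reach 19 --out wall.xyz
```

A config is a YAML document:

```yaml
system:
  rho: 0.4                       # total monomer number density
  confinement: {mode: sphere, radius: 10.0}
  n_long: 20                     # monomers per long ring
  m_long: 3                      # number of long rings
  n_short: 5                     # monomers per short ring (count derived
  kb_long: 50.0                  #   from rho unless m_short is given)
  kb_short: 50.0
schedule:
  timestep: 0.006
  equilibration_time: 600.0      # tau0
  production_time: 2400.0
  sample_interval: 2000          # steps between samples
seed: 1
```

## Package layout

| module | contents |
|---|---|
| `ringmix.core` | domain types (`ForceFieldParams`, `Topology`, `SystemState`, `Trajectory`, `RadialProfile`), config validation |
| `ringmix.builder` | unlinked initial-state construction, Gauss linking numbers, topology verification |
| `ringmix.forcefield` | FENE/WCA/bending/wall energies and analytic forces (NumPy reference + compiled cell-list path) |
| `ringmix.engine` | velocity-Verlet NVE/NVT integration, Nosé–Hoover thermostat, annealing schedules |
| `ringmix.observables` | density profiles, P2 orientation order, velocity decomposition, PMF, energy/entropy decomposition |
| `ringmix.fixtures` | synthetic configurations with known answers (rigid rings, Hopf links, Boltzmann samplers) |
| `ringmix.io`, `ringmix.cli`, `ringmix.pipeline` | XYZ/LAMMPS-dump/CSV/YAML/JSON formats, `ringmix` CLI, sweeps |

See `docs/methods.md` for the model equations, integration scheme,
conventions and analysis definitions.

## Tests

```bash
pytest -q            # full suite; the segregation-trend battery in
                     # tests/test_acceptance.py runs ~7 simulations of
                     # 5e5 steps and dominates the runtime (~15 min on 1 CPU)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
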