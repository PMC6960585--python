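# Methods

All quantities are in reduced Lennard-Jones units: monomer diameter σ,
thermal energy k\_BT and monomer mass m are 1, and the time unit is
τ₀ = (mσ²/k\_BT)^½. No conversion to physical units is provided.

## Model

Each polymer is a bead-spring chain; rings close on themselves. Three
bonded/non-bonded terms plus the confining wall:

**FENE backbone bonds**

U\_FENE(r) = −½ K R₀² ln[1 − (r/R₀)²],  K = 30 k\_BT/σ², R₀ = 1.5 σ.

The divergence at R₀ keeps bonds short enough that chains can never cross,
so ring topology (knotting/linking state) is conserved by the dynamics.

**WCA excluded volume** (all monomer pairs, bonded and non-bonded)

U\_WCA(r) = 4ε[(σ/r)¹² − (σ/r)⁶ + ¼] for r ≤ 2^(1/6) σ, else 0; ε = 1 k\_BT.

With both terms an isolated bonded pair minimises energy at r ≈ 0.961 σ.

**Bending stiffness**

U\_bend(θ) = K\_b (1 + cos θ), with θ the interior angle at each monomer
(θ = π for a straight chain ⇒ zero energy). Rings of N monomers carry N
angles; linear chains N−2. K\_b = 0 is fully flexible; K\_b ≈ 100 makes an
N = 20 ring effectively rigid.

**Confinement.** Sphere mode applies the same WCA form to the radial gap
d = R − |r| with ε\_wall = 1, a smooth purely repulsive wall: the potential
reaches 1 k\_BT at |r| = R − σ, so R − σ is the accessible (thermal) radius.
A particulate wall (explicit frozen beads on a Fibonacci lattice of the
sphere) is available as an alternative. Bulk references use a periodic
cubic box with minimum-image convention.

## Initial states

Chains are placed as rigid templates (planar regular polygons at bond
length 0.97 σ, or straight rods) with rejection-sampled random centres and
orientations: all monomers inside the accessible region, minimum distance
0.85 σ (relaxed gradually if placement stalls) to already placed monomers,
and — for rings — zero Gauss linking number with every geometrically
nearby placed ring. A short overdamped push-off with a force-capped WCA
ramp then opens residual contacts to ≥ 0.9 σ before Maxwell–Boltzmann
velocities (total momentum zero) are drawn. Starts are therefore unknotted
(polygons), non-concatenated (checked) and overlap-free.

## Integration

Velocity Verlet at Δt = 0.006 τ₀ with a single-variable Nosé–Hoover
thermostat in the symmetric (Martyna–Tuckerman–Klein) splitting: each step
applies a thermostat half-step (ξ updated from the on-step kinetic energy,
velocities scaled by e^(−ξΔt/2)), a half kick, the drift, a force
evaluation, the second half kick, and the mirrored thermostat half-step.
The coupling mass is Q = 3N T\* (100 Δt)², i.e. a ~100-step damping
period; the kinetic temperature uses 3N − 3 degrees of freedom (total
momentum removed at initialisation). With the thermostat off the scheme is
symplectic NVE (relative energy drift ≈ 2–4 × 10⁻⁵ over 10⁴ steps on
thermalised states).

Non-bonded interactions use a Verlet pair list (skin 0.4 σ) built by a
counting-sort cell list, rebuilt whenever the fastest particle has moved
more than half the skin; the compiled (numba) kernel path is verified
against an all-pairs NumPy reference to ≤ 10⁻⁹.

Runs follow an optional annealing ladder (T\* stages), an equilibration
segment, and a sampled production segment. On the final frame the Gauss
linking numbers of all ring pairs are re-verified; since FENE prevents
crossing, a violation there flags an integration blow-up.

## Topology

The Gauss linking number of two closed polylines is evaluated exactly with
the Klenin–Langowski solid-angle formula, summing the signed solid angle
subtended by every segment pair: 0 for unlinked rings, ±1 for a Hopf link,
invariant under rigid motions and discretisation refinement. Pairs whose
bounding spheres do not overlap are unlinked by geometry and skipped.

## Observables

* **Ring normal** n: normalised sum of cross products of consecutive bond
  vectors (wrap-around included) — the director of a nearly planar ring.
* **Orientation order** P2 = ⟨(3 cos²θ′ − 1)/2⟩ with cos θ′ = |n · r̂|,
  r̂ the unit vector from the sphere centre to the chain centre of mass:
  1 for wall-attached rings (normals radial), 0 isotropic, −0.5 tangential.
* **Radial density profile**: per-species monomer counts per shell volume
  and frame, reduced by the species mean density (uniform ⇒ 1 per bin).
* **Velocity decomposition**: over lag δt, each chain's centre-of-mass
  displacement d is split against its ring normal at the interval start;
  V\_∥ = |d| cos β/δt, V\_⊥ = |d| sin β/δt, averaged over chains and
  intervals (ratio of means). The V\_⊥/V\_∥ peak versus density marks the
  homogeneous-to-segregated transition (critical density from the parabola
  through the peak and its neighbours).
* **PMF**: V(r) = −ln p(r) (k\_BT = 1) with p the shell-normalised radial
  probability, anchored to zero at the innermost populated bin; empty bins
  are NaN. A PMF is defined up to an additive constant.
* **Energy/entropy decomposition**: ΔU\_bend(r) = ⟨U\_bend | r⟩\_confined −
  ⟨U\_bend⟩\_bulk, binning each confined chain's bending energy by its COM
  radius against an unconfined (periodic-box) run at the same density and
  composition; with ΔF(r) the chain-COM PMF, TΔS(r) = ΔU\_bend(r) − ΔF(r).
  A negative ΔU\_bend at the wall shows stiff rings relax their bending
  energy by lying flat against the curvature-matched surface, while the
  mixture's total entropy gain drives the segregation.

## Geometry anchors used in tests

A perfect rigid ring of N beads at bead-contact bond length b = 1 σ is a
regular N-gon of circumradius b / (2 sin(π/N)); its gyration radius equals
that circumradius (7.963 σ for N = 50). A ring lying flat against the
accessible shell at reach 19 σ (R = 20) has COM distance
√(19² − 7.963²) = 17.25 σ.
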