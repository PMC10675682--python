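# Methods

## The model

`slitdpd` simulates semi-dilute solutions of short amphiphilic diblock
copolymers — flexible A₅B₅ chains in a solvent S that is good for the A
block and poor for the B block — with dissipative particle dynamics
(DPD), in fully periodic bulk boxes and in slits bounded by two parallel
walls of tunable affinity for the insoluble block.

All quantities are in DPD reduced units: the pair-force cutoff r_c is
the length unit, kT the energy unit, the common bead mass m₀ the mass
unit, and τ = (m₀ r_c²/kT)^½ the time unit.  The force on a bead is a
sum over pairs within r_c of

* a soft conservative repulsion F^C = a_ij (1 − r) r̂,
* a dissipative friction force F^D = −γ w_D(r) (r̂·v_ij) r̂ with
  w_D = (1 − r)²,
* a random force F^R = σ w_R(r) θ Δt^−½ r̂ with w_R = 1 − r,

plus harmonic bond springs U = (K/2)(r − r₀)² between chain neighbours
and, in slits, a soft wall potential (below).  The dissipative and
random forces form the thermostat; the fluctuation–dissipation relation
σ² = 2γkT is enforced at construction time, so the default γ = 4.5 and
kT = 1 give σ = 3 exactly.

Repulsion amplitudes map linearly to Flory–Huggins interaction
parameters for bead density ρ r_c³ = 3:

    a_ij = a_ii + 3.27 χ_ij ,     a_ii = 25.

Compatible species (χ = 0) therefore interact at 25, the θ-state
(χ = ½) at 26.64, and a_ij = 40 describes a strongly unfavourable
χ = 4.59.

## Default parameter set

| parameter | value | meaning |
|---|---|---|
| ρ | 3 | bead number density (beads/r_c³) |
| Δt | 0.05 τ | timestep |
| γ, σ | 4.5, 3 | thermostat friction and noise |
| K, r₀ | 4, 0 | bond stiffness and rest length |
| a_AA = a_BB = a_SS = a_AS | 25 | athermal like/compatible pairs |
| a_AB = a_BS | 40 | selective solvent: χ ≈ 4.59 for the B block |
| a_AW = a_SW | 25 | wall athermal for corona and solvent |
| a_BW | 30 / 25 / 20 / 15 | slightly repulsive / inert / slightly / strongly attractive wall |
| a_wall, x_c | 25, 1.2 | soft wall-potential amplitude and range |

The interaction table is fully overridable through the INI
configuration; the four a_BW presets are exposed as named wall
scenarios.  r₀ = 0 with K = 4 is taken literally: the spring always
pulls bonded beads together and the equilibrium bond length emerges
from the balance with the soft repulsion (≈ 0.8–0.9 r_c at ρ = 3).
Users whose convention is U = K(r − r₀)² should double K.

Concentration is the softness-aware volume percentage
c = 100·N·n/(ρV) with n = 10 beads per chain; in slits V = D·Ly·Lz so
chain counts at fixed c scale with the slit width D.

## Slit geometry and walls

Walls are perpendicular to x; the reflecting planes sit at x = ±D/2 and
periodicity applies along y and z only.  Three mechanisms act together:

1. **Hard specular reflection** — a bead crossing a plane has its normal
   velocity inverted, tangential components untouched, and its position
   mirrored (kinetic energy conserved).
2. **Soft wall potential** U(x) = (a_wall·x_c/2)(1 − x/x_c)² for
   distances x < x_c from a plane, giving a linear inward force
   a_wall (1 − x/x_c).  With a_wall = 25 and x_c = 1.2 for all species it
   suppresses the density oscillations a hard wall would imprint.  The
   typeset source of this potential is ambiguous about its exponent; the
   quadratic form is adopted because it yields the linear soft force
   consistent with DPD conventions, and it is isolated behind
   `engine.wall_force` for easy substitution.
3. **Frozen wall beads** — one random slab of species W per side,
   thickness 1 r_c at density ρ_wall = 3, immediately outside each
   plane.  One slab suffices because all pair forces cut off at r_c.
   Wall beads interact with mobile beads through the interaction table
   (this is where a_BW acts) but never move; wall–wall pairs are
   skipped.

## Integration

The modified velocity-Verlet of Groot and Warren with λ = 0.65 — the
standard companion to σ = 3, γ = 4.5, Δt = 0.05:

    x ← x + Δt v + ½Δt² f
    ṽ = v + λ Δt f
    f′ = f(x, ṽ)
    v ← v + ½Δt (f + f′)

Pair search is a counting-sort cell list (cell edge ≥ r_c) rebuilt at
every force evaluation.  The random variate θ is uniform on
[−√3, √3] (zero mean, unit variance) and is drawn once per interacting
pair per force evaluation from an inline 64-bit LCG seeded per step, so
F^R is exactly antisymmetric and momentum is conserved to machine
precision; the long-run mean kinetic temperature of the standard
parameter set stays within a few percent of 1, the documented drift of
this integrator at Δt = 0.05.  Exact bead overlaps (r = 0) have no
defined force direction; they receive zero pair force and are counted
in the run log.  Runs are bit-reproducible given the master seed.

## Aggregate and adsorption criteria

Two beads on different chains form a **contact pair** when their
minimum-image distance is below r_c.  Two chains belong to the same
**aggregate** when they share at least three B–B contact pairs; the
aggregates of a frame are the connected components of this chain graph
(thresholds 1–4 are supported; 3 is the default).  Unimers are
aggregates of size one.  Clustering is per-frame; no temporal identity
is tracked, since observables are averaged over configurations sampled
every `sample_period` steps.

A chain is **wall-contacting** when at least three of its B beads lie
within r_c of a reflecting plane; an aggregate is **adsorbed** when it
contains at least one wall-contacting chain, otherwise free.  The
plane-distance reading of "in contact with the wall" mirrors the
bead–bead contact rule and is independent of the random wall-bead
placement; a wall-bead-proximity mode (`mode="beads"`) is available.

## Observables

**Association-number distributions.**  For pooled aggregate counts
c(A): F_n(A) = c(A)/Σc, F_w(A) = A·c(A)/ΣA·c, number and weight
averages ⟨A⟩_n = ΣA F_n and ⟨A⟩_w = ΣA²c/ΣAc.  The unimer fraction f₁
is F_n(1); f_low additionally sums the low associates up to the first
interior minimum of the smoothed F_n (centred moving average, window 3
bins; ties resolve to the smallest A).  The main-peak/tail split of F_w
is the maximum of the discrete second derivative of the smoothed F_w
beyond its mode — where the convex shoulder of the micelle peak hands
over to the slowly decaying tail of elongated associates.  For a pure
Gaussian peak this lands near μ + √3σ (the curvature maximum of a
Gaussian), leaving ~4% of mass in the "tail"; distributions whose
weight peaks at A = 1 or that are monotone return the largest A with a
warning.  The smoothing window is configurable; derivative-based
split points are inherently window-sensitive, so the window is reported
alongside results rather than hidden.

**Shape analysis.**  Aggregate coordinates are first unwrapped across
periodic boundaries by traversing the intra-aggregate contact network
and placing each newly reached bead at its minimum-image position
relative to an already-placed neighbour (unique up to translation;
aggregates spanning more than half a periodic box length are flagged as
ambiguous).  The gyration tensor S = (1/N)Σ(rᵢ−r̄)(rᵢ−r̄)ᵀ is then
diagonalised; the ordered eigenvalues λ₁² ≤ λ₂² ≤ λ₃² are reported
("diagonal components" in the principal frame — lab-frame diagonals are
basis-dependent and average poorly over isotropic ensembles, but a
`mode="diagonal"` option returns them).  Beads are unweighted (all
masses are 1).  Size scaling λ ∝ A_S^a is fitted by least squares on
log–log over a stated A_S window; compact homogeneous spheres give
a = 1/3, rods of fixed diameter approach a = 1 for the long axis.

**Density profiles.**  Across-slit profiles histogram mobile beads of a
species over x and normalise by slab volume (default bin 0.25 r_c —
fine enough to resolve micelle-scale structure without starving bins at
desk scale); profile integrals recover per-frame bead counts exactly.
Directional scans project positions onto a unit vector and fold them
onto one period of the projected lattice (the positive generator of
{Σ nᵢ Lᵢ uᵢ}, found by floating-point gcd) — well-defined for
axis-aligned and rational-diagonal directions, which are the ones used
to detect layering and lamellar motifs.  Wall coverage ρ_c counts B
beads within a stated width (default 1 r_c, matching the wall-contact
rule) of each plane per unit wall area.  Layer counting reports
prominent interior maxima of the smoothed profile (prominence
≥ 0.1 × max); boundary-hugging adsorption layers are deliberately not
counted as layers — wall coverage is the right observable for those.

## Synthetic fixtures

The planted generators produce configurations with exact ground truth
so that every analysis stage is testable without dynamics:

* `plant_micelle` — B beads uniform in a ball, A beads in a shell;
* `plant_rod` — each chain's B block a compact blob at a stratified
  anchor along a cylinder axis (chains in a cylindrical core are
  locally segregated; uniform scattering would not satisfy the
  pairwise three-contact criterion for long rods), A beads in the
  surrounding annulus;
* `plant_pancake` — B beads within a thin slab hugging one wall,
  guaranteeing the adsorption criterion when the slab is thinner than
  the wall-contact cutoff.

All generators verify their guarantees by rejection (re-drawing until
the clustering/adsorption criteria provably hold) rather than by
analytical construction — simpler and correct by definition.  What they
emulate is geometry only: planted objects have uniform cores, no
corona–solvent interpenetration and no thermal roughness, so passing
recovery tests validates the *criteria and estimators*, not the
thermodynamics of real trajectories.

## Scaled-down scenarios and problem sizes

Full-scale studies of this system use 25³ boxes (46,875 beads) and
10⁷-step equilibration — far beyond a test suite.  The named scenarios
(`bulk-small`, `slit-inert`, `slit-repulsive`, `slit-weak-attract`,
`slit-strong-attract`) keep every physical parameter (ρ = 3,
c = 25.6 %, the full interaction presets) but shrink the geometry to a
12³ box or a D = 10 × 12² slit (5,184 beads), where micellization and
adsorption develop from random initial conditions within a few 10⁴
steps.  The scenario default schedule is 2×10⁵ steps; the acceptance
tests run 2×10⁴ pre-equilibration + 4×10⁴ production steps, sampling
every 4×10³ — the qualitative wall-affinity phenomenology (B density
maxima adjacent to both walls and adsorbed > free for a_BW = 15;
interior maximum and a depleted wall-contact layer for inert walls) is
fully developed at that length.  A 12-wide box fits only a handful of
micelles (core diameter ≈ 3–4 r_c), so scenario distributions are far
noisier than full-scale ones; they support qualitative claims only.

The "near-zero wall coverage" check for inert walls reads the contact
layer (0.5 r_c from the plane), where the soft wall potential depletes
the density several-fold below the slit average; at c = 25.6 % the
1-r_c layer is *not* empty even for inert walls — the insoluble block
mildly prefers an athermal wall over a poor solvent, a real feature of
the model, not an artifact.

## Numerical choices and degenerate inputs

* Clustering ties and ordering: aggregates are reported sorted by their
  lowest chain id; minima/curvature maxima resolve ties to the smallest
  A_S for reproducibility.
* Exact overlaps get zero conservative/random force (direction
  undefined) and are counted.
* `chains_for_concentration` rounds to the nearest integer chain count
  and warns when the target is not exactly realisable (always within
  one chain).
* Trajectory text serialisation uses 17 significant digits, making
  read∘write bit-exact for positions and velocities.
* Periodic boxes must be ≥ 3 r_c per periodic dimension (cell-list
  half-stencil correctness); slits must be wider than 2 x_c.

## Known limitations

* No electrostatics; neutral systems only.
* kT = 1 only (the FDT check assumes it; no temperature ramps).
* Directional scans require directions whose projected lattice has a
  finite period (axis-aligned or rational diagonals).
* The unwrap is ambiguous for aggregates spanning more than half a
  periodic box length (flagged with a warning); percolating structures
  need a different estimator.
* Aggregate identity is not tracked over time; exchange kinetics are
  out of scope.
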