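# Methods

## The model

`memwrap` simulates the passive wrapping (endocytosis) of a rigid,
ligand-decorated nanosphere by a coarse-grained, implicit-solvent lipid
bilayer, with the explicit goal of quantifying the *ligand valency* — how
many membrane receptors bind one nanoparticle ligand — under two
interchangeable ligand-receptor coupling schemes.

All quantities are in reduced Lennard-Jones units (ε energy, σ length,
τ time, m mass; the package's reporting calibration is σ = 0.9 nm,
τ = 1 ns).

### Lipids

Each lipid is the standard three-bead implicit-solvent model: one head
bead and two tail beads, joined by FENE bonds

    U_FENE(r) = -1/2 K₁ R₀² ln[1 - (r/R₀)²] + U_WCA(r),
    K₁ = 30 ε/σ², R₀ = 1.5 σ,

straightened by a harmonic angle U(θ) = K₂ (θ - θ₀)² with K₂ = 10 ε/rad²
and θ₀ = 180°.  Excluded volume between all beads is the WCA potential

    U_WCA(r) = 4ε[(b/r)¹² - (b/r)⁶] + ε  for r < 2^(1/6) b, else 0,

with b = 0.95 σ for head-head and head-tail pairs and b = 1.0 σ for
tail-tail pairs (the sizing that yields a flat, tensionless bilayer with no
intrinsic curvature).  Bilayer cohesion is the broad cosine-squared
tail-tail attraction

    U_cos(r) = -ε                                for r ≤ r_c,
             = -ε cos²[π (r - r_c) / (2 w_c)]    for r_c < r ≤ r_c + w_c,
             = 0                                 beyond,

with r_c = 2^(1/6) σ and w_c = 1.5 σ at k_BT = 1 ε.  Nanoparticle surface
beads (plain and ligand) are purely repulsive toward everything
(b = 0.95 σ), so the particle volume is excluded but only ligands adhere.

### Ligand-receptor coupling: one potential, two schemes

Receptors are ordinary lipids whose head bead carries an extra short-range
attraction to ligand beads: the same cosine-squared well, scaled to
molecular contact range — onset r_c_LR = 2^(1/6) σ, width w_c_LR = 0.45 σ,
and depth ε_LR = 20 ε unless stated.  The onset is pinned by internal
consistency: with it the well still holds 1.25 ε at the 1.5 σ bond-rupture
separation used below.

* **Pair mode** applies this well between *every* ligand/receptor-head
  pair.  Nothing limits how many receptors crowd one ligand; the valency
  is an uncontrolled outcome of curvature, coverage and ε_LR.
* **Bond mode** applies the *identical* potential only through explicit
  bonds.  Once per timestep, (1) every live bond longer than
  r_break = 1.5 σ is removed, then (2) every unbound ligand/receptor pair
  within r_form = 2 σ is visited in seeded random order and forms a bond
  with probability p_form = 0.5 while both partners are below the valence
  cap (1 per ligand and per receptor by default).  Rupture runs before
  formation, so a bond created in (1.5 σ, 2 σ] survives until the next
  step's check; beyond the well support (≈1.572 σ) such a bond carries no
  energy or force.  At depth 20 ε the 1.25 ε rupture energy is far above
  thermal fluctuations, so accidental dissociation is negligible.

The well can also be exported as a textual (r, U, F) bond table in the
standard MD-engine format (2000 points by default, force from the analytic
derivative), so the identical scheme can be run in a reference engine.

### Dynamics

Langevin dynamics at k_BT = 1 ε with velocity relaxation time damp = 1 τ
and timestep dt = 0.01 τ, integrated with the BAOAB splitting of velocity
Verlet (plain velocity Verlet when the thermostat is off).  The
nanoparticle is one rigid body: per-bead forces are summed into a net
force and torque; the body carries six degrees of freedom with an
isotropic moment of inertia (exact to a fraction of a percent for the
near-uniform Fibonacci shell); the thermostat refresh acts on its
center-of-mass and angular velocities with the same rate as on free beads,
equivalent to summing per-bead Langevin forces over the body.

Kinetic temperature is reported from mid-step (post-refresh) velocities.
The on-step estimator under-reads by ≈2% at dt = 0.01 τ because of the
stiff FENE/WCA modes (a pure discretization artifact, absent in a WCA gas);
the mid-step estimator reduces this to a few tenths of a percent.

The zero-tension membrane condition is maintained by a first-order
(Berendsen-type) lateral barostat: each step, Lx and Ly (coupled jointly)
and all in-plane coordinates are rescaled by
μ = 1 + (dt / 2 pdamp) · Σ / kA_ref, where Σ = (P_lat − P_target)·Lz is
the measured lateral tension and kA_ref = 15 ε/σ² is a reference area
modulus; the actual relaxation time is pdamp times the ratio of the true
area modulus to kA_ref, i.e. of order pdamp.  This is a deliberate
simplification of a Nosé–Hoover chain barostat: the contract is zero mean
lateral tension, not the microscopic NPT ensemble (area fluctuations are
mildly suppressed; the equilibrium area per lipid is unaffected).  The
production default is pdamp = 10³ τ; desk-scale runs use pdamp = 50 τ so
the box relaxes well within a few hundred τ.  Lz stays fixed (≥ 60 σ, so
the membrane never sees its periodic image).

Nonbonded interactions are evaluated over a linked-cell Verlet list
(skin 0.4 σ, rebuilt when the two largest bead displacements sum past
the skin).
Inside the force kernel the cosine attractions are looked up in
per-species-pair tables on a uniform r² grid (4096 nodes, energy linearly
interpolated, force taken as the exact negative gradient of the
interpolant so the kernel is conservative by construction; table error
≲ 2×10⁻⁵ ε).  WCA, FENE and angle terms are analytic.

## Builders

* **Membrane**: two leaflets of n/2 three-bead lipids on a near-square
  lattice at an initial area per lipid of 1.2 σ² (slightly expanded; the
  barostat compresses it to the tensionless equilibrium, ≈1.13–1.16 σ²
  depending on patch size).  Receptors are a seeded uniform random subset
  of the nanoparticle-facing leaflet, count = floor(fraction × n/2); with
  this reading, 20% receptors on the 10,452-lipid membrane gives exactly
  the published 1045.  A switch selects the whole-membrane reading
  instead.
* **Nanosphere**: N_surface = floor(4πR²) beads on a Fibonacci
  (golden-angle) spherical lattice — deterministic, all beads exactly at
  radius R, median nearest-neighbor spacing ≈1 σ.  Ligands are a seeded
  uniform random subset, count = floor(coverage × N_surface); R = 12 σ at
  50% coverage gives the published 904 ligands.  The sphere is placed 3 σ
  above the upper-leaflet heads by default.
* **ε_LR scaling rules**: ε_LR = E_max / N_L holds the total maximum
  binding energy constant across radii (the curvature-sweep protocol;
  anchored at 20 ε for the smallest sphere, since the protocol fixes only
  the product), and ε_LR = ε_LR,o / X rescales the depth by a measured
  valency.  The published rescaled depths differ from 20/X of the
  published valencies by up to 0.015 ε (consistent with rounding of X
  before printing); the package uses the plain quotient.

## Measurements

* **Binding graph**: in bond mode, the live bond set; in pair mode, all
  ligand/receptor pairs closer than the interaction support
  r_c_LR + w_c_LR ≈ 1.572 σ (the distance criterion made explicit, since
  pair potentials define no bond).  A frame's mean valency is
  edges / N_L over *all* ligands.
* **Valency X**: unweighted mean of frame means over the window starting
  100 τ after complete wrapping — the value characterizes the
  equilibrated, fully wrapped (vesicle) state.
* **Wrapping time T_u**: first time the bound-ligand fraction reaches 0.95
  and holds it for 10 τ (configurable; "completely wrapped" needs an
  operational rule, so it is explicit and logged).  Runs that never wrap
  are flagged, never averaged.
* **Percent error**: 100 (T_u^NV − T_u^IV) / T_u^IV between the
  valence-unlimited (NV) and imposed-valence (IV) schemes, computed per
  replicate pair and then summarized; positive means the unrestricted
  potential wraps more slowly.
* **Energy-difference diagnostic**: (U_bond − U_pair)/(ε_LR N_L) + 1
  approximates the pair-mode valency from the potential energies of two
  otherwise identical fully wrapped runs (the +1 is the bond system's own
  one bond per ligand).  A coarse screening tool, not ground truth.
* **Area per lipid**: ⟨Lx·Ly⟩/(n/2) over a stated window; the edge of a
  larger membrane is extrapolated as sqrt(apl · n_target/2).

## Problem sizes and what the desk-scale runs show

The published protocol (10,452–16,296 lipids, 10⁴ τ, five replicates per
point) is reproduced by the presets `fig2`, `fig3`, `fig4` and `table1`,
each of which also accepts a scale factor.  The package's own test and
acceptance runs use scaled-down problem sizes chosen as the smallest
systems in which each claim is physically meaningful:

* **Tensionless membrane**: a 512-lipid patch equilibrated for 600–800 τ
  (barostat pdamp = 50 τ), averaging the final half.  Its area per lipid
  extrapolates to the full membrane's 77 σ edge within ≈1–2%.
* **Valency artifact in miniature**: the R = 5 σ sphere (ε_LR = 20 ε,
  30% ligand coverage) prepared directly in its wrapped end state —
  engulfed in a ~1,500-lipid bilayer vesicle whose nanoparticle-facing
  (inner) leaflet is 50% receptors — and equilibrated in both coupling
  modes under plain Langevin dynamics (a closed vesicle has no lateral
  box tension to regulate, so no barostat).  The valency X is by
  definition a property of the wrapped, equilibrated state; preparing
  that state directly sidesteps the kinetic wrapping of a flat desk-scale
  patch, which in exploratory runs absorbs area and enriches receptors as
  expected but needs several thousand τ to pass the 0.95 bound-ligand
  threshold.  The assertion is directional: pair mode accumulates X > 2
  (measured ≈4.5) while bond mode is capped at X ≤ 1.  Coverage 0.3
  keeps ≈2.5 receptors available per ligand so the uncontrolled valency
  has room to express itself within the vesicle's receptor budget.  The
  builder relaxes its concentric-shell lattice with a short overdamped
  small-timestep phase before production dynamics.
* **Energy conservation** is verified at dt = 0.0025 τ, where the bounded
  velocity-Verlet energy oscillation of the stiff bonds (≈3×10⁻³ ε/bead
  at dt = 0.01 τ) no longer masks secular drift; the measured drift is
  < 2×10⁻⁴ ε/bead over 10⁴ steps.

What the desk-scale runs do *not* show: quantitative valencies (≈5) of
the published table, their curvature dependence, or wrapping-time percent
errors — those require the full-scale membranes and replicate counts, for
which the presets are provided.  The synthetic systems also idealize real
membranes in the usual ways of this model class: no solvent, no lipid
mixtures, fixed receptor count (no recruitment from a reservoir), rigid
spherical particles only.

## Numerical and degenerate-input choices

* FENE convention: R₀ is the maximum extension (engine convention), and
  the bond folds in its own WCA repulsion; an overstretched bond aborts
  the run with a diagnostic rather than continuing silently.
* Candidate bond formation visits pairs in a seeded random order so no
  spatial scan order biases which receptor wins a contested ligand; one
  attempt per candidate pair per step.
* Same seed + same configuration → bitwise-identical trajectories (one
  PCG64 stream owns thermostat noise and bond-formation randomness;
  replicate k of an experiment uses base_seed + k).
* Neighbor-list cutoff must fit twice into every box edge; the cell list
  falls back to an O(N²) scan for boxes under three cells per axis; the
  barostat aborts if the box shrinks below twice the interaction range.
* Degenerate angle geometries (sin θ < 10⁻⁸) use a clamped denominator;
  positions are kept wrapped, and minimum-image folding assumes
  displacements under 2.5 box lengths (guaranteed for wrapped states with
  a body radius under half the box).

## Known limitations

* The Berendsen-style barostat does not reproduce NPT area fluctuations,
  so area-compressibility moduli should not be measured from box
  fluctuations.
* The rigid body ignores its small inertia anisotropy (< 1% for Fibonacci
  shells at R ≥ 5 σ) and its rotational kinetic contribution to the
  lateral pressure (a sub-percent, zero-mean term).
* Bond mode checks candidate pairs against the engine neighbor list;
  formation radii beyond the nonbonded cutoff (2.62 σ) would require a
  dedicated search and are rejected implicitly by the parameter contract
  (r_form = 2 σ by default).
* Wrapping detection by bound-ligand fraction cannot distinguish a fully
  wrapped vesicle from a flat membrane that happens to contact 95% of
  ligands; for the geometries simulated here the two coincide.
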