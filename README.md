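# memwrap

Coarse-grained molecular-dynamics simulations of nanoparticle wrapping
(passive endocytosis) by lipid membranes, built to expose and fix a common
modeling artifact: when ligand-receptor adhesion is represented by an
ordinary distance-dependent **pair potential**, nothing limits how many
membrane receptors bind one nanoparticle ligand.  This *valency* then
drifts with nanoparticle curvature, ligand coverage and interaction
strength, silently changing the effective adhesion energy and corrupting
comparisons between nanoparticles.  `memwrap` implements both that
unrestricted coupling and a **valence-limited dynamic-bond scheme** that
uses the identical potential through explicit, stochastically
created/ruptured bonds with a hard cap of one receptor per ligand — plus
the analysis layer that quantifies the valency, the wrapping time, and the
error the uncontrolled valency induces.

Intended users: simulators of nanoparticle-membrane interactions
(drug-delivery design, membrane biophysics) who use implicit-solvent
coarse-grained bilayers and need their ligand-receptor valency controlled
or at least measured.

## Model

Lipids are the standard three-bead implicit-solvent model (1 head + 2 tail
beads; FENE bonds with K₁ = 30 ε/σ², R₀ = 1.5 σ; harmonic angle
K₂ = 10 ε/rad² at 180°).  Excluded volume is WCA with b = 0.95 σ
(head pairs) and b = 1.0 σ (tail-tail); bilayer cohesion is the broad
tail-tail cosine-squared attraction of depth ε and width w_c = 1.5 σ at
k_BT = 1 ε.  Receptor lipids differ only by a short-ranged
cosine-squared attraction of their head bead to nanoparticle ligand beads:

    U_LR(r) = -ε_LR cos²[π (r - 2^(1/6)σ) / (2 · 0.45σ)]   on the decay,

with depth ε_LR = 20 ε by default — so the well still holds 1.25 ε at the
1.5 σ bond-rupture separation used by the valence-limited scheme.
Nanospheres are rigid Fibonacci-lattice shells (≈1 bead/σ²); membranes are
kept tensionless by a lateral barostat; dynamics is Langevin (BAOAB) at
dt = 0.01 τ.  Everything is in reduced units (σ ≈ 0.9 nm, τ ≈ 1 ns).

In **pair mode** the valency X (receptors per ligand, counted within the
interaction support and time-averaged after complete wrapping) is an
uncontrolled outcome; in **bond mode** X ≤ 1 by construction, at identical
energetics.  See `docs/methods.md` for the full model description and the
operational definitions of wrapping time and valency.

## Worked example

```python
import numpy as np
import memwrap as mw
from memwrap.engine import IntegratorParams, Simulation, steps_for
from memwrap.observers import ThermoLog
from memwrap.analysis import area_per_lipid, predicted_box_edge

# builder populations
mem = mw.build_membrane(mw.MembraneSpec(n_lipids=10452, receptor_fraction=0.2))
np12 = mw.build_nanoparticle(mw.NanoparticleSpec(radius=12, ligand_coverage=0.5))
print(f"receptors on facing leaflet: {mem.receptor_indices.size}")
print(f"ligands on R=12 sphere:     {np12.ligand_indices.size}")

# the ligand-receptor well at the rupture separation
p = mw.LigandReceptorParams()
print(f"|U_LR(1.5 sigma)| = {abs(mw.ligand_receptor_energy(1.5, p)):.3f} epsilon")

# a tensionless 200-lipid patch, 200 tau
state = mw.build_membrane(mw.MembraneSpec(n_lipids=200, seed=1))
mw.thermalize(state, 1.0, np.random.default_rng(2))
ip = IntegratorParams(seed=3, barostat=True, pdamp=50.0)
sim = Simulation(state, mw.ForceField.default(), ip)
log = ThermoLog(interval=100)
sim.run(steps_for(200.0), hooks=[log])
arr = log.arrays()
half = arr["time"] >= 100.0
apl = area_per_lipid(arr["lx"][half], arr["ly"][half], 200)
print(f"mean temperature:  {arr['temperature'][half].mean():.3f} epsilon/kB")
print(f"area per lipid:    {apl:.3f} sigma^2")
print(f"edge for 10452 lipids: {predicted_box_edge(apl, 10452):.1f} sigma")
```

Output:

```
receptors on facing leaflet: 1045
ligands on R=12 sphere:     904
|U_LR(1.5 sigma)| = 1.253 epsilon
mean temperature:  0.996 epsilon/kB
area per lipid:    1.164 sigma^2
edge for 10452 lipids: 78.0 sigma
```

The receptor and ligand counts are the model's calibration populations
(20% receptors on the facing leaflet of the 10,452-lipid membrane; 50%
ligand coverage of the 12 σ sphere).  The 1.25 ε value is the energy a
ligand-receptor bond still holds at its 1.5 σ rupture length — safely
above thermal fluctuations at k_BT = 1 ε.  The short tensionless run
thermostats the patch at the target temperature and settles near the
model's equilibrium area per lipid; extrapolating it to 10,452 lipids
predicts the ≈77 σ equilibrated membrane edge (a 200-lipid, 200 τ run is
for illustration — the longer 512-lipid run in `scripts/acceptance.py`
lands within ~1-2%).

## Command line

```
memwrap build cfg.yaml -o system.data      # initial state as a LAMMPS data file
memwrap run cfg.yaml -o runs/              # replicates + thermo logs + summaries
memwrap analyze runs/*.summary.json        # wrapping / valency report
memwrap reproduce fig4 --scale 0.4         # write (optionally run) a preset
```

Presets `fig2`, `fig3`, `fig4`, `table1` reproduce the full-scale study
designs (curvature sweep at constant total binding energy, coverage ×
depth grid, radius × receptor-fraction wrapping-error grid, valency
rescaling table); `desk_valency` is the desk-scale demonstration that pair
mode accumulates X > 2 while bond mode stays at X ≤ 1.  Every preset
accepts `--scale` for smoke runs.  Ligand-receptor bond tables for a
reference MD engine are written by
`memwrap.forcefield.tabulate_bond_potential` / `write_lammps_table`.

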