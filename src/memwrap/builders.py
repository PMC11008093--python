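"""Deterministic construction of bilayer membranes and ligand-coated spheres.

The membrane builder places two leaflets of three-bead lipids on a square
lattice at a chosen initial area per lipid (default 1.2 sigma^2, slightly
expanded; the lateral barostat compresses it to the tensionless
equilibrium).  Receptors are a seeded uniform random subset of the
nanoparticle-facing (upper) leaflet; a receptor differs from a plain lipid
only by the species label on its head bead.

The nanoparticle builder distributes ``floor(4 pi R^2)`` beads on a sphere
with the Fibonacci (golden-angle) lattice, which gives near-uniform ~1
sigma spacing, and labels a seeded uniform subset of them as ligands.  All
nanoparticle beads form one rigid body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .species import HEAD, LIGAND, NP_SURFACE, RECEPTOR_HEAD, TAIL
from .state import RigidBody, SystemState

__all__ = [
    "MembraneSpec", "NanoparticleSpec",
    "build_membrane", "build_nanoparticle", "build_wrapped_vesicle", "combine",
    "epsilon_for_constant_total_binding", "rescale_epsilon_by_valency",
]


@dataclass(frozen=True)
class MembraneSpec:
    """Declarative membrane description.

    ``receptor_fraction`` applies to the nanoparticle-facing leaflet: the
    receptor count is ``floor(fraction * n_lipids / 2)``.  With
    ``per_leaflet=False`` the fraction is instead taken of the whole lipid
    population (all receptors still live in the facing leaflet, which must
    be able to hold them).
    """

    n_lipids: int = 10452
    receptor_fraction: float = 0.5
    area_per_lipid: float = 1.2
    lz: float = 60.0
    seed: int = 0
    per_leaflet: bool = True

    def __post_init__(self):
        if self.n_lipids <= 0 or self.n_lipids % 2:
            raise ValueError("n_lipids must be a positive even number")
        if not 0.0 <= self.receptor_fraction <= 1.0:
            raise ValueError("receptor_fraction must lie in [0, 1]")

    @property
    def n_receptors(self) -> int:
        base = self.n_lipids // 2 if self.per_leaflet else self.n_lipids
        return math.floor(self.receptor_fraction * base)


@dataclass(frozen=True)
class NanoparticleSpec:
    """Declarative nanosphere description (radius and ligand coverage)."""

    radius: float = 7.0
    ligand_coverage: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.ligand_coverage <= 1.0:
            raise ValueError("ligand_coverage must lie in [0, 1]")

    @property
    def n_surface(self) -> int:
        """Surface bead count floor(4 pi R^2), i.e. ~1 bead per sigma^2."""
        return math.floor(4.0 * math.pi * self.radius ** 2)

    @property
    def n_ligands(self) -> int:
        return math.floor(self.ligand_coverage * self.n_surface)


def _factor_near_square(n: int):
    """Factor n = nx * ny with the aspect ratio as close to 1 as possible."""
    best = None
    for a in range(int(math.isqrt(n)), 0, -1):
        if n % a == 0:
            best = (a, n // a)
            break
    if best is None or best[1] / best[0] > 2.0:
        raise ValueError(
            f"{n} lipids per leaflet cannot fill a near-square lattice")
    return best


def build_membrane(spec: MembraneSpec) -> SystemState:
    """Two-leaflet bilayer on a square lattice, tails inward, heads outward.

    Each lipid contributes three consecutive beads (head, tail, tail), two
    FENE bonds and one 180-degree angle.  The upper (facing) leaflet
    occupies lipid indices ``0 .. n_lipids/2 - 1``.
    """
    n_upper = spec.n_lipids // 2
    nx, ny = _factor_near_square(n_upper)
    a = math.sqrt(spec.area_per_lipid)
    box = np.array([nx * a, ny * a, spec.lz])
    zmid = spec.lz / 2.0

    n_beads = 3 * spec.n_lipids
    pos = np.empty((n_beads, 3))
    species = np.empty(n_beads, dtype=np.int64)
    bonds = np.empty((2 * spec.n_lipids, 2), dtype=np.int64)
    bond_types = np.empty(2 * spec.n_lipids, dtype=np.int64)
    angles = np.empty((spec.n_lipids, 3), dtype=np.int64)

    lipid = 0
    for leaflet, sign in ((0, 1.0), (1, -1.0)):
        for iy in range(ny):
            for ix in range(nx):
                x = (ix + 0.5) * a
                y = (iy + 0.5) * a
                b0 = 3 * lipid
                pos[b0] = (x, y, zmid + sign * 2.5)      # head
                pos[b0 + 1] = (x, y, zmid + sign * 1.5)  # tail
                pos[b0 + 2] = (x, y, zmid + sign * 0.5)  # tail
                species[b0] = HEAD
                species[b0 + 1] = TAIL
                species[b0 + 2] = TAIL
                bonds[2 * lipid] = (b0, b0 + 1)
                bond_types[2 * lipid] = 0                # head-tail
                bonds[2 * lipid + 1] = (b0 + 1, b0 + 2)
                bond_types[2 * lipid + 1] = 1            # tail-tail
                angles[lipid] = (b0, b0 + 1, b0 + 2)
                lipid += 1

    n_rec = spec.n_receptors
    if n_rec > n_upper:
        raise ValueError("receptor count exceeds the facing leaflet population")
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(n_upper, size=n_rec, replace=False)
    species[3 * chosen] = RECEPTOR_HEAD

    return SystemState(pos, np.zeros((n_beads, 3)), species, box,
                       bonds, bond_types, angles, n_lipids=spec.n_lipids)


def fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n points on a sphere by the golden-angle (Fibonacci) lattice."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z * z)
    theta = math.pi * (3.0 - math.sqrt(5.0)) * i
    return radius * np.column_stack([rho * np.cos(theta),
                                     rho * np.sin(theta), z])


def build_nanoparticle(spec: NanoparticleSpec) -> SystemState:
    """Rigid ligand-decorated nanosphere centered at the origin.

    Surface beads sit exactly at radius R on a Fibonacci lattice (~1 sigma
    nearest-neighbor spacing); ``floor(coverage * N_surface)`` of them are
    relabeled as ligands by seeded uniform sampling.
    """
    n = spec.n_surface
    if n < 4:
        raise ValueError("radius too small: fewer than 4 surface beads")
    pos = fibonacci_sphere(n, spec.radius)
    species = np.full(n, NP_SURFACE, dtype=np.int64)
    rng = np.random.default_rng(spec.seed)
    chosen = rng.choice(n, size=spec.n_ligands, replace=False)
    species[chosen] = LIGAND
    body = RigidBody(indices=np.arange(n, dtype=np.int64),
                     com=np.zeros(3), rel=pos.copy())
    return SystemState(pos, np.zeros((n, 3)), species,
                       np.array([np.inf, np.inf, np.inf]),
                       np.empty((0, 2)), np.empty(0), np.empty((0, 3)),
                       body=body)


def combine(membrane: SystemState, particle: SystemState,
            gap: float = 3.0) -> SystemState:
    """Merge a membrane and a nanoparticle into one system.

    The particle is centered laterally and its lowest surface bead placed
    ``gap`` sigma above the top of the upper-leaflet head beads.
    """
    if particle.body is None:
        raise ValueError("particle fragment must carry a rigid body")
    n_m = membrane.n_beads
    top = float(np.max(membrane.positions[membrane.species != TAIL][:, 2]))
    radius = float(np.max(np.linalg.norm(particle.body.rel, axis=1)))
    com = np.array([membrane.box[0] / 2.0, membrane.box[1] / 2.0,
                    top + gap + radius])
    if com[2] + radius >= membrane.box[2]:
        raise ValueError("box height too small to place the nanoparticle")

    pos = np.vstack([membrane.positions, com + particle.body.rel])
    vel = np.vstack([membrane.velocities, particle.velocities])
    species = np.concatenate([membrane.species, particle.species])
    body = RigidBody(indices=particle.body.indices + n_m, com=com,
                     rel=particle.body.rel.copy())
    return SystemState(pos, vel, species, membrane.box.copy(),
                       membrane.bonds, membrane.bond_types, membrane.angles,
                       body=body, n_lipids=membrane.n_lipids)


def build_wrapped_vesicle(particle_spec: NanoparticleSpec,
                          receptor_fraction: float = 0.5,
                          area_per_lipid: float = 1.16,
                          margin: float = 5.0,
                          seed: int = 0) -> SystemState:
    """Nanoparticle fully engulfed in a bilayer vesicle (the wrapped end state).

    Two concentric leaflets of radially oriented lipids surround the rigid
    sphere: the inner (nanoparticle-facing) leaflet's heads sit at contact
    distance from the surface beads, tails pointing outward; the outer
    leaflet mirrors them.  Leaflet populations come from the area of each
    leaflet's mid-surface at the given area per lipid, and receptors are a
    seeded uniform subset of the inner leaflet (``receptor_fraction`` of
    it).  The construct equilibrates in place under plain Langevin
    dynamics (no barostat: a closed vesicle has no lateral box tension to
    regulate), which makes the fully wrapped state accessible at desk
    scale where kinetic wrapping of a flat patch is geometrically
    frustrated.
    """
    if not 0.0 <= receptor_fraction <= 1.0:
        raise ValueError("receptor_fraction must lie in [0, 1]")
    R = particle_spec.radius
    spacing = 0.95                      # radial bead spacing within a lipid
    r_head_in = R + 1.05                # head-surface contact distance
    radii_in = (r_head_in, r_head_in + spacing, r_head_in + 2 * spacing)
    r_tail_out = radii_in[2] + 1.0      # tail-tail contact across leaflets
    radii_out = (r_tail_out + 2 * spacing, r_tail_out + spacing, r_tail_out)

    # leaflet populations from a counting radius biased half a bead toward
    # each leaflet's crowded surface (the head sphere inside, the terminal
    # tail sphere outside), so neither initial shell starts overpacked
    r_count_in = radii_in[1] - 0.45
    r_count_out = radii_out[1] - 0.45
    n_in = math.floor(4.0 * math.pi * r_count_in ** 2 / area_per_lipid)
    n_out = math.floor(4.0 * math.pi * r_count_out ** 2 / area_per_lipid)
    n_lipids = n_in + n_out

    particle = build_nanoparticle(particle_spec)
    n_np = particle.n_beads
    edge = 2.0 * (radii_out[0] + margin)
    box = np.array([edge, edge, edge])
    center = box / 2.0

    # lipids first, nanoparticle beads last (a contiguous rigid block)
    n_beads = 3 * n_lipids + n_np
    pos = np.empty((n_beads, 3))
    species = np.empty(n_beads, dtype=np.int64)
    bonds = np.empty((2 * n_lipids, 2), dtype=np.int64)
    bond_types = np.empty(2 * n_lipids, dtype=np.int64)
    angles = np.empty((n_lipids, 3), dtype=np.int64)
    lipid = 0
    for n_leaf, radii in ((n_in, radii_in), (n_out, radii_out)):
        unit = fibonacci_sphere(n_leaf, 1.0)
        for k in range(n_leaf):
            b0 = 3 * lipid
            for m, r in enumerate(radii):       # head, tail, tail
                pos[b0 + m] = center + r * unit[k]
            species[b0] = HEAD
            species[b0 + 1] = TAIL
            species[b0 + 2] = TAIL
            bonds[2 * lipid] = (b0, b0 + 1)
            bond_types[2 * lipid] = 0
            bonds[2 * lipid + 1] = (b0 + 1, b0 + 2)
            bond_types[2 * lipid + 1] = 1
            angles[lipid] = (b0, b0 + 1, b0 + 2)
            lipid += 1

    pos[3 * n_lipids:] = center + particle.positions
    species[3 * n_lipids:] = particle.species

    rng = np.random.default_rng(seed)
    n_rec = math.floor(receptor_fraction * n_in)
    chosen = rng.choice(n_in, size=n_rec, replace=False)
    species[3 * chosen] = RECEPTOR_HEAD

    body = RigidBody(indices=np.arange(3 * n_lipids, n_beads, dtype=np.int64),
                     com=center.copy(), rel=particle.positions.copy())
    return SystemState(pos, np.zeros((n_beads, 3)), species, box,
                       bonds, bond_types, angles, body=body,
                       n_lipids=n_lipids)


def epsilon_for_constant_total_binding(n_ligands: int, e_max: float) -> float:
    """Well depth that keeps the total maximum binding energy constant.

    Scaling ``eps_LR = E_max / N_L`` holds ``N_L * eps_LR`` fixed across
    nanoparticle sizes, so all fully wrapped spheres release the same
    energy if every ligand binds exactly one receptor.
    """
    if n_ligands <= 0:
        raise ValueError("n_ligands must be positive")
    return e_max / n_ligands


def rescale_epsilon_by_valency(eps_original: float, valency: float) -> float:
    """Divide the well depth by a measured valency.

    ``eps_LR = eps_LR_original / X`` compensates the excess binding energy
    an uncontrolled valency X accumulates; it reduces but does not remove
    the inconsistency, since the rescaled system settles at a new valency.
    """
    if valency <= 0:
        raise ValueError("valency must be positive")
    return eps_original / valency
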