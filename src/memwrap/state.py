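"""System state container: beads, topology, dynamic bonds, box, rigid body."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .species import LIGAND, NP_SURFACE, RECEPTOR_HEAD


@dataclass
class RigidBody:
    """A rigid cluster of beads (the nanoparticle).

    Bead positions are ``com + rel``; ``rel`` carries the current
    orientation and is rotated as a whole, so intra-body distances are
    preserved to rounding error.  The inertia tensor of a near-uniform
    spherical shell is close to isotropic, so a single scalar moment (the
    mean of the eigenvalues) is used.
    """

    indices: np.ndarray
    com: np.ndarray
    rel: np.ndarray
    vel: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def mass(self) -> float:
        return float(self.indices.size)

    @property
    def inertia(self) -> float:
        return float(np.sum(self.rel ** 2)) * 2.0 / 3.0

    def copy(self) -> "RigidBody":
        return RigidBody(self.indices.copy(), self.com.copy(), self.rel.copy(),
                         self.vel.copy(), self.omega.copy())


@dataclass
class SystemState:
    """Positions, velocities, species, topology and box of the whole system.

    Static topology (FENE bonds, angles) never changes during a run; the
    dynamic ligand-receptor bond set (``dyn_lig``/``dyn_rec`` parallel
    arrays of bead indices) is rewritten by the bond-dynamics update.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    box: np.ndarray                       # (Lx, Ly, Lz) in sigma
    bonds: np.ndarray                     # (nb, 2) bead indices
    bond_types: np.ndarray                # (nb,) 0 head-tail, 1 tail-tail
    angles: np.ndarray                    # (na, 3) head, tail1, tail2
    masses: Optional[np.ndarray] = None
    dyn_lig: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    dyn_rec: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    body: Optional[RigidBody] = None
    time: float = 0.0
    n_lipids: int = 0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.species = np.ascontiguousarray(self.species, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=float)
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_types = np.ascontiguousarray(self.bond_types, dtype=np.int64)
        self.angles = np.ascontiguousarray(self.angles, dtype=np.int64).reshape(-1, 3)
        if self.masses is None:
            self.masses = np.ones(len(self.positions))

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.flatnonzero(self.species == LIGAND)

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.species == RECEPTOR_HEAD)

    @property
    def particle_indices(self) -> np.ndarray:
        return np.flatnonzero((self.species == NP_SURFACE) | (self.species == LIGAND))

    @property
    def n_dynamic_bonds(self) -> int:
        return len(self.dyn_lig)

    def wrap(self) -> None:
        """Wrap all bead positions into the periodic box [0, L)."""
        self.positions -= np.floor(self.positions / self.box) * self.box
        if self.body is not None:
            self.body.com -= np.floor(self.body.com / self.box) * self.box
            self.positions[self.body.indices] = self.body.com + self.body.rel

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        return d - self.box * np.rint(d / self.box)

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(), self.velocities.copy(), self.species.copy(),
            self.box.copy(), self.bonds.copy(), self.bond_types.copy(),
            self.angles.copy(), self.masses.copy(),
            self.dyn_lig.copy(), self.dyn_rec.copy(),
            self.body.copy() if self.body is not None else None,
            self.time, self.n_lipids)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Save the full state (topology, dynamic bonds, rigid body) to .npz."""
        data = {
            "positions": self.positions, "velocities": self.velocities,
            "species": self.species, "box": self.box, "bonds": self.bonds,
            "bond_types": self.bond_types, "angles": self.angles,
            "masses": self.masses, "dyn_lig": self.dyn_lig, "dyn_rec": self.dyn_rec,
            "time": np.array(self.time), "n_lipids": np.array(self.n_lipids),
        }
        if self.body is not None:
            data.update(body_indices=self.body.indices, body_com=self.body.com,
                        body_rel=self.body.rel, body_vel=self.body.vel,
                        body_omega=self.body.omega)
        np.savez(path, **data)

    @classmethod
    def load(cls, path) -> "SystemState":
        with np.load(path) as z:
            body = None
            if "body_indices" in z:
                body = RigidBody(z["body_indices"], z["body_com"], z["body_rel"],
                                 z["body_vel"], z["body_omega"])
            return cls(z["positions"], z["velocities"], z["species"], z["box"],
                       z["bonds"], z["bond_types"], z["angles"], z["masses"],
                       z["dyn_lig"], z["dyn_rec"], body,
                       float(z["time"]), int(z["n_lipids"]))


def thermalize(state: SystemState, kT: float, rng: np.random.Generator) -> None:
    """Draw Maxwell-Boltzmann velocities at temperature ``kT`` in place.

    Flexible beads get independent Gaussian components; the rigid body gets
    thermal center-of-mass and angular velocities for its six degrees of
    freedom.
    """
    n = state.n_beads
    state.velocities = rng.normal(0.0, 1.0, (n, 3)) * np.sqrt(
        kT / state.masses)[:, None]
    if state.body is not None:
        b = state.body
        state.velocities[b.indices] = 0.0
        b.vel = rng.normal(0.0, float(np.sqrt(kT / b.mass)), 3)
        b.omega = rng.normal(0.0, float(np.sqrt(kT / b.inertia)), 3)
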