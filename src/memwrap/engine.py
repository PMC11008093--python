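"""Langevin dynamics engine with a tensionless-membrane lateral barostat.

Integration is velocity-Verlet with a BAOAB Langevin splitting: half kick,
half drift, Ornstein-Uhlenbeck velocity refresh, half drift, force
recomputation, half kick.  With the thermostat disabled the scheme reduces
to plain velocity Verlet (NVE).  The nanoparticle is one rigid body: the
per-bead interaction forces are summed into a net force and torque and the
body moves with six degrees of freedom (isotropic moment of inertia, a very
good approximation for a near-uniform spherical shell); the
Ornstein-Uhlenbeck refresh acts on its center-of-mass and angular
velocities with the same relaxation rate as on free beads, which is what
summing per-bead Langevin friction and noise over the body would give.

The zero-tension condition is maintained by a first-order (Berendsen-type)
lateral barostat: each step the box edges Lx, Ly and all in-plane
coordinates are rescaled jointly toward zero lateral pressure with a
relaxation time of order ``pdamp``.  This reproduces the zero-mean-tension
contract of a Nose-Hoover chain barostat without its oscillatory inertial
dynamics (the microscopic NPT ensemble is not targeted; see the methods
notes).

Neighbor search uses a linked-cell Verlet list with a skin, rebuilt
whenever the largest bead displacement since the last build exceeds half
the skin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .bond_dynamics import BondEventLog, update_bonds
from .forcefield import ForceField, OverstretchedBondError
from .species import LIGAND, NP_SURFACE, RECEPTOR_HEAD
from .state import SystemState

__all__ = [
    "IntegratorParams", "Simulation", "SimulationError",
    "neighbor_pairs", "steps_for", "step", "apply_lateral_barostat",
]


class SimulationError(RuntimeError):
    """Fatal integration failure (non-finite coordinate, box collapse...)."""


@dataclass
class IntegratorParams:
    """Integration, thermostat and barostat settings.

    ``damp`` is the Langevin velocity relaxation time (friction gamma =
    m/damp); ``damp=None`` disables the thermostat (NVE).  ``pdamp`` sets
    the relaxation time scale of the lateral barostat, which is only active
    when ``barostat`` is true.  ``kA_ref`` is the area-compressibility
    scale used to convert measured lateral tension into an area strain
    rate; the barostat's actual relaxation time is ``pdamp`` times the
    ratio of the true area modulus to ``kA_ref`` (order one for this
    membrane).
    """

    dt: float = 0.01
    kT: float = 1.0
    damp: Optional[float] = 1.0
    pdamp: float = 1.0e3
    p_target: float = 0.0
    barostat: bool = False
    kA_ref: float = 15.0
    seed: int = 0
    skin: float = 0.4

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.damp is not None and self.damp <= 0:
            raise ValueError("damp must be positive (or None for NVE)")


def steps_for(duration_tau: float, dt: float = 0.01) -> int:
    """Number of timesteps needed to cover ``duration_tau``."""
    return int(round(duration_tau / dt))


def neighbor_pairs(state: SystemState, cutoff: float) -> np.ndarray:
    """All bead pairs with minimum-image distance < cutoff (i < j).

    The cutoff must not exceed half the smallest box edge, otherwise the
    minimum-image convention is ambiguous.  Implemented with a periodic
    KD-tree, independently of the engine's cell list.
    """
    if cutoff > 0.5 * float(np.min(state.box)):
        raise ValueError("cutoff exceeds half the smallest box edge")
    pos = state.positions % state.box
    tree = cKDTree(pos, boxsize=state.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return pairs.astype(np.int64).reshape(-1, 2)
    d = _kernels.pair_distances(state.positions, state.box,
                                pairs[:, 0].astype(np.int64).copy(),
                                pairs[:, 1].astype(np.int64).copy())
    return pairs[d < cutoff].astype(np.int64)


def _rotate(rel: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """Rotate body-frame offsets by the Rodrigues rotation omega*dt."""
    angle = float(np.linalg.norm(omega)) * dt
    if angle < 1e-14:
        return rel
    axis = omega / np.linalg.norm(omega)
    c, s = np.cos(angle), np.sin(angle)
    cross = np.cross(np.broadcast_to(axis, rel.shape), rel)
    dot = rel @ axis
    return c * rel + s * cross + (1.0 - c) * dot[:, None] * axis


class Simulation:
    """Owns a :class:`SystemState`, a :class:`ForceField` and the integrator.

    Typical use::

        sim = Simulation(state, ff, IntegratorParams(seed=1))
        sim.run(steps_for(100.0), hooks=[thermo_log])
    """

    def __init__(self, state: SystemState, ff: ForceField,
                 params: IntegratorParams):
        self.state = state
        self.ff = ff
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.tables = ff.tables()
        self.cutoff = ff.max_cutoff
        self._pair_cut = ff.pair_cutoffs()
        self.bond_log = BondEventLog()
        self.step_count = 0

        n = state.n_beads
        body = state.body
        self._flex: Union[slice, np.ndarray]
        if body is None:
            self._flex = slice(0, n)
            self._n_flex = n
        elif np.array_equal(body.indices,
                            np.arange(n - body.indices.size, n)):
            self._flex = slice(0, n - body.indices.size)
            self._n_flex = n - body.indices.size
        else:
            self._flex = np.setdiff1d(np.arange(n), body.indices)
            self._n_flex = self._flex.size
        self._m_flex = state.masses[self._flex][:, None].copy()
        self._sqrt_m_flex = np.sqrt(self._m_flex)
        self._excl_keys = self._exclusion_keys()
        b = state.bonds
        self._excl_span = int(np.max(np.abs(b[:, 0] - b[:, 1]))) if b.size else 0
        self.forces = np.zeros((n, 3))
        self._rebuild_neighbors()
        self._compute_forces()
        self._ke_mid = self.kinetic_energy()

    # -- neighbor list ----------------------------------------------------

    def _exclusion_keys(self) -> np.ndarray:
        b = self.state.bonds
        if b.size == 0:
            return np.empty(0, dtype=np.int64)
        lo = np.minimum(b[:, 0], b[:, 1])
        hi = np.maximum(b[:, 0], b[:, 1])
        return np.sort(lo * self.state.n_beads + hi)

    def _rebuild_neighbors(self) -> None:
        st = self.state
        r = self.cutoff + self.params.skin
        if r > 0.5 * float(np.min(st.box)):
            raise SimulationError(
                f"neighbor cutoff {r:.2f} exceeds half the box "
                f"{np.min(st.box) / 2:.2f}; box too small")
        cut2 = (self._pair_cut + self.params.skin) ** 2
        pi, pj = _kernels.build_pair_list(st.positions, st.box, r, cut2,
                                          st.species, self._excl_keys,
                                          self._excl_span, NP_SURFACE)
        if pi.size == 0 and st.n_beads > 200:
            raise SimulationError("pair-list buffer overflow")
        self._pi = pi
        self._pj = pj
        # ligand/receptor candidate pairs for the bond-dynamics update
        sp = st.species
        lr = (sp[pi] == LIGAND) & (sp[pj] == RECEPTOR_HEAD)
        rl = (sp[pi] == RECEPTOR_HEAD) & (sp[pj] == LIGAND)
        self._cand_l = np.concatenate([pi[lr], pj[rl]])
        self._cand_r = np.concatenate([pj[lr], pi[rl]])
        self._ref_pos = st.positions.copy()
        self._ref_box = st.box.copy()

    def _maybe_rebuild(self) -> None:
        st = self.state
        if not np.array_equal(st.box, self._ref_box):
            self._ref_pos *= st.box / self._ref_box
            self._ref_box = st.box.copy()
        d1, d2 = _kernels.max_displacement_sq(st.positions, self._ref_pos,
                                              st.box)
        if np.sqrt(d1) + np.sqrt(d2) > self.params.skin:
            self._rebuild_neighbors()

    # -- forces and observables ------------------------------------------

    def _compute_forces(self) -> None:
        st = self.state
        t = self.tables
        self.forces[:] = 0.0
        e, wxx, wyy, wzz = _kernels.pair_forces(
            st.positions, st.box, self._pi, self._pj, st.species,
            t["wca_eps"], t["wca_b2"], t["wca_rc2"],
            t["cos_rc2"], t["cos_scale"], t["cos_u"], t["cos_fr"],
            self.forces)
        if st.bonds.size:
            eb, bx, by, bz, bad = _kernels.fene_forces(
                st.positions, st.box,
                np.ascontiguousarray(st.bonds[:, 0]),
                np.ascontiguousarray(st.bonds[:, 1]),
                st.bond_types, t["fene_K"], t["fene_R0"],
                t["fene_eps"], t["fene_b2"], self.forces)
            if bad >= 0:
                i, j = st.bonds[bad]
                raise OverstretchedBondError(
                    f"FENE bond {i}-{j} overstretched at t={st.time:.2f} tau")
            e += eb
            wxx += bx
            wyy += by
            wzz += bz
        if st.angles.size:
            ea, ax, ay, az = _kernels.angle_forces(
                st.positions, st.box,
                np.ascontiguousarray(st.angles[:, 0]),
                np.ascontiguousarray(st.angles[:, 1]),
                np.ascontiguousarray(st.angles[:, 2]),
                t["angle_K"], t["angle_theta0"], self.forces)
            e += ea
            wxx += ax
            wyy += ay
            wzz += az
        if st.n_dynamic_bonds:
            el, lx, ly, lz = _kernels.lr_bond_forces(
                st.positions, st.box, st.dyn_lig, st.dyn_rec,
                t["lr_eps"], t["lr_rc"], t["lr_wc"], self.forces)
            e += el
            wxx += lx
            wyy += ly
            wzz += lz
        if not np.isfinite(e):
            raise SimulationError(f"non-finite energy at t={st.time:.2f} tau")
        self.potential_energy = e
        self.virial = np.array([wxx, wyy, wzz])

    def kinetic_energy(self) -> float:
        st = self.state
        ke = 0.5 * float(np.sum(self._m_flex * st.velocities[self._flex] ** 2))
        if st.body is not None:
            b = st.body
            ke += 0.5 * b.mass * float(b.vel @ b.vel)
            ke += 0.5 * b.inertia * float(b.omega @ b.omega)
        return ke

    @property
    def n_dof(self) -> int:
        n = 3 * self._n_flex
        if self.state.body is not None:
            n += 6
        return n

    def temperature(self) -> float:
        """Instantaneous kinetic temperature (epsilon / k_B).

        Computed from the mid-step (post-refresh) velocities, whose kinetic
        average carries a much smaller timestep bias for the stiff bonded
        modes than the on-step velocities do.
        """
        return 2.0 * self._ke_mid / self.n_dof

    def lateral_pressure(self) -> float:
        """Instantaneous lateral pressure (Pxx + Pyy)/2 in epsilon/sigma^3.

        Kinetic contribution from flexible beads plus the body's
        center-of-mass motion (body rotation is neglected, a sub-percent
        effect on the box-averaged pressure).
        """
        st = self.state
        v = st.velocities[self._flex]
        kin = np.sum(self._m_flex * v * v, axis=0)
        if st.body is not None:
            kin += st.body.mass * st.body.vel ** 2
        vol = float(np.prod(st.box))
        pxx = (kin[0] + self.virial[0]) / vol
        pyy = (kin[1] + self.virial[1]) / vol
        return 0.5 * float(pxx + pyy)

    def total_momentum(self) -> np.ndarray:
        st = self.state
        p = np.sum(self._m_flex * st.velocities[self._flex], axis=0)
        if st.body is not None:
            p = p + st.body.mass * st.body.vel
        return p

    # -- integration ------------------------------------------------------

    def _kick(self, half_dt: float) -> None:
        st = self.state
        st.velocities[self._flex] += half_dt / self._m_flex * self.forces[self._flex]
        if st.body is not None:
            b = st.body
            fb = self.forces[b.indices]
            b.vel += half_dt * np.sum(fb, axis=0) / b.mass
            torque = np.sum(np.cross(b.rel, fb), axis=0)
            b.omega += half_dt * torque / b.inertia

    def _drift(self, half_dt: float) -> None:
        st = self.state
        st.positions[self._flex] += half_dt * st.velocities[self._flex]
        if st.body is not None:
            b = st.body
            b.com += half_dt * b.vel
            b.rel = _rotate(b.rel, b.omega, half_dt)

    def _ou(self) -> None:
        p = self.params
        if p.damp is None:
            return
        st = self.state
        c1 = np.exp(-p.dt / p.damp)
        c2 = np.sqrt((1.0 - c1 * c1) * p.kT)
        noise = self.rng.standard_normal((self._n_flex, 3))
        v = st.velocities[self._flex]
        v *= c1
        v += c2 / self._sqrt_m_flex * noise
        if isinstance(self._flex, np.ndarray):
            st.velocities[self._flex] = v
        if st.body is not None:
            b = st.body
            b.vel = c1 * b.vel + c2 / np.sqrt(b.mass) * self.rng.standard_normal(3)
            b.omega = (c1 * b.omega
                       + c2 / np.sqrt(b.inertia) * self.rng.standard_normal(3))

    def apply_barostat(self) -> None:
        """One Berendsen-style lateral rescale toward zero lateral tension.

        The measured tension ``(P_lat - P_target) * Lz`` is converted to an
        area strain rate through the reference modulus ``kA_ref``; Lx, Ly
        are coupled jointly (isotropic in plane) and Lz is untouched.
        """
        st = self.state
        p = self.params
        tension = (self.lateral_pressure() - p.p_target) * st.box[2]
        mu = 1.0 + 0.5 * p.dt / p.pdamp * tension / p.kA_ref
        mu = min(max(mu, 0.999), 1.001)
        st.box[0] *= mu
        st.box[1] *= mu
        st.positions[self._flex, 0] *= mu
        st.positions[self._flex, 1] *= mu
        if st.body is not None:
            st.body.com[0] *= mu
            st.body.com[1] *= mu
            st.positions[st.body.indices] = st.body.com + st.body.rel
        if np.min(st.box) < 2.0 * (self.cutoff + p.skin):
            raise SimulationError("box shrank below twice the interaction range")

    def step(self) -> None:
        """Advance one timestep (BAOAB + bond update + barostat)."""
        st = self.state
        p = self.params
        half = 0.5 * p.dt
        self._kick(half)
        self._drift(half)
        self._ou()
        self._ke_mid = self.kinetic_energy()
        self._drift(half)
        if st.body is not None:
            st.positions[st.body.indices] = st.body.com + st.body.rel
        st.wrap()
        if self.ff.lr.mode == "bond":
            update_bonds(st, self.ff.lr, self.rng,
                         candidates=(self._cand_l, self._cand_r),
                         log=self.bond_log)
        self._maybe_rebuild()
        self._compute_forces()
        self._kick(half)
        if p.barostat:
            self.apply_barostat()
        st.time += p.dt
        self.step_count += 1

    def run(self, n_steps: int, hooks: Iterable = (),
            stop: Optional[Callable[["Simulation"], bool]] = None,
            stop_every: int = 1000) -> None:
        """Integrate ``n_steps`` steps, invoking observer hooks at their strides.

        Each hook must expose ``interval`` (in steps) and be callable with
        the simulation.  Hooks are called once before the first step and
        after every ``interval``-th step.  ``stop(sim)`` is evaluated every
        ``stop_every`` steps and ends the run early when it returns true.
        """
        hooks = list(hooks)
        for h in hooks:
            h(self)
        for i in range(1, n_steps + 1):
            self.step()
            for h in hooks:
                if self.step_count % h.interval == 0:
                    h(self)
            if stop is not None and i % stop_every == 0 and stop(self):
                break

    # -- checkpointing ----------------------------------------------------

    def save_checkpoint(self, path) -> None:
        """Full restart file: state, dynamic bonds and RNG stream position."""
        import json
        self.state.save(path)
        with open(str(path) + ".rng.json", "w") as fh:
            json.dump({"state": self.rng.bit_generator.state,
                       "step_count": self.step_count}, fh)

    @classmethod
    def load_checkpoint(cls, path, ff: ForceField,
                        params: IntegratorParams) -> "Simulation":
        import json
        state = SystemState.load(path)
        sim = cls(state, ff, params)
        try:
            with open(str(path) + ".rng.json") as fh:
                meta = json.load(fh)
            sim.rng.bit_generator.state = meta["state"]
            sim.step_count = meta["step_count"]
        except FileNotFoundError:
            pass
        return sim


def step(state: SystemState, ff: ForceField, ip: IntegratorParams) -> SystemState:
    """Functional single-step convenience wrapper (builds a fresh engine)."""
    sim = Simulation(state, ff, ip)
    sim.step()
    return sim.state


def apply_lateral_barostat(state: SystemState, ff: ForceField,
                           ip: IntegratorParams) -> SystemState:
    """Apply one lateral barostat rescale to ``state`` (in place) and return it."""
    sim = Simulation(state, ff, ip)
    sim.apply_barostat()
    return sim.state
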