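"""Integrator, neighbor search, barostat and rigid-body contracts."""

import numpy as np
import pytest

import memwrap as mw
from memwrap.engine import (IntegratorParams, Simulation, SimulationError,
                            neighbor_pairs, steps_for)
from memwrap.state import SystemState

from conftest import brute_force_pairs, gas_state


def two_bead_state(sep, box_edge=10.0):
    box = np.array([box_edge] * 3)
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + sep, 1.0, 1.0]])
    return SystemState(pos, np.zeros((2, 3)), np.zeros(2, dtype=np.int64),
                       box, np.empty((0, 2)), np.empty(0), np.empty((0, 3)))


class TestNeighborPairs:
    def test_single_pair(self):
        st = two_bead_state(0.9)
        assert len(neighbor_pairs(st, 1.0)) == 1

    def test_minimum_image_across_boundary(self):
        st = two_bead_state(0.9)
        st.positions[1, 0] = st.positions[0, 0] - 0.5 + st.box[0]
        st.wrap()
        assert len(neighbor_pairs(st, 1.0)) == 1

    def test_matches_brute_force_on_gas(self):
        rng = np.random.default_rng(42)
        st = gas_state(200, 12.0, rng, min_sep=0.5)
        got = {tuple(p) for p in neighbor_pairs(st, 1.8).tolist()}
        assert got == brute_force_pairs(st.positions, st.box, 1.8)

    def test_cutoff_beyond_half_box_rejected(self):
        st = two_bead_state(0.9)
        with pytest.raises(ValueError):
            neighbor_pairs(st, 6.0)


class TestCellList:
    def test_matches_kdtree_on_membrane(self, small_membrane, ff_pair):
        sim = Simulation(small_membrane, ff_pair, IntegratorParams(seed=1))
        got = {(min(i, j), max(i, j))
               for i, j in zip(sim._pi.tolist(), sim._pj.tolist())}
        # reference: KD-tree pairs at the widest radius, filtered down to
        # each species pair's own list radius
        cuts = ff_pair.pair_cutoffs() + sim.params.skin
        sp = small_membrane.species
        pos = small_membrane.positions
        box = small_membrane.box
        ref = set()
        for i, j in neighbor_pairs(small_membrane, sim.cutoff
                                   + sim.params.skin).tolist():
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            if np.sqrt(d @ d) < cuts[sp[i], sp[j]]:
                ref.add((i, j))
        bonded = {(min(i, j), max(i, j))
                  for i, j in small_membrane.bonds.tolist()}
        assert got == ref - bonded

    def test_rigid_internal_pairs_dropped(self, ff_pair):
        part = mw.build_nanoparticle(mw.NanoparticleSpec(radius=3))
        part.box = np.array([20.0, 20.0, 20.0])
        part.positions += 10.0
        part.body.com += 10.0
        sim = Simulation(part, ff_pair, IntegratorParams(seed=1))
        assert sim._pi.size == 0


class TestIntegration:
    def test_free_streaming(self):
        st = two_bead_state(5.0)
        st.velocities[0] = (0.5, -0.2, 0.1)
        sim = Simulation(st, mw.ForceField.default(),
                         IntegratorParams(seed=0, damp=None))
        x0 = st.positions[0].copy()
        sim.step()
        np.testing.assert_allclose(st.positions[0] - x0,
                                   np.array([0.5, -0.2, 0.1]) * 0.01)

    def test_zero_steps_is_identity(self, small_membrane, ff_pair):
        pos0 = small_membrane.positions.copy()
        sim = Simulation(small_membrane, ff_pair, IntegratorParams(seed=1))
        sim.run(0)
        np.testing.assert_array_equal(small_membrane.positions, pos0)

    def test_production_run_length(self):
        assert steps_for(1.0e4, dt=0.01) == 10 ** 6

    def test_determinism_same_seed(self, ff_pair):
        results = []
        for _ in range(2):
            st = mw.build_membrane(mw.MembraneSpec(n_lipids=72, seed=2))
            mw.thermalize(st, 1.0, np.random.default_rng(3))
            sim = Simulation(st, ff_pair, IntegratorParams(seed=7))
            sim.run(300)
            results.append(st.positions.copy())
        np.testing.assert_array_equal(results[0], results[1])

    def test_momentum_conserved_without_thermostat(self, small_membrane,
                                                   ff_pair):
        sim = Simulation(small_membrane, ff_pair,
                         IntegratorParams(seed=1, damp=None))
        p0 = sim.total_momentum()
        sim.run(200)
        assert np.abs(sim.total_momentum() - p0).max() < 1e-10 * 200

    def test_overstretched_bond_aborts(self, ff_pair):
        st = mw.build_membrane(mw.MembraneSpec(n_lipids=72))
        st.positions[1] = st.positions[0] + (0.0, 0.0, 1.6)
        with pytest.raises(mw.OverstretchedBondError):
            Simulation(st, ff_pair, IntegratorParams(seed=1))

    def test_rigid_body_rotates_with_angular_velocity(self):
        """A freely spinning body moves its beads along omega x r."""
        part = mw.build_nanoparticle(mw.NanoparticleSpec(radius=3))
        part.box = np.array([20.0, 20.0, 20.0])
        part.positions += 10.0
        part.body.com += 10.0
        part.body.omega = np.array([0.0, 0.0, 0.5])
        sim = Simulation(part, mw.ForceField.default(),
                         IntegratorParams(seed=1, damp=None))
        r0 = part.body.rel.copy()
        sim.step()
        expected = np.cross(np.array([0.0, 0.0, 0.5]), r0) * 0.01
        np.testing.assert_allclose(part.body.rel - r0, expected, atol=1e-4)

    def test_rigid_body_shape_preserved(self, ff_pair):
        mem = mw.build_membrane(mw.MembraneSpec(n_lipids=128, seed=2))
        part = mw.build_nanoparticle(mw.NanoparticleSpec(radius=2.5))
        sys = mw.combine(mem, part, gap=1.0)
        mw.thermalize(sys, 1.0, np.random.default_rng(6))
        sim = Simulation(sys, ff_pair, IntegratorParams(seed=8))
        r0 = np.linalg.norm(sys.body.rel, axis=1)
        sim.run(500)
        r1 = np.linalg.norm(sys.body.rel, axis=1)
        assert np.abs(r1 - r0).max() < 1e-6


class TestBarostat:
    def test_zero_pressure_leaves_box_unchanged(self):
        st = two_bead_state(4.0, box_edge=12.0)
        sim = Simulation(st, mw.ForceField.default(),
                         IntegratorParams(seed=1, barostat=True))
        box0 = st.box.copy()
        sim.apply_barostat()
        np.testing.assert_array_equal(st.box, box0)

    def test_compressed_patch_expands(self, ff_pair):
        st = mw.build_membrane(
            mw.MembraneSpec(n_lipids=128, area_per_lipid=0.85, seed=2))
        sim = Simulation(st, ff_pair,
                         IntegratorParams(seed=1, barostat=True, pdamp=10.0))
        lx0 = st.box[0]
        for _ in range(50):
            sim.apply_barostat()
            sim._compute_forces()
        assert st.box[0] > lx0
        assert st.box[2] == pytest.approx(st.positions[:, 2].max(), abs=60.0)

    def test_lz_untouched(self, small_membrane, ff_pair):
        sim = Simulation(small_membrane, ff_pair,
                         IntegratorParams(seed=1, barostat=True, pdamp=20.0))
        lz0 = small_membrane.box[2]
        sim.run(200)
        assert small_membrane.box[2] == lz0


class TestCheckpoint:
    def test_roundtrip_resumes_identically(self, tmp_path, ff_pair):
        st = mw.build_membrane(mw.MembraneSpec(n_lipids=72, seed=2))
        mw.thermalize(st, 1.0, np.random.default_rng(3))
        sim = Simulation(st, ff_pair, IntegratorParams(seed=7))
        sim.run(100)
        path = tmp_path / "check.npz"
        sim.save_checkpoint(path)
        sim.run(100)
        sim2 = Simulation.load_checkpoint(path, ff_pair,
                                          IntegratorParams(seed=7))
        sim2.run(100)
        np.testing.assert_allclose(sim2.state.positions, sim.state.positions,
                                   atol=1e-12)
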