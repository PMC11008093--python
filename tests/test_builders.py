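"""Membrane and nanoparticle builders: counts, topology, geometry."""

import numpy as np
import pytest

import memwrap as mw
from memwrap.builders import fibonacci_sphere
from memwrap.species import (HEAD, LIGAND, NP_SURFACE, RECEPTOR_HEAD, TAIL)


class TestMembrane:
    def test_receptor_count_full_membrane(self):
        # 20% of the facing leaflet of the 10,452-lipid membrane
        spec = mw.MembraneSpec(n_lipids=10452, receptor_fraction=0.2)
        assert spec.n_receptors == 1045
        state = mw.build_membrane(spec)
        assert state.receptor_indices.size == 1045

    def test_per_lipid_topology(self):
        state = mw.build_membrane(mw.MembraneSpec(n_lipids=4))
        assert state.n_beads == 12
        assert len(state.bonds) == 8
        assert len(state.angles) == 4
        assert np.count_nonzero(state.species == TAIL) == 8

    @pytest.mark.parametrize("fraction", [0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    def test_receptor_floor_formula(self, fraction):
        spec = mw.MembraneSpec(n_lipids=200, receptor_fraction=fraction,
                               seed=1)
        state = mw.build_membrane(spec)
        assert state.receptor_indices.size == int(fraction * 100)

    def test_receptors_only_in_facing_leaflet(self):
        state = mw.build_membrane(
            mw.MembraneSpec(n_lipids=128, receptor_fraction=1.0))
        # facing leaflet = first half of the lipids; its heads sit higher
        rec_z = state.positions[state.receptor_indices][:, 2]
        head_z = state.positions[state.species == HEAD][:, 2]
        assert state.receptor_indices.size == 64
        assert rec_z.min() > head_z.mean()

    def test_leaflets_balanced(self):
        state = mw.build_membrane(mw.MembraneSpec(n_lipids=72))
        zmid = state.box[2] / 2
        heads = (state.species == HEAD) | (state.species == RECEPTOR_HEAD)
        upper = np.count_nonzero(state.positions[heads][:, 2] > zmid)
        assert upper == 36

    def test_whole_membrane_fraction_switch(self):
        spec = mw.MembraneSpec(n_lipids=200, receptor_fraction=0.2,
                               per_leaflet=False)
        assert spec.n_receptors == 40

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            mw.MembraneSpec(n_lipids=7)
        with pytest.raises(ValueError):
            mw.MembraneSpec(receptor_fraction=1.5)

    def test_deterministic(self):
        a = mw.build_membrane(mw.MembraneSpec(n_lipids=72, seed=9))
        b = mw.build_membrane(mw.MembraneSpec(n_lipids=72, seed=9))
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.species, b.species)


class TestNanoparticle:
    def test_printed_ligand_count(self):
        # radius 12 sigma at half coverage
        spec = mw.NanoparticleSpec(radius=12, ligand_coverage=0.5)
        assert spec.n_surface == 1809
        assert spec.n_ligands == 904
        state = mw.build_nanoparticle(spec)
        assert state.ligand_indices.size == 904

    def test_zero_coverage(self):
        state = mw.build_nanoparticle(
            mw.NanoparticleSpec(radius=7, ligand_coverage=0.0))
        assert state.ligand_indices.size == 0
        assert np.all(state.species == NP_SURFACE)

    def test_beads_exactly_on_sphere(self):
        state = mw.build_nanoparticle(mw.NanoparticleSpec(radius=9))
        r = np.linalg.norm(state.positions, axis=1)
        assert np.all(np.abs(r - 9.0) < 1e-10)

    @pytest.mark.parametrize("radius", [7.0, 10.0])
    def test_near_unit_spacing(self, radius):
        pts = fibonacci_sphere(int(4 * np.pi * radius ** 2), radius)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert 0.8 <= np.median(nn) <= 1.2
        assert nn.min() > 0.5

    def test_rigid_body_attached(self):
        state = mw.build_nanoparticle(mw.NanoparticleSpec(radius=5))
        assert state.body is not None
        assert state.body.indices.size == state.n_beads

    def test_tiny_radius_rejected(self):
        with pytest.raises(ValueError):
            mw.build_nanoparticle(mw.NanoparticleSpec(radius=0.4))

    def test_deterministic(self):
        a = mw.build_nanoparticle(mw.NanoparticleSpec(radius=6, seed=3))
        b = mw.build_nanoparticle(mw.NanoparticleSpec(radius=6, seed=3))
        np.testing.assert_array_equal(a.species, b.species)


class TestCombine:
    def test_particle_placed_above_membrane(self):
        mem = mw.build_membrane(mw.MembraneSpec(n_lipids=512))
        part = mw.build_nanoparticle(mw.NanoparticleSpec(radius=4))
        sys = mw.combine(mem, part, gap=3.0)
        head_top = sys.positions[sys.species == HEAD][:, 2].max()
        np_low = sys.positions[sys.particle_indices][:, 2].min()
        assert np_low == pytest.approx(head_top + 3.0, abs=0.1)
        assert sys.n_beads == mem.n_beads + part.n_beads
        assert sys.body.indices[0] == mem.n_beads

    def test_box_too_short_rejected(self):
        mem = mw.build_membrane(mw.MembraneSpec(n_lipids=512, lz=20.0))
        part = mw.build_nanoparticle(mw.NanoparticleSpec(radius=8))
        with pytest.raises(ValueError):
            mw.combine(mem, part)


class TestWrappedVesicle:
    def test_geometry_and_populations(self):
        spec = mw.NanoparticleSpec(radius=5, ligand_coverage=0.3, seed=3)
        st = mw.build_wrapped_vesicle(spec, receptor_fraction=0.5, seed=4)
        assert st.ligand_indices.size == spec.n_ligands
        # receptors live in the inner leaflet: their heads sit closer to
        # the particle centre than any outer-leaflet head
        center = st.body.com
        rec_r = np.linalg.norm(st.positions[st.receptor_indices] - center,
                               axis=1)
        head_r = np.linalg.norm(
            st.positions[st.species == HEAD] - center, axis=1)
        assert rec_r.max() < head_r.max()
        # particle beads form the trailing rigid block
        assert st.body.indices[0] == 3 * st.n_lipids
        # every lipid: 3 beads, 2 bonds, 1 angle
        assert len(st.bonds) == 2 * st.n_lipids
        assert len(st.angles) == st.n_lipids

    def test_receptor_fraction_of_inner_leaflet(self):
        spec = mw.NanoparticleSpec(radius=5, ligand_coverage=0.2)
        full = mw.build_wrapped_vesicle(spec, receptor_fraction=1.0)
        half = mw.build_wrapped_vesicle(spec, receptor_fraction=0.5)
        n_inner = full.receptor_indices.size
        assert half.receptor_indices.size == n_inner // 2

    def test_initially_wrapped(self):
        st = mw.build_wrapped_vesicle(
            mw.NanoparticleSpec(radius=5, ligand_coverage=0.3, seed=3),
            receptor_fraction=0.5, seed=4)
        counts, mean = mw.ligand_valency(st, mw.LigandReceptorParams())
        assert (counts > 0).mean() > 0.9

    def test_deterministic(self):
        spec = mw.NanoparticleSpec(radius=4, ligand_coverage=0.3, seed=1)
        a = mw.build_wrapped_vesicle(spec, seed=2)
        b = mw.build_wrapped_vesicle(spec, seed=2)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.species, b.species)


class TestEpsilonScaling:
    def test_constant_total_binding(self):
        assert mw.epsilon_for_constant_total_binding(904, 904 * 20.0) == 20.0
        e1 = mw.epsilon_for_constant_total_binding(100, 500.0)
        e2 = mw.epsilon_for_constant_total_binding(200, 500.0)
        assert e1 == 2 * e2
        assert mw.epsilon_for_constant_total_binding(10, 0.0) == 0.0
        with pytest.raises(ValueError):
            mw.epsilon_for_constant_total_binding(0, 100.0)

    def test_rescale_by_valency(self):
        assert mw.rescale_epsilon_by_valency(20.0, 1.0) == 20.0
        assert mw.rescale_epsilon_by_valency(20.0, 5.15) == \
            pytest.approx(3.88, abs=0.01)
        assert mw.rescale_epsilon_by_valency(20.0, 4.35) == \
            pytest.approx(4.60, abs=0.01)
        with pytest.raises(ValueError):
            mw.rescale_epsilon_by_valency(20.0, 0.0)
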