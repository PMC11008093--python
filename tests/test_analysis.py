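"""Valency averaging, wrapping detection, percent error, membrane observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import memwrap as mw
from memwrap.analysis import (NOT_WRAPPED, ValencyTimeSeries, WrappingReport,
                              valency_series)
from memwrap.forcefield import LigandReceptorParams
from memwrap.species import LIGAND, RECEPTOR_HEAD
from memwrap.state import SystemState

from conftest import brute_force_lr_edges, gas_state


def series(times, counts):
    return ValencyTimeSeries(np.asarray(times, dtype=float),
                             np.asarray(counts))


class TestLigandValency:
    def test_uniform_double_binding(self):
        # two receptors flanking each of three ligands
        lig = np.array([[5.0, 5, 5], [8, 5, 5], [11, 5, 5]])
        rec = np.vstack([lig + (1.0, 0, 0), lig - (1.0, 0, 0)])
        pos = np.vstack([lig, rec])
        sp = np.array([LIGAND] * 3 + [RECEPTOR_HEAD] * 6, dtype=np.int64)
        state = SystemState(pos, np.zeros_like(pos), sp, np.full(3, 30.0),
                            np.empty((0, 2)), np.empty(0), np.empty((0, 3)))
        counts, mean = mw.ligand_valency(state, LigandReceptorParams())
        assert np.all(counts == 2)
        assert mean == 2.0

    def test_no_receptors_in_range(self):
        pos = np.array([[5.0, 5, 5], [15, 15, 15]])
        sp = np.array([LIGAND, RECEPTOR_HEAD], dtype=np.int64)
        state = SystemState(pos, np.zeros_like(pos), sp, np.full(3, 40.0),
                            np.empty((0, 2)), np.empty(0), np.empty((0, 3)))
        counts, mean = mw.ligand_valency(state, LigandReceptorParams())
        assert mean == 0.0

    def test_matches_brute_force_adjacency(self):
        rng = np.random.default_rng(3)
        state = gas_state(13, 6.0, rng,
                          species=[LIGAND] * 5 + [RECEPTOR_HEAD] * 8,
                          min_sep=0.7)
        p = LigandReceptorParams()
        counts, _ = mw.ligand_valency(state, p)
        edges = brute_force_lr_edges(state, p.r_cut)
        for k, li in enumerate(state.ligand_indices):
            assert counts[k] == sum(1 for (l, _) in edges if l == li)

    def test_no_ligands_rejected(self):
        state = gas_state(4, 8.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            mw.ligand_valency(state, LigandReceptorParams())

    def test_invariant_under_rigid_translation(self):
        rng = np.random.default_rng(9)
        state = gas_state(16, 8.0, rng,
                          species=[LIGAND] * 6 + [RECEPTOR_HEAD] * 10,
                          min_sep=0.7)
        p = LigandReceptorParams()
        _, m0 = mw.ligand_valency(state, p)
        state.positions += np.array([2.3, -1.1, 0.7])
        state.wrap()
        _, m1 = mw.ligand_valency(state, p)
        assert m0 == m1


class TestTimeAveragedValency:
    def test_constant_series(self):
        s = series([0, 50, 100, 150, 200], np.full((5, 4), 3))
        assert mw.time_averaged_valency(s, wrap_time=0.0) == 3.0

    def test_arithmetic_mean_of_frames(self):
        counts = np.array([[9, 9], [4, 4], [6, 6]])
        s = series([0, 150, 200], counts)
        # frames at 150 and 200 lie in the window; (4 + 6) / 2 = 5
        assert mw.time_averaged_valency(s, wrap_time=10.0) == 5.0

    def test_window_respects_equilibration(self):
        s = series([0, 99, 101], [[10], [10], [2]])
        assert mw.time_averaged_valency(s, wrap_time=0.0) == 2.0

    def test_short_trajectory_rejected(self):
        s = series([0, 50], [[1], [1]])
        with pytest.raises(ValueError):
            mw.time_averaged_valency(s, wrap_time=0.0)


class TestWrappingTime:
    def test_never_wrapped(self):
        s = series(np.arange(0, 100, 10.0), np.zeros((10, 5), dtype=int))
        assert np.isnan(mw.wrapping_time(s))

    def test_step_transition(self):
        t = np.arange(0, 1000, 10.0)
        counts = np.where(t[:, None] >= 500.0, 1, 0) * np.ones((1, 8), int)
        s = series(t, counts)
        assert mw.wrapping_time(s) == 500.0

    def test_transient_spike_not_counted(self):
        t = np.arange(0, 300, 5.0)
        frac = np.zeros(t.size)
        frac[10] = 1.0                # single-frame spike at t = 50
        frac[t >= 200] = 1.0
        counts = (frac[:, None] * np.ones((1, 10))).astype(int)
        s = series(t, counts)
        assert mw.wrapping_time(s) == 200.0

    @given(st.floats(0.5, 0.99), st.floats(0.5, 0.99))
    @settings(max_examples=40, derandomize=True)
    def test_threshold_monotonicity(self, th1, th2):
        rng = np.random.default_rng(77)
        t = np.arange(0, 500, 5.0)
        frac = np.clip(np.linspace(0, 1.2, t.size)
                       + rng.normal(0, 0.05, t.size), 0, 1)
        counts = np.zeros((t.size, 100), dtype=int)
        for k in range(t.size):
            counts[k, :int(frac[k] * 100)] = 1
        s = series(t, counts)
        lo, hi = sorted((th1, th2))
        t_lo = mw.wrapping_time(s, threshold=lo)
        t_hi = mw.wrapping_time(s, threshold=hi)
        if not np.isnan(t_hi):
            assert np.isnan(t_lo) or t_lo <= t_hi


class TestPercentError:
    @pytest.mark.parametrize("nv, iv, expected", [
        (250.0, 250.0, 0.0),
        (125.0, 250.0, -50.0),
        (500.0, 250.0, 100.0),
    ])
    def test_values(self, nv, iv, expected):
        assert mw.percent_error(nv, iv) == pytest.approx(expected)

    def test_monotone_in_unlimited_time(self):
        vals = [mw.percent_error(x, 100.0) for x in (50, 100, 150, 300)]
        assert vals == sorted(vals)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            mw.percent_error(100.0, 0.0)

    def test_report_excludes_unwrapped(self):
        rep = WrappingReport()
        rep.add(200.0, 100.0)
        rep.add(NOT_WRAPPED, 120.0)
        assert rep.n_unwrapped == 1
        assert rep.percent_errors().tolist() == [100.0]
        assert rep.summary()["mean_percent_error"] == 100.0


class TestEnergyValencyDiagnostic:
    def test_equal_energies_mean_valency_one(self):
        assert mw.valency_from_energy(-500.0, -500.0, 20.0, 10) == 1.0

    def test_one_extra_receptor_per_ligand(self):
        # pair system deeper by eps * N_L than the bonded one
        assert mw.valency_from_energy(-700.0, -500.0, 20.0, 10) == 2.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mw.valency_from_energy(-1.0, -1.0, 20.0, 0)
        with pytest.raises(ValueError):
            mw.valency_from_energy(-1.0, -1.0, 0.0, 5)

    def test_tracks_measured_valency_on_synthetic_frame(self):
        """The energy-difference estimate agrees with the direct count
        when every bound receptor sits at full well depth."""
        rng = np.random.default_rng(4)
        n_lig = 6
        lig = np.column_stack([np.linspace(4, 24, n_lig),
                               np.full(n_lig, 10.0), np.full(n_lig, 10.0)])
        offsets = np.array([[1.05, 0, 0], [-1.05, 0, 0], [0, 1.05, 0]])
        rec = np.vstack([lig + o for o in offsets])
        pos = np.vstack([lig, rec])
        sp = np.array([LIGAND] * n_lig + [RECEPTOR_HEAD] * len(rec),
                      dtype=np.int64)
        state = SystemState(pos, np.zeros_like(pos), sp, np.full(3, 40.0),
                            np.empty((0, 2)), np.empty(0), np.empty((0, 3)))
        p = LigandReceptorParams()
        counts, mean_x = mw.ligand_valency(state, p)
        # all receptors are inside the plateau: U_pair = -eps * edges
        u_pair = -p.epsilon_LR * counts.sum()
        u_bond = -p.epsilon_LR * n_lig      # one bond per ligand
        est = mw.valency_from_energy(u_pair, u_bond, p.epsilon_LR, n_lig)
        assert est == pytest.approx(mean_x, abs=0.5)


class TestAreaPerLipid:
    def test_static_box_identity(self):
        apl = mw.area_per_lipid([77.0] * 10, [77.0] * 10, 10452)
        assert mw.predicted_box_edge(apl, 10452) == pytest.approx(77.0)

    def test_edge_scales_with_sqrt_lipids(self):
        apl = 1.2
        e1 = mw.predicted_box_edge(apl, 1000)
        e2 = mw.predicted_box_edge(apl, 2000)
        assert e2 == pytest.approx(np.sqrt(2) * e1)

    def test_window_selection(self):
        lx = [10.0] * 5 + [20.0] * 5
        apl = mw.area_per_lipid(lx, lx, 100, window=slice(5, None))
        assert apl == pytest.approx(400.0 / 50)


def test_unit_calibration_roundtrip():
    from memwrap import units
    assert units.sigma_to_nm(1.0) == pytest.approx(0.9)
    assert units.nm_to_sigma(units.sigma_to_nm(3.3)) == pytest.approx(3.3)
    assert units.tau_to_ns(2.0) == pytest.approx(2.0)


def test_valency_series_packaging():
    class FakeSampler:
        time = [0.0, 1.0]
        counts = [np.array([1, 2]), np.array([3, 4])]

    s = valency_series(FakeSampler())
    assert s.frame_mean.tolist() == [1.5, 3.5]
    assert s.bound_fraction.tolist() == [1.0, 1.0]
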