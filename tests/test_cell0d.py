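"""0D cell model: resting state, AP, pacing, SRF injection, classification."""

import numpy as np
import pytest

import srfsim._kernels as K
from srfsim.cell0d import (
    CellModel,
    CellParams,
    classify_dad_ta,
    run_pacing_protocol,
    whole_cell_jrel,
)
from srfsim.sampling import SRFDistribution
from srfsim.waveform import SRFWaveform, eval_waveform


@pytest.fixture(scope="module")
def settled_cell():
    cell = CellModel(CellParams(), seed=1)
    cell.run(3000.0)
    return cell


class TestWholeCellJrel:
    def test_zero_open_fraction(self):
        assert whole_cell_jrel(0.0, 3.0, 1.0, 0.1) == 0.0

    def test_zero_gradient(self):
        assert whole_cell_jrel(0.5, 3.0, 0.001, 1.0) == 0.0

    def test_linear_scaling(self):
        assert whole_cell_jrel(0.1, 2.0, 1.0, 0.0) == pytest.approx(0.1 * 2.0 * 1000.0)


class TestBasicElectrophysiology:
    def test_stable_resting_state(self, settled_cell):
        rec = settled_cell.run(1000.0)
        assert np.ptp(rec["vm"]) < 0.5
        assert -90.0 < rec["vm"][-1] < -75.0

    def test_action_potential_contract(self, settled_cell):
        rec = settled_cell.run(600.0, stim_times=[10.0])
        assert rec["vm"].max() > 0.0
        assert rec["vm"][-1] < -70.0
        assert rec["ca_cyto"].max() > 3 * rec["ca_cyto"][0]

    def test_apd_ordering_across_cell_types(self):
        apds = {}
        for ct in ("atrial", "vent_epi", "vent_endo", "vent_m"):
            cell = CellModel(CellParams(cell_type=ct), seed=1)
            cell.run(2500.0)
            rest = cell.S[0, K.IV]
            rec = cell.run(800.0, stim_times=[5.0])
            vm = rec["vm"]
            v90 = vm.max() - 0.9 * (vm.max() - rest)
            above = vm > v90
            apds[ct] = above.sum()
        assert apds["atrial"] < apds["vent_epi"] < apds["vent_endo"] < apds["vent_m"]

    def test_closed_cell_calcium_conserved(self):
        cell = CellModel(CellParams(sarco_scale=0.0), seed=2)
        tot0 = cell.total_calcium()
        cell.run(500.0, stim_times=[10.0])
        assert abs(cell.total_calcium() - tot0) / tot0 < 1e-6

    def test_dt_bound_enforced(self):
        with pytest.raises(ValueError):
            CellModel(CellParams(), dt=0.05)


class TestSRFInjection:
    def _dvm_for_peak(self, n_peak, g_k1_scale=1.0, casr=1.0):
        from dataclasses import replace

        p = CellParams()
        p = replace(p, g_k1=p.g_k1 * g_k1_scale)
        cell = CellModel(p, seed=2)
        cell.run(2000.0)
        cell.set_casr(casr)
        w = SRFWaveform(t_i=50.0, lam=150.0, t_p=125.0, n_peak=n_peak)
        tab = K.build_voltage_table(0.02)
        v0 = cell.S[0, K.IV]
        vmax = v0
        # drive the override directly with the analytical waveform
        t0 = cell.t
        for step in range(400):
            tt = cell.t - t0
            val = eval_waveform(tt, w)
            cell._override[0] = val if val > 1e-4 else -1.0
            for _ in range(50):
                K.step_cells(cell.S, cell.P, 0.02, cell.t, cell._stim,
                             cell._diff, cell._override, tab)
                cell.t += 0.02
            vmax = max(vmax, cell.S[0, K.IV])
        return vmax - v0

    def test_depolarisation_monotone_in_release_amplitude(self):
        dvs = [self._dvm_for_peak(p) for p in (0.05, 0.1, 0.2)]
        assert dvs[0] < dvs[1] < dvs[2]
        assert dvs[0] < 10.0  # small release stays a sub-threshold DAD

    def test_reduced_ik1_lowers_ta_threshold(self):
        def min_ta_peak(scale):
            for n_peak in (0.1, 0.15, 0.2, 0.25, 0.3, 0.4):
                if self._dvm_for_peak(n_peak, g_k1_scale=scale) > 60.0:
                    return n_peak
            return np.inf

        assert min_ta_peak(0.7) < min_ta_peak(1.0)


class TestPacingProtocol:
    def test_srf_off_runs_identical(self):
        kw = dict(bcl=350.0, n_beats=2, quiescent=400.0, n_trials=2,
                  n_prepace=8)
        trials = run_pacing_protocol(CellParams(), seed=5, **kw)
        assert np.array_equal(trials[0]["traces"]["vm"], trials[1]["traces"]["vm"])

    def test_zero_release_probability_matches_srf_off(self):
        d = SRFDistribution(p_scr=0.0, ti_sep=400.0, k_f1=50.0, k_f2=50.0,
                            md=100.0, dw1=40.0, dw2=40.0)
        kw = dict(bcl=350.0, n_beats=2, quiescent=400.0, n_trials=1,
                  n_prepace=8)
        on = run_pacing_protocol(CellParams(), seed=6, srf_mode="direct",
                                 srf_params=d, **kw)
        off = run_pacing_protocol(CellParams(), seed=6, srf_mode="off", **kw)
        assert np.array_equal(on[0]["traces"]["vm"], off[0]["traces"]["vm"])

    def test_sr_load_monotone_in_pacing_rate(self):
        loads = {}
        for bcl in (300.0, 450.0, 600.0):
            cell = CellModel(CellParams(), seed=1)
            for _ in range(45):
                cell.run(bcl, stim_times=[2.0])
            loads[bcl] = cell.S[0, K.ICANSR]
        assert loads[300.0] > loads[450.0] > loads[600.0]

    def test_direct_mode_produces_diastolic_events(self):
        d = SRFDistribution(p_scr=1.0, ti_sep=500.0, k_f1=60.0, k_f2=80.0,
                            md=120.0, dw1=50.0, dw2=60.0)
        trials = run_pacing_protocol(
            CellParams(iso=True), bcl=350.0, n_beats=3, quiescent=1200.0,
            n_trials=5, seed=7, srf_mode="direct", srf_params=d, n_prepace=12)
        assert all(tr["n_events"] >= 1 for tr in trials)
        assert any(tr["classification"] in ("DAD", "TA") for tr in trials)


class TestClassifier:
    def test_flat_trace_is_none(self):
        t = np.arange(0.0, 500.0)
        vm = np.full_like(t, -80.0)
        assert classify_dad_ta(t, vm, (0.0, 500.0)) == "none"

    def test_subthreshold_bump_is_dad(self):
        t = np.arange(0.0, 500.0)
        vm = -80.0 + 5.0 * np.exp(-((t - 250.0) / 40.0) ** 2)
        assert classify_dad_ta(t, vm, (0.0, 500.0)) == "DAD"

    def test_full_upstroke_is_ta(self):
        t = np.arange(0.0, 500.0)
        vm = np.where((t > 250) & (t < 350), 20.0, -80.0)
        assert classify_dad_ta(t, vm, (0.0, 500.0)) == "TA"

    def test_short_window_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            classify_dad_ta(t, np.full_like(t, -80.0), (0.0, 40.0))
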