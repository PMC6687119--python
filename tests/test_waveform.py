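"""Analytical SRF waveform shapes, derived parameters and amplitudes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srfsim.waveform import (
    SHAPE,
    InvalidWaveformError,
    SRFWaveform,
    derived_spike_params,
    eval_plateau,
    eval_spike,
    eval_waveform,
    expected_amplitudes,
)


class TestDerivedSpikeParams:
    def test_degenerate_peak_at_initiation_gives_offset_width(self):
        w = SRFWaveform(t_i=0.0, lam=100.0, t_p=0.0, n_peak=0.2)
        assert derived_spike_params(w)["k1"] == pytest.approx(0.00255)

    def test_symmetric_waveform_arithmetic(self):
        w = SRFWaveform(t_i=0.0, lam=100.0, t_p=50.0, n_peak=0.2)
        p = derived_spike_params(w)
        assert p["t1"] == 25.0
        assert p["t2"] == 75.0
        assert p["k1"] == pytest.approx(0.1689 * 50.0 + 0.00255)
        assert p["k1"] == p["k2"]

    @pytest.mark.parametrize("t_p", [30.0, 50.0, 70.0])
    def test_symmetry_of_widths(self, t_p):
        w = SRFWaveform(t_i=0.0, lam=2 * t_p, t_p=t_p, n_peak=0.1)
        p = derived_spike_params(w)
        assert p["k1"] == pytest.approx(p["k2"])

    def test_reversed_ordering_rejected(self):
        with pytest.raises(InvalidWaveformError):
            SRFWaveform(t_i=0.0, lam=100.0, t_p=150.0, n_peak=0.1)


class TestEvalSpike:
    def test_tail_is_negligible(self):
        w = SRFWaveform(t_i=100.0, lam=100.0, t_p=150.0, n_peak=0.3)
        k1 = derived_spike_params(w)["k1"]
        assert eval_spike(w.t_i - 10 * k1, w) < 1e-3 * w.n_peak

    def test_value_matches_direct_two_sigmoid_product(self):
        w = SRFWaveform(t_i=0.0, lam=300.0, t_p=150.0, n_peak=0.1)
        p = derived_spike_params(w)
        t = 75.0
        expected = (w.n_peak
                    / (1.0 + np.exp(-(t - p["t1"]) / p["k1"]))
                    / (1.0 + np.exp((t - p["t2"]) / p["k2"])))
        assert eval_spike(t, w) == pytest.approx(expected, rel=1e-12)

    def test_numeric_maximum_close_to_peak_amplitude(self):
        # with edge widths k = 0.1689 * interval the two-sigmoid product
        # peaks at ~0.90 n_peak; verify against numeric maximisation
        w = SRFWaveform(t_i=0.0, lam=200.0, t_p=100.0, n_peak=0.4)
        t = np.linspace(-100.0, 300.0, 40001)
        m = eval_spike(t, w).max()
        assert 0.85 * w.n_peak < m <= w.n_peak

    def test_unimodal(self):
        w = SRFWaveform(t_i=0.0, lam=150.0, t_p=60.0, n_peak=0.2)
        y = eval_spike(np.linspace(-50, 250, 3001), w)
        d = np.diff(y)
        switch = np.nonzero(np.sign(d[:-1]) > np.sign(d[1:]))[0]
        assert len(switch) == 1


class TestEvalPlateau:
    def w(self, **kw):
        d = dict(t_i=0.0, lam=500.0, t_p=250.0, n_peak=0.12, n_plateau=0.04)
        d.update(kw)
        return SRFWaveform(**d)

    def test_mid_plateau_level(self):
        w = self.w()
        assert eval_plateau(100.0, w) == pytest.approx(w.n_plateau, rel=0.01)

    def test_spike_half_activation_matches_direct_evaluation(self):
        w = self.w()
        t = w.t_p - 25.0
        base = (w.n_plateau
                / (1.0 + np.exp(-(t - (w.t_i + 17.5)) / 5.946))
                / (1.0 + np.exp((t - (w.t_f - 17.5)) / 5.946)))
        spike = (w.n_peak - w.n_plateau) * 0.5 / (
            1.0 + np.exp((t - (w.t_p + 17.5)) / 5.946))
        assert eval_plateau(t, w) == pytest.approx(base + spike, rel=1e-12)

    def test_zero_at_infinity(self):
        w = self.w()
        assert eval_plateau(-1e4, w) == pytest.approx(0.0, abs=1e-12)
        assert eval_plateau(1e4, w) == pytest.approx(0.0, abs=1e-12)

    def test_spike_window_violation_rejected(self):
        with pytest.raises(InvalidWaveformError):
            self.w(t_p=10.0)


class TestDispatchAndAmplitudes:
    def test_morphology_dispatch_threshold(self):
        assert SRFWaveform(t_i=0, lam=400, t_p=200, n_peak=0.1,
                           n_plateau=0.05).morphology == "plateau"
        assert SRFWaveform(t_i=0, lam=200, t_p=100,
                           n_peak=0.1).morphology == "spike"
        # bisect the dispatch threshold over lam
        lo, hi = 200.0, 400.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            w = SRFWaveform(t_i=0, lam=mid, t_p=mid / 2, n_peak=0.1,
                            n_plateau=0.05)
            if w.morphology == "plateau":
                hi = mid
            else:
                lo = mid
        assert hi == pytest.approx(300.0, abs=1e-6)

    def test_expected_peak_asymptote(self):
        assert expected_amplitudes(1e7)["exp_peak"] == pytest.approx(0.059, abs=1e-4)

    def test_expected_amplitudes_at_reference_durations(self):
        out = expected_amplitudes(300.0)
        assert out["exp_peak"] == pytest.approx(692.99 * 300.0**-1.6 + 0.059,
                                                rel=1e-12)
        assert "exp_plateau" not in out
        out = expected_amplitudes(500.0)
        assert out["exp_plateau"] == pytest.approx(31.09 * 5.0**-7.39 + 0.034,
                                                   rel=1e-12)

    def test_expected_amplitudes_strictly_decreasing(self):
        lams = np.linspace(80.0, 2000.0, 200)
        peaks = [expected_amplitudes(l)["exp_peak"] for l in lams]
        assert np.all(np.diff(peaks) < 0)
        lams = np.linspace(301.0, 2000.0, 100)
        plats = [expected_amplitudes(l)["exp_plateau"] for l in lams]
        assert np.all(np.diff(plats) < 0)

    def test_invalid_duration(self):
        with pytest.raises(InvalidWaveformError):
            expected_amplitudes(0.0)


@settings(max_examples=100, deadline=None)
@given(
    t_i=st.floats(0.0, 500.0),
    lam=st.floats(20.0, 1500.0),
    frac=st.floats(0.15, 0.85),
    n_peak=st.floats(0.01, 1.0),
)
def test_waveform_values_bounded_and_area_positive(t_i, lam, frac, n_peak):
    """Any valid waveform stays in [0, 1] and encloses positive area."""
    t_p = t_i + frac * lam
    if lam > SHAPE.morphology_threshold:
        t_p = max(t_p, t_i + 42.5)
        w = SRFWaveform(t_i=t_i, lam=lam, t_p=t_p, n_peak=n_peak,
                        n_plateau=0.3 * n_peak)
    else:
        w = SRFWaveform(t_i=t_i, lam=lam, t_p=t_p, n_peak=n_peak)
    t = np.linspace(t_i - 200.0, t_i + lam + 200.0, 2000)
    y = eval_waveform(t, w)
    assert np.all(y >= 0.0) and np.all(y <= 1.0)
    assert np.trapezoid(y, t) > 0.0


def test_area_increases_with_peak_amplitude():
    t = np.linspace(-100.0, 400.0, 4000)
    areas = []
    for n_peak in (0.1, 0.2, 0.4, 0.8):
        w = SRFWaveform(t_i=0.0, lam=200.0, t_p=90.0, n_peak=n_peak)
        areas.append(np.trapezoid(eval_waveform(t, w), t))
    assert np.all(np.diff(areas) > 0)
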