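"""Inverse-transform sampling and the three SRF parameterisation modes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srfsim.sampling import (
    FIG11_BASELINE,
    DWFitParams,
    GeneralDynamicParams,
    InvalidDistributionError,
    SRFDistribution,
    duration_cdf,
    dw_from_md,
    default_dynamic_fit_coefficients,
    dynamic_fit_map,
    general_dynamic_map,
    sample_amplitudes,
    sample_duration,
    sample_ti,
    sample_tp,
    sample_waveform,
    ti_cdf,
)


def ks_distance(samples, cdf):
    s = np.sort(samples)
    ecdf = (np.arange(1, len(s) + 1) - 0.5) / len(s)
    return float(np.max(np.abs(cdf(s) - ecdf)))


class TestSampleTi:
    def test_separation_point_quantile(self, basic_distribution):
        d = basic_distribution
        assert sample_ti(d.cf_ti_sep, d) == pytest.approx(d.ti_sep)

    def test_known_inverse_value(self):
        # u = 0.2 on the lower branch: ti_sep - k_f1 * ln(2 cf / u - 1)
        d = SRFDistribution(p_scr=1.0, ti_sep=300.0, k_f1=100.0, k_f2=100.0,
                            md=100.0, dw1=50.0, dw2=50.0)
        assert sample_ti(0.2, d) == pytest.approx(300.0 - 100.0 * math.log(3.0),
                                                  abs=1e-9)

    def test_empirical_cdf_round_trip(self, basic_distribution, rng):
        d = basic_distribution
        ti = sample_ti(rng.random(100_000), d)
        assert ks_distance(ti, lambda t: ti_cdf(t, d)) < 0.01

    def test_cdf_continuous_at_separation(self, basic_distribution):
        d = basic_distribution
        eps = 1e-9
        below = ti_cdf(d.ti_sep - eps, d)
        above = ti_cdf(d.ti_sep + eps, d)
        assert below == pytest.approx(d.cf_ti_sep, abs=1e-6)
        assert above == pytest.approx(d.cf_ti_sep, abs=1e-6)

    def test_extreme_uniform_draws_clamped(self, basic_distribution):
        assert np.isfinite(sample_ti(0.0, basic_distribution))
        assert np.isfinite(sample_ti(1.0, basic_distribution))


class TestSampleDuration:
    def test_median_draw(self, basic_distribution):
        assert sample_duration(0.5, basic_distribution) == pytest.approx(
            basic_distribution.md)

    def test_known_inverse_value(self):
        d = SRFDistribution(p_scr=1.0, ti_sep=300.0, k_f1=100.0, k_f2=100.0,
                            md=300.0, dw1=100.0, dw2=150.0)
        assert sample_duration(0.25, d) == pytest.approx(
            300.0 - 0.261 * 100.0 * math.log(3.0), abs=1e-9)

    def test_empirical_cdf_round_trip(self, basic_distribution, rng):
        d = basic_distribution
        lam = sample_duration(rng.random(100_000), d)
        assert ks_distance(lam, lambda x: duration_cdf(x, d)) < 0.01


class TestDwFromMd:
    P = DWFitParams(a_dw1=80.0, a_dw2=120.0, mid_dw1=250.0, mid_dw2=300.0,
                    k_dw1=50.0, k_dw2=60.0, dw1_min=20.0, dw2_min=30.0)

    def test_asymptotes(self):
        lo = dw_from_md(1e-6, self.P)
        hi = dw_from_md(1e6, self.P)
        assert lo["dw1"] == pytest.approx(self.P.dw1_min, abs=0.6)
        assert hi["dw1"] == pytest.approx(self.P.a_dw1 + self.P.dw1_min, rel=1e-6)

    def test_half_activation(self):
        out = dw_from_md(self.P.mid_dw1, self.P)
        assert out["dw1"] == pytest.approx(self.P.a_dw1 / 2 + self.P.dw1_min)

    def test_distribution_resolves_widths_from_md(self):
        d = SRFDistribution(p_scr=0.5, ti_sep=300.0, k_f1=50.0, k_f2=50.0,
                            md=250.0, dw_mode="from_md", dw_params=self.P)
        assert d.dw1 == pytest.approx(self.P.a_dw1 / 2 + self.P.dw1_min)


class TestSampleTpAndAmplitudes:
    def test_peak_window_bounds(self):
        assert sample_tp(0.0, 10.0, 200.0) == pytest.approx(10.0 + 25.0)
        assert sample_tp(1.0, 10.0, 200.0) == pytest.approx(10.0 + 148.0)

    def test_short_event_midpoint_fallback(self):
        assert sample_tp(0.7, 0.0, 60.0) == pytest.approx(30.0)

    def test_amplitude_expectation_and_jitter(self):
        out = sample_amplitudes(0.5, 0.5, 150.0)
        assert out["n_peak"] == pytest.approx(692.99 * 150.0**-1.6 + 0.059)
        lo = sample_amplitudes(0.0, 0.5, 150.0)["n_peak"]
        hi = sample_amplitudes(1.0, 0.5, 150.0)["n_peak"]
        assert hi - lo == pytest.approx(0.05)

    def test_plateau_jitter_endpoints(self):
        exp_plat = 31.09 * (0.01 * 500.0) ** -7.39 + 0.034
        lo = sample_amplitudes(0.5, 0.0, 500.0)["n_plateau"]
        hi = sample_amplitudes(0.5, 1.0, 500.0)["n_plateau"]
        assert lo == pytest.approx(exp_plat * (1 - 0.125), rel=1e-9)
        assert hi == pytest.approx(exp_plat * (1 + 0.125), rel=1e-9)


class TestSampleWaveform:
    def test_deterministic_given_seed(self, basic_distribution):
        w1 = sample_waveform(np.random.default_rng(7), basic_distribution)
        w2 = sample_waveform(np.random.default_rng(7), basic_distribution)
        assert w1 == w2

    def test_median_duration(self, basic_distribution, rng):
        lams = [sample_waveform(rng, basic_distribution).lam
                for _ in range(10_000)]
        assert np.median(lams) == pytest.approx(basic_distribution.md, rel=0.02)

    def test_amplitude_duration_anticorrelation(self, rng):
        from scipy import stats

        d = SRFDistribution(p_scr=1.0, ti_sep=400.0, k_f1=50.0, k_f2=50.0,
                            md=250.0, dw1=350.0, dw2=500.0)
        ws = [sample_waveform(rng, d) for _ in range(4000)]
        lam = np.array([w.lam for w in ws])
        keep = (lam >= 50) & (lam <= 600)
        rho = stats.spearmanr(lam[keep],
                              np.array([w.n_peak for w in ws])[keep]).statistic
        assert rho < -0.8


@settings(max_examples=200, deadline=None)
@given(
    ti_sep=st.floats(50.0, 1000.0),
    k1=st.floats(5.0, 300.0),
    k2=st.floats(5.0, 300.0),
    cf=st.floats(0.1, 0.9),
    md=st.floats(30.0, 800.0),
    dw1=st.floats(10.0, 400.0),
    dw2=st.floats(10.0, 400.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_sampled_waveforms_always_valid(ti_sep, k1, k2, cf, md, dw1, dw2, seed):
    """Every draw from any valid distribution yields a valid waveform."""
    d = SRFDistribution(p_scr=1.0, ti_sep=ti_sep, k_f1=k1, k_f2=k2,
                        cf_ti_sep=cf, md=md, dw1=dw1, dw2=dw2)
    w = sample_waveform(np.random.default_rng(seed), d)
    assert w.t_i >= 0.0
    assert w.lam >= 10.0
    assert w.t_i <= w.t_p <= w.t_f
    assert 0.0 <= w.n_plateau <= w.n_peak <= 1.0


class TestGeneralDynamic:
    def test_probability_endpoints(self, fig11_baseline):
        p = fig11_baseline
        assert general_dynamic_map(p.casr_threshold, p).p_scr == pytest.approx(
            0.02, abs=1e-6)
        assert general_dynamic_map(p.casr_threshold + p.casr_p_range,
                                   p).p_scr == pytest.approx(0.98, abs=1e-6)
        assert general_dynamic_map(p.casr_threshold - 5 * p.casr_p_range,
                                   p).p_scr < 0.02

    def test_saturated_median_duration(self, fig11_baseline):
        assert general_dynamic_map(fig11_baseline.casr_max,
                                   fig11_baseline).md == 150.0
        assert general_dynamic_map(2.0, fig11_baseline).md == 150.0

    def test_monotone_decreasing_md_and_ti_sep(self, fig11_baseline):
        cs = np.linspace(1.0, 1.7, 100)
        md = [general_dynamic_map(c, fig11_baseline).md for c in cs]
        ts = [general_dynamic_map(c, fig11_baseline).ti_sep for c in cs]
        assert np.all(np.diff(md) <= 0)
        assert np.all(np.diff(ts) <= 0)

    def test_invariant_violation_rejected(self):
        with pytest.raises(InvalidDistributionError):
            GeneralDynamicParams(
                casr_threshold=1.0, casr_p_range=0.3, casr_max=1.2,
                ti_sep_min=100, ti_sep_max=500, ti_width_min=50,
                ti_width_max=200, md_min=100, md_max=300,
                lam_width_min=30, lam_width_max=100)


class TestDynamicFit:
    def test_shipped_coefficients_monotone(self):
        c = default_dynamic_fit_coefficients()
        for cond in ("control", "r_cru_cru", "r_serca_ncx"):
            cs = np.linspace(0.9, 1.3, 50)
            p = [dynamic_fit_map(x, c, cond).p_scr for x in cs]
            md = [dynamic_fit_map(x, c, cond).md for x in cs]
            assert np.all(np.diff(p) >= -1e-12)
            assert np.all(np.diff(md) <= 1e-9)

    def test_out_of_range_clamped_with_warning(self):
        c = default_dynamic_fit_coefficients()
        with pytest.warns(UserWarning, match="outside fitted range"):
            d = dynamic_fit_map(2.5, c, "control")
        ref = dynamic_fit_map(c.casr_range["control"][1], c, "control")
        assert d.md == pytest.approx(ref.md)

    def test_condition_aliases(self):
        c = default_dynamic_fit_coefficients()
        a = dynamic_fit_map(1.1, c, "R_CRU-CRU")
        b = dynamic_fit_map(1.1, c, "r_cru_cru")
        assert a.md == b.md
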