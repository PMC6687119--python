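import numpy as np
import pytest

from srfsim.sampling import GeneralDynamicParams, SRFDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def basic_distribution():
    """A representative SRF distribution with negligible mass below t=0."""
    return SRFDistribution(p_scr=1.0, ti_sep=500.0, k_f1=60.0, k_f2=90.0,
                           md=300.0, dw1=100.0, dw2=150.0)


@pytest.fixture
def fig11_baseline():
    from srfsim.sampling import FIG11_BASELINE

    return FIG11_BASELINE


@pytest.fixture
def reentry_gd():
    """General Dynamic parameters matched to the desk-scale re-entry loading."""
    return GeneralDynamicParams(
        casr_threshold=1.02, casr_p_range=0.04, casr_max=1.10,
        ti_sep_min=80.0, ti_sep_max=500.0, ti_width_min=15.0,
        ti_width_max=250.0, md_min=40.0, md_max=200.0,
        lam_width_min=10.0, lam_width_max=100.0, h_width=2.5)
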