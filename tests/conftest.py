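import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=40)
settings.load_profile("suite")

from phantomt1 import build_layout, ir_protocol, render_series


@pytest.fixture(scope="session")
def layout3():
    return build_layout(3.0)


@pytest.fixture(scope="session")
def layout15():
    return build_layout(1.5)


@pytest.fixture(scope="session")
def ir_series_clean(layout3):
    """Noise-free IR series of the 3 T phantom."""
    return render_series(layout3, ir_protocol())


@pytest.fixture(scope="session")
def ir_series_snr50(layout3):
    """IR series at SNR ~ 50 in the unit-signal phantom."""
    return render_series(layout3, ir_protocol(noise_sigma=0.02, rng_seed=5))
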