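import numpy as np
import pytest

from neurofei.bands import FrequencyBin, band_envelope, design_bandpass
from neurofei.timeseries import TimeSeries

ALPHA = FrequencyBin(8.0, 10.5, index=4)
FS = 250.0


@pytest.fixture(scope="session")
def alpha_bin() -> FrequencyBin:
    return ALPHA


@pytest.fixture(scope="session")
def alpha_fir():
    return design_bandpass(ALPHA, FS)


@pytest.fixture(scope="session")
def white_noise_envelope(alpha_fir):
    """Alpha-band envelope of 400 s of Gaussian white noise at 250 Hz."""
    rng = np.random.default_rng(42)
    ts = TimeSeries(rng.standard_normal(int(400 * FS)), FS)
    return band_envelope(ts, ALPHA, fir=alpha_fir)


@pytest.fixture(scope="session")
def tiny_cros_raster():
    """A short run of a small grid network, shared across tests."""
    from neurofei.cros import NetworkConfig, build_network, run_simulation

    cfg = NetworkConfig(grid_side=20, c_e=40.0, c_i=40.0, seed=11)
    return run_simulation(build_network(cfg), duration=20.0)
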