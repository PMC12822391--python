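import numpy as np
import pytest

from bindrisk.spectra import EmissionSpectrum, TitrationSeries
from bindrisk.synthetic import DEFAULT_CONCS, SimConfig, gen_enhancement_series, gen_titration_series


@pytest.fixture
def noiseless_cfg():
    return SimConfig(seed=1, noise_sd=0.0)


@pytest.fixture
def quench_series():
    """Noiseless single-site static-quenching series, Ksv = Ka = 3.57e4 L/mol."""
    ksv = 3.57e4
    return {q: 1000.0 / (1.0 + ksv * q) for q in DEFAULT_CONCS}


@pytest.fixture
def enhancement_series():
    """Noiseless saturable enhancement series, Ka = 4.16e4, F0=1000, Finf=3000."""
    ka, f0, finf = 4.16e4, 1000.0, 3000.0
    return {q: f0 + (finf - f0) * ka * q / (1.0 + ka * q) for q in DEFAULT_CONCS}


@pytest.fixture
def gaussian_spectrum():
    wl = np.linspace(300.0, 400.0, 101)
    it = 1000.0 * np.exp(-0.5 * ((wl - 335.0) / 25.0) ** 2)
    return EmissionSpectrum(wl, it, quencher_conc=0.0, temperature=298.0)


@pytest.fixture
def quench_titration(noiseless_cfg):
    return gen_titration_series(3.57e4, cfg=noiseless_cfg)


@pytest.fixture
def enhancement_titration(noiseless_cfg):
    return gen_enhancement_series(4.16e4, cfg=noiseless_cfg)
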