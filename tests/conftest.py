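import numpy as np
import pytest

import ccframan as cf


@pytest.fixture(scope="session")
def windows():
    """The packaged 25-window ccfDNA reference table."""
    return cf.load_reference_windows()


@pytest.fixture(scope="session")
def quiet_config():
    """Simulation defaults with noise but no cosmic spikes (ground truth
    stays trivially comparable)."""
    return cf.SyntheticGroupConfig(spike_rate=0.0)


@pytest.fixture(scope="session")
def male_spectrum(windows, quiet_config):
    """One healthy-male acquisition plus its generative components."""
    config = cf.config_from_reference(
        "Healthy Male ccfDNA", windows, defaults=quiet_config
    )
    spectrum, components = cf.simulate_spectrum(
        config, 0, 0, seed=7, return_components=True
    )
    return config, spectrum, components


def flat_spectrum(value=0.0, n=501, start=300.0):
    shifts = start + np.arange(n, dtype=float)
    return cf.RamanSpectrum(shifts=shifts, intensities=np.full(n, float(value)))
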