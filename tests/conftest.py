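import numpy as np
import pytest

from soilspec import SpectrumSet, SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """60 x 750 synthetic spectra with ground truth, shared read-only."""
    return generate(SyntheticConfig(n_samples=60, n_channels=750, seed=62710))


@pytest.fixture()
def toy_spectra():
    """Tiny deterministic SpectrumSet for unit tests."""
    rng = np.random.default_rng(7)
    wavelengths = np.linspace(400.0, 499.0, 100)
    intensities = 0.5 + 0.1 * rng.standard_normal((5, 100)).cumsum(axis=1) * 0.05
    return SpectrumSet(wavelengths, intensities, [f"t{i}" for i in range(5)])
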