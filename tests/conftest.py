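import numpy as np
import pytest

from plumspec import GeneratorConfig, generate_dataset, make_split, truncate_wavelengths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_campaign():
    """The default synthetic campaign (linear response), truncated to the
    analysis window, with its ground truth."""
    spectra, reference, truth = generate_dataset(GeneratorConfig(seed=0))
    spectra = truncate_wavelengths(spectra)
    return spectra, reference, truth


@pytest.fixture(scope="session")
def default_xy(default_campaign):
    spectra, reference, truth = default_campaign
    return spectra.absorbance, reference.aligned_to(spectra), spectra.wavelengths_nm


@pytest.fixture(scope="session")
def default_split():
    return make_split(160, seed=0)
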