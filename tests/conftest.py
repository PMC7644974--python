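import pytest

from isodiel.pairing import pair_with_internal_standard
from isodiel.synthetic import GeneratorConfig, generate_library, generate_study


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def default_library(default_config):
    return generate_library(default_config)


@pytest.fixture(scope="session")
def default_bundle(default_config, default_library):
    return generate_study(default_config, default_library)


@pytest.fixture(scope="session")
def default_pairs(default_bundle):
    return {
        sample: pair_with_internal_standard(feats)
        for sample, feats in default_bundle.mixed_features.items()
    }


@pytest.fixture(scope="session")
def small_config():
    """A miniature study for fast I/O and CLI tests."""
    return GeneratorConfig(seed=3, n_metabolites=6, n_unknown=3, n_background=5)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_study(small_config)
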