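import pytest

from karyokit import GeneratorConfig, default_band_map, generate


@pytest.fixture(scope="session")
def band_map():
    return default_band_map()


@pytest.fixture(scope="session")
def sample_karyotypes(band_map):
    """A seeded sample shared by the property-style tests."""
    return generate(GeneratorConfig(seed=20260929, n=300), band_map)
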