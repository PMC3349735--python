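import pytest

from tfbindmode.synthgen import SimConfig, generate_bundle


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size simulation for fast unit tests (same structure as default)."""
    return SimConfig(
        seed=7,
        n_chrom=2,
        chrom_length=1_200_000,
        n_genes_universe=150,
        n_unique=60,
        n_redundant=50,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """Bundle at the default (study-scale) configuration."""
    return generate_bundle(SimConfig(seed=11))
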