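import pytest

from ibrd.synthetic import SimConfig, generate_fixture


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort for unit tests: 6 IBD patients + 3 controls."""
    return SimConfig(
        seed=7,
        n_patients_ibd=6,
        n_controls=3,
        n_genes=300,
        n_persistent_up=20,
        n_transient_up=20,
        cells_per_biopsy_range=(80, 160),
        n_zotus=120,
    )


@pytest.fixture(scope="session")
def small_fixture(small_config):
    return generate_fixture(small_config)
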