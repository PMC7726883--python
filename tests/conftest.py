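import pytest
from hypothesis import settings

from mitobench.annotation_orf import invertebrate_mito_code
from mitobench.synthetic_data import GenomeSpec, simulate_mitogenome

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code():
    return invertebrate_mito_code()


@pytest.fixture(scope="session")
def small_genome():
    """2 kb circular genome with 2 PCGs — fast enough for per-test alignment."""
    spec = GenomeSpec(length=2000, n_pcg=2, n_trna=4, n_rrna=1,
                      control_region_len=100, seed=42)
    return simulate_mitogenome(spec)


@pytest.fixture(scope="session")
def default_genome():
    """Full-size (15,739 bp) synthetic mitogenome, shared across tests."""
    return simulate_mitogenome(GenomeSpec(seed=7))
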