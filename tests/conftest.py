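import pytest
from hypothesis import settings

from mircompass.synthetic_data import SimConfig, simulate_all

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study shared across read-only tests."""
    return simulate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def truth(bundle):
    return bundle.truth


@pytest.fixture(scope="session")
def small_cfg():
    """A light configuration for tests that re-simulate repeatedly."""
    return SimConfig(
        seed=3,
        n_genes=400,
        frac_shared_up=0.1,
        frac_shared_down=0.08,
        n_hairpins=4,
        n_novel=2,
        n_decoy_kmers=10,
        genome_len=60_000,
        n_unique_background=300,
        library_sizes={"rdr2-1": 400, "dcl1-7": 500, "Col-0": 300},
    )
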