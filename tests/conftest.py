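import pytest
from hypothesis import HealthCheck, settings

import phenocompare as pc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fx():
    """Toy universe + two databases + two gene lists."""
    return pc.make_fixtures(seed=7)


@pytest.fixture(scope="session")
def small_synth():
    """A small dense synthetic database (1,000 genes, 300 terms)."""
    return pc.generate_synthetic_db(pc.SyntheticDbSpec(
        n_genes=1000, n_terms=300, mean_terms_per_gene=12.0, seed=101,
        name="smallsynth"))
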