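import pytest

from lakecycle.synthetic_data import SimulationConfig, simulate_community


@pytest.fixture(scope="session")
def small_truth():
    """A small noiseless community shared by read-only tests."""
    cfg = SimulationConfig(
        n_genomes=12, genome_length=8_000, n_clusters=2, cluster_members=1
    )
    return simulate_community(cfg, seed=42)


@pytest.fixture(scope="session")
def default_truth():
    """The default study-condition community (noiseless)."""
    return simulate_community(SimulationConfig(), seed=7)
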