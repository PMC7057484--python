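import pytest

from hexadose import SimulationConfig, compute_fpkm, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Compact five-genotype dataset shared by read-only tests."""
    cfg = SimulationConfig(
        genes_per_chromosome=60, replicates_per_genotype=3, seed=7
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fpkm(small_dataset):
    d = small_dataset
    return compute_fpkm(d.counts, d.annotation["length"], d.design)
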