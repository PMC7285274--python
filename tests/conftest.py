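import numpy as np
import pytest
from hypothesis import settings

from transitnet import CooccurrenceNetwork, OtuTable, SyntheticSpec, generate_otu_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def net_from_adjacency(a, condition="", rho=None, p=None):
    """Wrap a plain 0/1 adjacency into a CooccurrenceNetwork."""
    a = np.asarray(a, dtype=np.int8)
    n = a.shape[0]
    mask = a.astype(bool)
    return CooccurrenceNetwork(
        taxon_ids=[f"t{i:03d}" for i in range(n)],
        adjacency=a,
        edge_rho=np.where(mask, 0.5, 0.0) if rho is None else rho,
        edge_p=np.zeros((n, n)) if p is None else p,
        condition=condition,
    )


def random_adjacency(n, p, rng):
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1)
    a = (a | a.T).astype(np.int8)
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    return OtuTable(
        counts=np.array(
            [[5, 0, 3, 9], [1, 2, 3, 4], [0, 0, 7, 1]]
        ),
        taxon_ids=["otu_a", "otu_b", "otu_c"],
        sample_ids=["s1", "s2", "s3", "s4"],
        condition=["ACT", "ACT", "SED", "SED"],
        taxonomy=["k__A; g__x", "k__A; g__y", "k__B; g__z"],
    )


@pytest.fixture(scope="session")
def paired_small():
    """A 30-taxon two-condition synthetic dataset with ground truth."""
    spec = SyntheticSpec(n_taxa=30, seed=7)
    table, truth = generate_otu_table(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def paired_default():
    """The default-shape synthetic cohort (150 taxa, 64/45 samples)."""
    spec = SyntheticSpec(seed=0)
    table, truth = generate_otu_table(spec)
    return spec, table, truth
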