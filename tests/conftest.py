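import numpy as np
import pytest

from luctrap import CohortConfig, TDnaTemplate, generate_cohort, generate_genome


@pytest.fixture(scope="session")
def template():
    return TDnaTemplate()


@pytest.fixture(scope="session")
def small_genome():
    """Two 60 kb chromosomes, 40 genes, ~50% genic."""
    return generate_genome(n_chrom=2, chrom_len=60_000, n_genes=40, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    return generate_cohort(small_genome, CohortConfig(n_lines=30, seed=202))


@pytest.fixture()
def rng():
    return np.random.default_rng(777)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
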