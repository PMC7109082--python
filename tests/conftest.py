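import numpy as np
import pytest

from paneltmb import (
    GenomeSpec,
    GenomicInterval,
    SimulationConfig,
    simulate_cohort,
)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=500, max_len=40):
    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, max_pos))
        out.append(GenomicInterval(chrom, start, start + int(rng.integers(1, max_len))))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-condition cohort shared by read-only tests."""
    config = SimulationConfig(
        seed=5,
        n_samples=40,
        genome=GenomeSpec(n_genes=300, n_chromosomes=2),
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    small_cohort.write(out)
    return out
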