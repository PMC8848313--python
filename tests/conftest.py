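import numpy as np
import pytest

from spanweld.assembly import Assembly, scaffold_from_sequence
from spanweld.config import PipelineConfig
from spanweld.simulate import (
    RepeatFamily,
    make_test_assembly,
    plan_gaps,
    simulate_genome,
    simulate_reads,
)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def small_genome():
    """60 kb genome with one planted repeat family plus its repeat track."""
    return simulate_genome(60_000, [RepeatFamily(4, 1200, 0.05)], seed=101)


@pytest.fixture(scope="session")
def small_benchmark(small_genome):
    """Test assembly with 3 introduced gaps, 15x reads, and all truths."""
    genome, repeats = small_genome
    spec = plan_gaps(genome, repeats, 3, (60, 900), seed=102)
    test, truths, _ = make_test_assembly(genome, gap_spec=spec)
    reads, origins = simulate_reads(
        genome, coverage=15, mean_len=9000, len_param=45000, seed=103
    )
    return genome, test, truths, reads, origins


@pytest.fixture()
def config():
    return PipelineConfig(read_coverage=15)
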