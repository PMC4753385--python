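import numpy as np
import pytest

import poolcnv as pc

# Study-condition fixture: a 5-chromosome toy genome totalling 1.6 Mb
# (40 windows of 40 kb), a 200k-read in-silico reference, and pools of 4.
TOY_LENGTHS = [400_000, 320_000, 320_000, 280_000, 280_000]
TOY_GENOME_SEED = 7
REFERENCE_SEED = 3
N_REFERENCE_READS = 200_000
POOL_SIZE = 4
PER_MEMBER_READS = 50_000


@pytest.fixture(scope="session")
def toy_genome():
    """(sequences, GenomeIndex, cytobands) for the standard toy genome."""
    return pc.make_toy_genome(TOY_LENGTHS, seed=TOY_GENOME_SEED)


@pytest.fixture(scope="session")
def grid(toy_genome):
    _, genome, _ = toy_genome
    return pc.WindowGrid(genome)


@pytest.fixture(scope="session")
def reference_counts(toy_genome, grid):
    """Window counts of a 200k-read in-silico reference on the toy genome."""
    sequences, genome, _ = toy_genome
    config = pc.SamplingConfig(N_REFERENCE_READS, read_length_bp=75, seed=REFERENCE_SEED)
    reads = pc.sample_reference_reads(sequences, config, genome)
    return pc.count_reads_in_windows(reads, grid)


@pytest.fixture(scope="session")
def neutral_pool_counts(toy_genome, grid):
    """Window counts of a CNV-free pool of 4 at 50k reads per member."""
    _, genome, _ = toy_genome
    config = pc.PoolSimConfig(POOL_SIZE, PER_MEMBER_READS, seed=11)
    reads = pc.simulate_pool_reads(genome, config)
    return pc.count_reads_in_windows(reads, grid)


def simulate_counts(genome, grid, cnvs, seed, pool_size=POOL_SIZE,
                    per_member_reads=PER_MEMBER_READS):
    config = pc.PoolSimConfig(pool_size, per_member_reads, seed=seed,
                              cnvs=tuple(cnvs))
    reads = pc.simulate_pool_reads(genome, config)
    return pc.count_reads_in_windows(reads, grid)
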