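"""In-silico reference read sampling.

The reference profile against which tumor pools are compared is not a
sequenced normal: it is a set of reads drawn uniformly at random from the
reference genome sequence itself.  Each read start is uniform over all valid
start positions genome-wide — a chromosome is chosen with probability
proportional to its number of valid starts, then a position uniform within
it — so expected per-window coverage is flat and per-chromosome read counts
are proportional to chromosome length.  Sampling is with replacement,
matching shotgun statistics.

No error, GC-bias or insert-size model is applied; the reference is a plain
positional sampling.  Reads can either be counted directly at their true
positions (the fast path used throughout the test-suite) or emitted as FASTQ
for an external mapper, in which case low-mappability regions will lose
reads that the direct path keeps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO, Union

import numpy as np

from .genome_io import GenomeIndex, MappedRead

PathLike = Union[str, os.PathLike]


@dataclass(frozen=True)
class SamplingConfig:
    """Parameters of the uniform read sampler.

    read_length_bp defaults to 75 bp, typical of the single-end short-read
    instruments this analysis targets; n_reads is normally set to the
    sample's filtered read count so that sample and reference library sizes
    match (library-size normalization downstream guards the general case).
    """

    n_reads: int
    read_length_bp: int = 75
    seed: int = 0
    exclude_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.read_length_bp < 1:
            raise ValueError("read_length_bp must be >= 1")


def _valid_starts(genome: GenomeIndex, read_length_bp: int) -> np.ndarray:
    starts = np.array(
        [max(0, length - read_length_bp + 1) for _, length in genome.entries],
        dtype=np.int64,
    )
    return starts


def sample_reference_reads(
    sequences: Mapping[str, str],
    config: SamplingConfig,
    genome: GenomeIndex | None = None,
) -> list[MappedRead]:
    """Draw ``config.n_reads`` uniform read starts from the genome.

    *sequences* maps chromosome name to sequence string; *genome* defaults
    to an index built from it (insertion order).  With
    ``config.exclude_ambiguous``, reads whose ``read_length_bp`` window
    contains an ``N`` are rejected and redrawn.  The same config and seed
    always produce the same reads.
    """
    if genome is None:
        genome = GenomeIndex(tuple((name, len(seq)) for name, seq in sequences.items()))
    valid = _valid_starts(genome, config.read_length_bp)
    total_valid = int(valid.sum())
    if total_valid == 0:
        raise ValueError(
            f"no chromosome offers a valid start for reads of "
            f"{config.read_length_bp} bp"
        )
    rng = np.random.default_rng(config.seed)
    names = genome.names
    # precompute N masks only if needed
    has_n = None
    if config.exclude_ambiguous:
        has_n = {
            name: np.frombuffer(sequences[name].upper().encode(), dtype=np.uint8) == ord("N")
            for name in names
        }
    probs = valid / total_valid
    reads: list[MappedRead] = []
    n_needed = config.n_reads
    serial = 0
    while len(reads) < config.n_reads:
        chrom_idx = rng.choice(len(names), size=n_needed, p=probs)
        positions = (rng.random(n_needed) * valid[chrom_idx]).astype(np.int64)
        for ci, pos in zip(chrom_idx, positions):
            name = names[ci]
            if has_n is not None:
                window = has_n[name][pos : pos + config.read_length_bp]
                if window.any():
                    continue
            reads.append(MappedRead(name, int(pos), True, f"insilico_{serial}"))
            serial += 1
            if len(reads) == config.n_reads:
                break
        n_needed = config.n_reads - len(reads)
    return reads


def write_fastq(
    reads: Iterable[MappedRead],
    sequences: Mapping[str, str],
    read_length_bp: int,
    dest: Union[PathLike, TextIO],
) -> int:
    """Emit sampled reads as FASTQ with constant quality 'I' (Phred 40)."""
    if not hasattr(dest, "write"):
        with open(os.fspath(dest), "w") as handle:
            return write_fastq(reads, sequences, read_length_bp, handle)
    n = 0
    for read in reads:
        seq = sequences[read.chrom][read.start_bp : read.start_bp + read_length_bp]
        dest.write(f"@{read.read_id or f'read_{n}'}\n{seq}\n+\n{'I' * len(seq)}\n")
        n += 1
    return n
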