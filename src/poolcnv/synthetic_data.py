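"""Synthetic genomes, cytoband tables, and pooled tumor read sets.

Everything downstream of mapping can be exercised without any external data:
``make_toy_genome`` produces random chromosome sequences with a plausible
banded karyotype (p and q arms around an acen centromere pair), and
``simulate_pool_reads`` produces reads for a pool of tumor genomes whose
per-region sampling rate is proportional to local copy number.

The dosage model is piecewise-constant: each pool member is diploid (2
copies) everywhere except inside the copy-number variants it carries, where
the rate is ``copies_per_cell``; pooled reads are the concatenation over
members.  There are no breakpoint-spanning artifacts and no noise beyond
multinomial sampling — enough structure to exercise every window statistic,
while real data additionally carries GC, mappability and library biases this
generator deliberately omits.

Default pool sizes of interest are 4 and 5, the sizes of the retinoblastoma
and medulloblastoma pools this analysis style was designed around.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TextIO, Union

import numpy as np

from .genome_io import CytoBand, GenomeIndex, MappedRead

PathLike = Union[str, os.PathLike]

_STAIN_CYCLE = ("gneg", "gpos25", "gpos50", "gpos75", "gpos100", "gneg", "gvar")


@dataclass(frozen=True)
class CnvSpec:
    """One engineered copy-number event: interval, copy state, carriers."""

    chrom: str
    start_bp: int
    end_bp: int
    copies_per_cell: int  # 2 = neutral, 1 = hemizygous loss, 0 = homozygous
    carriers: tuple[int, ...]  # indices of pool members carrying the event

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("CnvSpec interval is empty")
        if not 0 <= self.copies_per_cell <= 8:
            raise ValueError("copies_per_cell must be in [0, 8]")


@dataclass(frozen=True)
class PoolSimConfig:
    pool_size: int
    per_member_reads: int
    read_length_bp: int = 75
    seed: int = 0
    cnvs: tuple[CnvSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.per_member_reads < 1:
            raise ValueError("per_member_reads must be >= 1")


# ---------------------------------------------------------------------------
# toy genome

def make_toy_genome(
    lengths: Sequence[int],
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> tuple[dict[str, str], GenomeIndex, list[CytoBand]]:
    """Random sequences plus a valid banded karyotype for each chromosome.

    Each chromosome gets 3-8 bands: a p arm and a q arm of 1-3 bands each
    around a two-band centromere (p11/q11, both acen), stains cycling
    through the palette.  Bands tile [0, length) exactly and always pass
    cytoband validation.  Deterministic under *seed*.
    """
    if any(l < 8 for l in lengths):
        raise ValueError("chromosome lengths must be >= 8 bp to band")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"chr{i + 1}" for i in range(len(lengths))]
    sequences: dict[str, str] = {}
    bands: list[CytoBand] = []
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    stain_offset = 0
    for name, length in zip(names, lengths):
        seq = alphabet[rng.integers(0, 4, size=length)].tobytes().decode()
        sequences[name] = seq
        # centromere midpoint somewhere central; acen pair ~4% of length
        centro_mid = int(length * rng.uniform(0.3, 0.7))
        half_acen = max(1, int(length * 0.02))
        acen_start = max(1, centro_mid - half_acen)
        acen_end = min(length - 1, centro_mid + half_acen)
        n_p = int(rng.integers(1, 4))
        n_q = int(rng.integers(1, 4))
        p_cuts = np.sort(rng.choice(np.arange(1, acen_start), size=n_p - 1,
                                    replace=False)) if n_p > 1 and acen_start > n_p else []
        q_cuts = np.sort(rng.choice(np.arange(acen_end + 1, length), size=n_q - 1,
                                    replace=False)) if n_q > 1 and length - acen_end > n_q else []
        p_bounds = [0, *map(int, p_cuts), acen_start]
        q_bounds = [acen_end, *map(int, q_cuts), length]
        # band numbers count outward from the centromere: acen pair is
        # p11/q11, then p12, p13... toward the p telomere (file order is
        # telomere-first on the p arm) and q12, q13... toward the q telomere
        n_p_bands = len(p_bounds) - 1
        p_names = [f"p1{n_p_bands - i + 1}" for i in range(n_p_bands)]
        q_names = [f"q1{i + 2}" for i in range(len(q_bounds) - 1)]
        intervals = (
            list(zip(p_bounds[:-1], p_bounds[1:], p_names))
            + [(acen_start, centro_mid, "p11"), (centro_mid, acen_end, "q11")]
            + list(zip(q_bounds[:-1], q_bounds[1:], q_names))
        )
        intervals.sort(key=lambda t: t[0])
        for i, (start, end, band_name) in enumerate(intervals):
            if band_name in ("p11", "q11"):
                stain = "acen"
            else:
                stain = _STAIN_CYCLE[(stain_offset + i) % len(_STAIN_CYCLE)]
            bands.append(CytoBand(name, start, end, band_name, stain))
        stain_offset += 1
    genome = GenomeIndex(tuple((n, int(l)) for n, l in zip(names, lengths)))
    return sequences, genome, bands


def write_fasta(sequences: Mapping[str, str], dest: PathLike, width: int = 70) -> None:
    with open(os.fspath(dest), "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_cytoband_table(bands: Sequence[CytoBand], dest: Union[PathLike, TextIO]) -> None:
    if not hasattr(dest, "write"):
        with open(os.fspath(dest), "w") as handle:
            write_cytoband_table(bands, handle)
        return
    for b in bands:
        dest.write(f"{b.chrom}\t{b.start_bp}\t{b.end_bp}\t{b.band_name}\t{b.stain}\n")


# ---------------------------------------------------------------------------
# pooled read simulation

def _member_intervals(
    genome: GenomeIndex, member: int, cnvs: Sequence[CnvSpec]
) -> tuple[list[tuple[str, int, int, int]], np.ndarray]:
    """Piecewise-constant copy-number intervals for one pool member.

    Returns (intervals, weights): intervals are (chrom, start, end, copies),
    weights proportional to copies * span.
    """
    carried: dict[str, list[CnvSpec]] = {}
    for cnv in cnvs:
        if member in cnv.carriers:
            carried.setdefault(cnv.chrom, []).append(cnv)
    intervals: list[tuple[str, int, int, int]] = []
    for chrom, length in genome.entries:
        events = sorted(carried.get(chrom, ()), key=lambda c: c.start_bp)
        for a, b in zip(events, events[1:]):
            if b.start_bp < a.end_bp:
                raise ValueError(
                    f"overlapping CNVs for member {member} on {chrom}: "
                    f"[{a.start_bp},{a.end_bp}) and [{b.start_bp},{b.end_bp})"
                )
        cursor = 0
        for event in events:
            if event.start_bp > cursor:
                intervals.append((chrom, cursor, event.start_bp, 2))
            intervals.append((chrom, event.start_bp, event.end_bp, event.copies_per_cell))
            cursor = event.end_bp
        if cursor < length:
            intervals.append((chrom, cursor, length, 2))
    weights = np.array([(e - s) * c for _, s, e, c in intervals], dtype=float)
    return intervals, weights


def simulate_pool_reads(
    genome: GenomeIndex,
    config: PoolSimConfig,
) -> list[MappedRead]:
    """Sample reads for every pool member and concatenate them.

    Each member contributes exactly ``per_member_reads`` reads; within a
    member, a read falls into a genomic interval with probability
    proportional to interval span times local copy number, and uniformly
    within the interval.  Deterministic under the config seed.
    """
    for cnv in config.cnvs:
        if cnv.chrom not in genome:
            raise ValueError(f"CNV on unknown chromosome {cnv.chrom!r}")
        if cnv.end_bp > genome.length_of(cnv.chrom):
            raise ValueError(f"CNV beyond end of {cnv.chrom}")
        if any(m >= config.pool_size or m < 0 for m in cnv.carriers):
            raise ValueError("CNV carrier index outside pool")
    rng = np.random.default_rng(config.seed)
    reads: list[MappedRead] = []
    serial = 0
    for member in range(config.pool_size):
        intervals, weights = _member_intervals(genome, member, config.cnvs)
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"member {member} has zero sampling mass")
        probs = weights / total
        choice = rng.choice(len(intervals), size=config.per_member_reads, p=probs)
        offsets = rng.random(config.per_member_reads)
        for ci, u in zip(choice, offsets):
            chrom, start, end, _ = intervals[ci]
            pos = start + int(u * (end - start))
            reads.append(MappedRead(chrom, pos, True, f"pool_m{member}_{serial}"))
            serial += 1
    return reads
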