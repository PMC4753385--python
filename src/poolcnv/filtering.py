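"""Read-level filters: quality, complexity, and unique-mapper extraction.

Three filters are applied in a fixed order — mean quality, then sequence
complexity, then mapping uniqueness — and every read is counted exactly once
at its first failure, so filter reports are comparable across runs and the
counts always partition the input.

The thresholds here are toolkit choices (the upstream analysis protocol
names the filters but not their parameters): mean Phred >= 20, Shannon
entropy >= 1.0 bits, tag-based uniqueness with MAPQ >= 30 as the fallback
proxy.  All are configurable.
"""

from __future__ import annotations

import json
import math
import os
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator, Sequence, Union

import pysam

from .genome_io import GenomeFormatError, GenomeIndex, MappedRead

PathLike = Union[str, os.PathLike]


@dataclass(frozen=True)
class FilterConfig:
    min_mean_quality: float = 20.0
    complexity_method: str = "entropy"  # "entropy" | "dust"
    min_entropy_bits: float = 1.0
    max_dust_score: float = 7.0
    uniqueness_rule: str = "tag_based"  # "tag_based" | "mapq_threshold"
    min_mapq: int = 30

    def __post_init__(self) -> None:
        if self.complexity_method not in ("entropy", "dust"):
            raise ValueError(f"unknown complexity_method {self.complexity_method!r}")
        if self.uniqueness_rule not in ("tag_based", "mapq_threshold"):
            raise ValueError(f"unknown uniqueness_rule {self.uniqueness_rule!r}")
        if not 0.0 <= self.min_entropy_bits <= 2.0:
            raise ValueError("min_entropy_bits must be in [0, 2]")


@dataclass
class FilterReport:
    """Partition of the input reads by their first failing filter."""

    n_input: int = 0
    n_fail_quality: int = 0
    n_fail_complexity: int = 0
    n_fail_uniqueness: int = 0
    n_pass: int = 0

    def check(self) -> None:
        total = (self.n_fail_quality + self.n_fail_complexity
                 + self.n_fail_uniqueness + self.n_pass)
        if total != self.n_input:
            raise AssertionError(
                f"filter report does not partition input: {total} != {self.n_input}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def __str__(self) -> str:
        rows = [
            ("input", self.n_input),
            ("fail quality", self.n_fail_quality),
            ("fail complexity", self.n_fail_complexity),
            ("fail uniqueness", self.n_fail_uniqueness),
            ("pass", self.n_pass),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v:>10}" for k, v in rows)


# ---------------------------------------------------------------------------
# per-read predicates

def mean_quality_filter(qualities: Sequence[int], min_mean_quality: float) -> bool:
    """Pass iff the arithmetic mean Phred score is >= the threshold (inclusive)."""
    if qualities is None or len(qualities) == 0:
        raise GenomeFormatError(
            "quality filter enabled but read carries no base qualities"
        )
    return sum(qualities) / len(qualities) >= min_mean_quality


def shannon_entropy(sequence: str) -> float:
    """Shannon entropy (bits) of mononucleotide frequencies.

    N counts as a fifth symbol.  A homopolymer scores 0; an equal mix of the
    four bases scores 2 bits, the maximum for DNA.
    """
    if not sequence:
        return 0.0
    counts = Counter(sequence.upper())
    n = len(sequence)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def dust_score(sequence: str) -> float:
    """DUST-style triplet over-representation score.

    Counts every overlapping 3-mer (triplets containing N are skipped) and
    returns ``10 * sum(c*(c-1)/2) / (T-1)`` where c are the per-triplet
    occurrence counts and T the number of counted triplets.  A random-ish
    read scores near 0; a dinucleotide repeat like ACACAC... scores near the
    ~33 ceiling.  Unlike entropy the score is order-sensitive.
    """
    seq = sequence.upper()
    counts: Counter[str] = Counter()
    for i in range(len(seq) - 2):
        triplet = seq[i : i + 3]
        if "N" in triplet:
            continue
        counts[triplet] += 1
    total = sum(counts.values())
    if total <= 1:
        return 0.0
    raw = sum(c * (c - 1) // 2 for c in counts.values())
    return 10.0 * raw / (total - 1)


def complexity_filter(sequence: str, config: FilterConfig) -> bool:
    """Pass iff the read is complex enough under the configured method."""
    if config.complexity_method == "entropy":
        return shannon_entropy(sequence) >= config.min_entropy_bits
    return dust_score(sequence) <= config.max_dust_score


# ---------------------------------------------------------------------------
# uniqueness

def _alignment_multiplicity(record: "pysam.AlignedSegment") -> int | None:
    """Reported alignment count for a record, or None if undecidable.

    Prefers the NH tag (explicit hit count).  Without NH, a Bowtie2-style
    XS:i tag (score of the best alternative alignment) marks a multi-mapper;
    a record lacking both NH and XS is taken to map once, but only when the
    aligner emitted XS for at least one record in the file — that is decided
    by the caller, which tracks whether any multiplicity evidence exists.
    """
    if record.has_tag("NH"):
        return int(record.get_tag("NH"))
    if record.has_tag("XS"):
        return 2
    return None


def unique_mapper_filter(
    records: Iterable["pysam.AlignedSegment"],
    config: FilterConfig,
) -> Iterator["pysam.AlignedSegment"]:
    """Yield primary alignments of reads that map only once.

    tag_based: keep records whose alignment-count tag is 1, or which lack a
    secondary/alternative-hit indication while other records in the stream
    carry one.  If no record in the whole stream carries multiplicity
    information the rule is undecidable and a hard error advises the
    mapq_threshold proxy.  mapq_threshold: keep MAPQ >= min_mapq.
    """
    if config.uniqueness_rule == "mapq_threshold":
        for record in records:
            if record.is_unmapped or record.is_secondary or record.is_supplementary:
                continue
            if record.mapping_quality >= config.min_mapq:
                yield record
        return

    all_mapped = [r for r in records if not r.is_unmapped]
    primaries = [r for r in all_mapped
                 if not (r.is_secondary or r.is_supplementary)]
    name_hits = Counter(r.query_name for r in all_mapped if not r.is_supplementary)
    any_secondary = any(r.is_secondary for r in all_mapped)
    any_tag = any(r.has_tag("NH") or r.has_tag("XS") for r in primaries)
    if primaries and not (any_tag or any_secondary):
        raise GenomeFormatError(
            "tag_based uniqueness requested but no record carries NH/XS "
            "multiplicity tags or secondary alignments; use "
            "uniqueness_rule='mapq_threshold' instead"
        )
    for record in primaries:
        mult = _alignment_multiplicity(record)
        if mult is None:
            mult = name_hits[record.query_name]
        if mult == 1:
            yield record


# ---------------------------------------------------------------------------
# whole-file driver

def filter_fastq_records(
    records: Iterable[tuple[str, str, Sequence[int]]],
    config: FilterConfig,
) -> tuple[list[tuple[str, str, Sequence[int]]], FilterReport]:
    """Apply quality then complexity filters to (id, seq, quals) records."""
    report = FilterReport()
    passed: list[tuple[str, str, Sequence[int]]] = []
    for rec_id, seq, quals in records:
        report.n_input += 1
        if not mean_quality_filter(quals, config.min_mean_quality):
            report.n_fail_quality += 1
            continue
        if not complexity_filter(seq, config):
            report.n_fail_complexity += 1
            continue
        report.n_pass += 1
        passed.append((rec_id, seq, quals))
    report.check()
    return passed, report


def filter_alignments(
    source: PathLike,
    genome: GenomeIndex,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[MappedRead], FilterReport]:
    """Full read-level filter chain over a SAM/BAM file.

    Quality and complexity are evaluated from the alignment record's stored
    sequence/qualities where present; uniqueness per the configured rule.
    Order: quality -> complexity -> uniqueness, first failure counted.
    """
    path = os.fspath(source)
    mode = "rb" if path.lower().endswith(".bam") else "r"
    report = FilterReport()
    stage_pass: list[pysam.AlignedSegment] = []
    with pysam.AlignmentFile(path, mode, check_sq=False) as handle:
        all_records = [r for r in handle if not r.is_unmapped]
    secondaries = [r for r in all_records if r.is_secondary or r.is_supplementary]
    for record in all_records:
        if record.is_secondary or record.is_supplementary:
            continue
        report.n_input += 1
        quals = record.query_qualities
        if quals is not None and not mean_quality_filter(quals, config.min_mean_quality):
            report.n_fail_quality += 1
            continue
        seq = record.query_sequence
        if seq is not None and not complexity_filter(seq, config):
            report.n_fail_complexity += 1
            continue
        stage_pass.append(record)
    # secondaries ride along as multiplicity evidence; only primaries emerge
    unique = list(unique_mapper_filter(stage_pass + secondaries, config))
    report.n_fail_uniqueness = len(stage_pass) - len(unique)
    report.n_pass = len(unique)
    report.check()
    reads = [
        MappedRead(r.reference_name, r.reference_start, True, r.query_name or "")
        for r in unique
        if r.reference_name in genome
    ]
    return reads, report
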