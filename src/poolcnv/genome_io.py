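"""Genomic input/output and the shared coordinate convention.

All coordinates are 0-based, half-open internally.  BED is consumed natively;
SAM/BAM positions are converted on read (pysam already reports 0-based
``reference_start``).  Coordinates destined for human eyes (reports, ideogram
labels) are printed 1-based inclusive to match cytogenetic convention.

Chromosome naming is strict: "chr1" and "1" are different sequences and are
never harmonized silently, because a mismatch would corrupt cytoband lookups.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence, TextIO, Union

import pysam
from Bio import SeqIO

logger = logging.getLogger("poolcnv")

#: gieStain classes of the UCSC cytoBand table.
VALID_STAINS = frozenset(
    {"gneg", "gpos25", "gpos50", "gpos75", "gpos100", "acen", "gvar", "stalk"}
)

PathLike = Union[str, os.PathLike]


class GenomeFormatError(ValueError):
    """Raised when a genomic input file violates its format contract."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths defining the coordinate space.

    The order of ``entries`` is the file order of the source and is preserved
    for all downstream per-chromosome iteration (window grids, integrity
    scores, panorama panels).
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise GenomeFormatError(f"duplicate sequence name: {dup!r}")
        for name, length in self.entries:
            if length < 1:
                raise GenomeFormatError(f"non-positive length for {name!r}: {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.entries)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(
                f"chromosome {chrom!r} not in genome index; if your data uses a "
                "different naming scheme (e.g. '1' vs 'chr1'), rename the "
                "sequences with a mapping file before loading"
            ) from None

    def total_bp(self) -> int:
        return sum(length for _, length in self.entries)


@dataclass(frozen=True)
class CytoBand:
    """One Giemsa band: a named, stained interval of a chromosome."""

    chrom: str
    start_bp: int
    end_bp: int
    band_name: str
    stain: str

    def __post_init__(self) -> None:
        if not 0 <= self.start_bp < self.end_bp:
            raise GenomeFormatError(
                f"invalid band interval {self.chrom}:{self.start_bp}-{self.end_bp}"
            )
        if self.stain not in VALID_STAINS:
            raise GenomeFormatError(
                f"unknown stain {self.stain!r} for band {self.chrom} {self.band_name}"
            )


@dataclass(frozen=True)
class MappedRead:
    """A mapped read reduced to what window counting needs: a start position."""

    chrom: str
    start_bp: int
    is_unique: bool = True
    read_id: str = ""


# ---------------------------------------------------------------------------
# genome index

def load_genome_index(source: PathLike) -> GenomeIndex:
    """Read chromosome names and lengths from FASTA or a 2-column TSV.

    The source format is decided by content: a first non-blank character of
    ``>`` means FASTA, anything else a tab-separated chrom/length table.
    File order becomes index order.
    """
    path = os.fspath(source)
    with open(path) as handle:
        first = handle.read(1)
    if first == "":
        raise GenomeFormatError(f"empty genome source: {path}")
    if first == ">":
        entries = []
        for record in SeqIO.parse(path, "fasta"):
            entries.append((record.id, len(record.seq)))
    else:
        entries = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise GenomeFormatError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                try:
                    entries.append((fields[0], int(fields[1])))
                except ValueError:
                    raise GenomeFormatError(
                        f"{path}:{lineno}: length {fields[1]!r} is not an integer"
                    ) from None
    if not entries:
        raise GenomeFormatError(f"no sequences found in {path}")
    return GenomeIndex(tuple(entries))


def write_genome_index(genome: GenomeIndex, dest: Union[PathLike, TextIO]) -> None:
    """Write the index as the 2-column TSV ``load_genome_index`` re-reads."""
    if hasattr(dest, "write"):
        for name, length in genome.entries:
            dest.write(f"{name}\t{length}\n")
    else:
        with open(os.fspath(dest), "w") as handle:
            write_genome_index(genome, handle)


# ---------------------------------------------------------------------------
# cytobands

def load_cytobands(source: PathLike, genome: GenomeIndex) -> list[CytoBand]:
    """Parse a UCSC cytoBand.txt-style 5-column TSV.

    Bands on chromosomes absent from *genome* are dropped with a logged
    warning.  Per chromosome, bands are returned sorted by start and must be
    non-overlapping; overlap or an empty interval is a hard error.
    """
    path = os.fspath(source)
    bands: list[CytoBand] = []
    n_dropped = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise GenomeFormatError(
                    f"{path}:{lineno}: expected 5 tab-separated columns"
                )
            chrom, start_s, end_s, name, stain = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GenomeFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if end <= start:
                raise GenomeFormatError(
                    f"{path}:{lineno}: band end {end} <= start {start}"
                )
            if chrom not in genome:
                n_dropped += 1
                continue
            if end > genome.length_of(chrom):
                raise GenomeFormatError(
                    f"{path}:{lineno}: band end {end} beyond {chrom} length "
                    f"{genome.length_of(chrom)}"
                )
            bands.append(CytoBand(chrom, start, end, name, stain))
    if n_dropped:
        logger.warning("dropped %d cytobands on chromosomes absent from the index", n_dropped)
    bands.sort(key=lambda b: (genome.names.index(b.chrom), b.start_bp))
    previous: dict[str, CytoBand] = {}
    for band in bands:
        prev = previous.get(band.chrom)
        if prev is not None and band.start_bp < prev.end_bp:
            raise GenomeFormatError(
                f"overlapping bands on {band.chrom}: {prev.band_name} "
                f"[{prev.start_bp},{prev.end_bp}) and {band.band_name} "
                f"[{band.start_bp},{band.end_bp})"
            )
        previous[band.chrom] = band
    return bands


def bands_for_chrom(bands: Iterable[CytoBand], chrom: str) -> list[CytoBand]:
    return sorted((b for b in bands if b.chrom == chrom), key=lambda b: b.start_bp)


# ---------------------------------------------------------------------------
# mapped reads

class ReadStream:
    """Iterator over :class:`MappedRead` with skip counters.

    Iterating consumes the underlying source once.  ``n_skipped_unknown``
    (reads on chromosomes absent from the index) and ``n_skipped_unmapped``
    are updated during iteration and final once the stream is exhausted.
    """

    def __init__(self, iterator: Iterator[MappedRead]):
        self._iterator = iterator
        self.n_skipped_unknown = 0
        self.n_skipped_unmapped = 0

    def __iter__(self) -> Iterator[MappedRead]:
        return self._iterator


def load_mapped_reads(source: PathLike, genome: GenomeIndex) -> ReadStream:
    """Stream mapped reads from SAM/BAM or BED3 in the internal convention.

    SAM/BAM records are taken mapped/unmapped from the FLAG field; BED
    records are all treated as mapped and unique (a BED of mapped positions
    carries no multiplicity information).  Reads on chromosomes not in the
    index are skipped and counted on the returned stream.
    """
    path = os.fspath(source)
    lower = path.lower()
    if lower.endswith((".sam", ".bam", ".cram")):
        if lower.endswith(".cram"):
            raise GenomeFormatError("CRAM input is not supported")
        stream = ReadStream(iter(()))
        stream._iterator = _iter_sam(path, genome, stream)
        return stream
    stream = ReadStream(iter(()))
    stream._iterator = _iter_bed(path, genome, stream)
    return stream


def _iter_sam(path: str, genome: GenomeIndex, stream: ReadStream) -> Iterator[MappedRead]:
    mode = "rb" if path.lower().endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as handle:
        for record in handle:
            if record.is_unmapped:
                stream.n_skipped_unmapped += 1
                continue
            if record.is_secondary or record.is_supplementary:
                continue
            chrom = record.reference_name
            if chrom not in genome:
                stream.n_skipped_unknown += 1
                continue
            start = record.reference_start  # pysam: already 0-based
            if not 0 <= start < genome.length_of(chrom):
                raise GenomeFormatError(
                    f"{path}: read {record.query_name} start {start} outside "
                    f"{chrom} [0,{genome.length_of(chrom)})"
                )
            yield MappedRead(chrom, start, True, record.query_name or "")


def _iter_bed(path: str, genome: GenomeIndex, stream: ReadStream) -> Iterator[MappedRead]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeFormatError(
                    f"{path}:{lineno}: BED record needs at least 3 columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise GenomeFormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            if end <= start or start < 0:
                raise GenomeFormatError(
                    f"{path}:{lineno}: invalid BED interval {start}-{end}"
                )
            if chrom not in genome:
                stream.n_skipped_unknown += 1
                continue
            if start >= genome.length_of(chrom):
                raise GenomeFormatError(
                    f"{path}:{lineno}: start {start} beyond {chrom} length"
                )
            name = fields[3] if len(fields) > 3 else ""
            yield MappedRead(chrom, start, True, name)


def write_reads_bed(reads: Iterable[MappedRead], dest: Union[PathLike, TextIO],
                    read_length_bp: int = 1) -> int:
    """Write reads as BED3(+name); returns the number written."""
    if not hasattr(dest, "write"):
        with open(os.fspath(dest), "w") as handle:
            return write_reads_bed(reads, handle, read_length_bp)
    n = 0
    for read in reads:
        end = read.start_bp + read_length_bp
        if read.read_id:
            dest.write(f"{read.chrom}\t{read.start_bp}\t{end}\t{read.read_id}\n")
        else:
            dest.write(f"{read.chrom}\t{read.start_bp}\t{end}\n")
        n += 1
    return n
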