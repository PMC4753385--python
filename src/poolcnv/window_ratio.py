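"""Fixed-width window counting and the per-window log2 sample/reference ratio.

Each chromosome is tiled by non-overlapping windows of ``window_bp`` bases
(40 kb by default); the last window of a chromosome may be short and is
flagged, but its count is not length-rescaled — the reference window is
equally short, so the ratio remains fair.  A read belongs to exactly one
window: the one containing its start position (0-based, half-open).

The per-window statistic is

    log2_ratio = log2(reads_in_sample_window / reads_in_reference_window)

which is symmetric in sign for reciprocal dosage relations: +2 and -2
correspond to 4:1 and 1:4, both a fold change of 4.  With the default
pseudocount of 0, windows where either count is zero are marked undefined
(NaN) rather than +/-infinity, so extreme losses are never silently shrunk;
a positive pseudocount is opt-in.  Library-size normalization (scaling the
reference counts by the ratio of totals) is on by default.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO, Union

import numpy as np

from .genome_io import GenomeIndex, MappedRead

PathLike = Union[str, os.PathLike]

DEFAULT_WINDOW_BP = 40_000


@dataclass(frozen=True)
class WindowGrid:
    """Tiling of every chromosome into fixed-length windows.

    Window ``i`` of a chromosome spans ``[i*window_bp, min((i+1)*window_bp,
    length))``; the number of windows is ``ceil(length / window_bp)``.
    """

    genome: GenomeIndex
    window_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")

    def n_windows(self, chrom: str) -> int:
        return -(-self.genome.length_of(chrom) // self.window_bp)

    def window_bounds(self, chrom: str, index: int) -> tuple[int, int]:
        length = self.genome.length_of(chrom)
        start = index * self.window_bp
        if not 0 <= start < length:
            raise IndexError(f"window {index} out of range for {chrom}")
        return start, min(start + self.window_bp, length)

    def is_short_window(self, chrom: str, index: int) -> bool:
        start, end = self.window_bounds(chrom, index)
        return end - start < self.window_bp

    def total_windows(self) -> int:
        return sum(self.n_windows(c) for c in self.genome.names)


@dataclass
class WindowCounts:
    """Per-window mapped-read counts for one dataset on one grid."""

    grid: WindowGrid
    counts: dict[str, np.ndarray]
    total_reads: int

    def check(self) -> None:
        for chrom, arr in self.counts.items():
            if len(arr) != self.grid.n_windows(chrom):
                raise AssertionError(f"count array misaligned with grid on {chrom}")
            if (arr < 0).any():
                raise AssertionError(f"negative count on {chrom}")
        if sum(int(a.sum()) for a in self.counts.values()) != self.total_reads:
            raise AssertionError("window counts do not sum to total_reads")

    def per_chromosome_totals(self) -> dict[str, int]:
        return {c: int(a.sum()) for c, a in self.counts.items()}


@dataclass
class RatioTrack:
    """Per-window log2(sample/reference); NaN marks an undefined window."""

    grid: WindowGrid
    log2_ratio: dict[str, np.ndarray]
    pseudocount: float = 0.0
    normalized: bool = True


def count_reads_in_windows(reads: Iterable[MappedRead], grid: WindowGrid) -> WindowCounts:
    """Assign each read to the window containing its start and count.

    A read beyond its chromosome end is an upstream invariant breach and a
    hard error, not a silent drop.
    """
    genome = grid.genome
    counts = {c: np.zeros(grid.n_windows(c), dtype=np.int64) for c in genome.names}
    total = 0
    for read in reads:
        length = genome.length_of(read.chrom)
        if not 0 <= read.start_bp < length:
            raise ValueError(
                f"read {read.read_id!r} at {read.chrom}:{read.start_bp} outside "
                f"[0,{length})"
            )
        counts[read.chrom][read.start_bp // grid.window_bp] += 1
        total += 1
    wc = WindowCounts(grid, counts, total)
    wc.check()
    return wc


def log2_ratio_track(
    sample: WindowCounts,
    reference: WindowCounts,
    pseudocount: float = 0.0,
    normalize: bool = True,
) -> RatioTrack:
    """Per-window log2 ratio of sample over reference counts.

    With *normalize*, reference counts are scaled by
    ``sample.total_reads / reference.total_reads`` first so the genome-wide
    expectation is 0 even when library sizes differ.  With pseudocount p,
    each window's value is ``log2((s + p) / (r_scaled + p))``; with p == 0,
    windows where either count is 0 are NaN.
    """
    if sample.grid != reference.grid:
        raise ValueError("sample and reference grids differ")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    scale = 1.0
    if normalize:
        if reference.total_reads == 0:
            raise ValueError("cannot normalize against an empty reference")
        scale = sample.total_reads / reference.total_reads
    ratios: dict[str, np.ndarray] = {}
    for chrom in sample.grid.genome.names:
        s = sample.counts[chrom].astype(float)
        r = reference.counts[chrom].astype(float) * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            value = np.log2((s + pseudocount) / (r + pseudocount))
        value[~np.isfinite(value)] = np.nan
        ratios[chrom] = value
    return RatioTrack(sample.grid, ratios, pseudocount, normalize)


def fold_change(log2_value: float) -> float:
    """Fold change implied by a log2 ratio: 2**|x|; NaN stays NaN."""
    if math.isnan(log2_value):
        return math.nan
    return 2.0 ** abs(log2_value)


# ---------------------------------------------------------------------------
# serialization

def write_bedgraph(track_or_counts, dest: Union[PathLike, TextIO]) -> None:
    """Write per-window values as bedGraph (chrom, start, end, value).

    Accepts a RatioTrack (NaN windows written as 'nan') or WindowCounts.
    """
    if not hasattr(dest, "write"):
        with open(os.fspath(dest), "w") as handle:
            write_bedgraph(track_or_counts, handle)
        return
    grid = track_or_counts.grid
    values = (track_or_counts.log2_ratio if isinstance(track_or_counts, RatioTrack)
              else track_or_counts.counts)
    for chrom in grid.genome.names:
        arr = values[chrom]
        for i, v in enumerate(arr):
            start, end = grid.window_bounds(chrom, i)
            if isinstance(track_or_counts, RatioTrack):
                text = "nan" if np.isnan(v) else f"{v:.6g}"
            else:
                text = str(int(v))
            dest.write(f"{chrom}\t{start}\t{end}\t{text}\n")


def write_ratio_tsv(track: RatioTrack, dest: Union[PathLike, TextIO]) -> None:
    """TSV with window index and flags; band annotation is added downstream."""
    if not hasattr(dest, "write"):
        with open(os.fspath(dest), "w") as handle:
            write_ratio_tsv(track, handle)
        return
    dest.write("chrom\twindow_index\tstart\tend\tshort_window\tlog2_ratio\n")
    for chrom in track.grid.genome.names:
        for i, v in enumerate(track.log2_ratio[chrom]):
            start, end = track.grid.window_bounds(chrom, i)
            short = int(track.grid.is_short_window(chrom, i))
            text = "nan" if np.isnan(v) else f"{v:.6g}"
            dest.write(f"{chrom}\t{i}\t{start}\t{end}\t{short}\t{text}\n")
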