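"""Threshold-based loss/gain segment calling, cross-pool intersection, and
cytoband annotation.

This is deliberately not a statistical segmentation model (no HMM, no
circular binary segmentation): the procedure is maximal runs of windows
beyond a log2-ratio threshold, read against a cytogenetic band map.  The
default thresholds (-0.5 / +0.5, at least 3 consecutive windows, at most 1
bridged gap window) are toolkit choices and are exposed on the CLI.

"Shared" losses across pools are the genomic intersection of same-direction
segments present in every pool; a k-of-n mode exists but defaults to all.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO, Union

import numpy as np

from .genome_io import CytoBand, bands_for_chrom
from .window_ratio import RatioTrack

PathLike = Union[str, os.PathLike]


@dataclass(frozen=True)
class CnvSegment:
    """A contiguous lost or gained region, in 0-based half-open coordinates."""

    chrom: str
    start_bp: int
    end_bp: int
    direction: str  # "loss" | "gain"
    n_windows: int
    mean_log2: float
    bands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"empty segment {self.chrom}:{self.start_bp}-{self.end_bp}"
            )
        if self.direction not in ("loss", "gain"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "loss" and self.mean_log2 > 0:
            raise ValueError("loss segment with positive mean_log2")
        if self.direction == "gain" and self.mean_log2 < 0:
            raise ValueError("gain segment with negative mean_log2")


@dataclass(frozen=True)
class CallConfig:
    loss_threshold: float = -0.5
    gain_threshold: float = 0.5
    min_consecutive_windows: int = 1
    max_gap_windows: int = 0

    def __post_init__(self) -> None:
        if self.loss_threshold >= 0:
            raise ValueError("loss_threshold must be < 0")
        if self.gain_threshold <= 0:
            raise ValueError("gain_threshold must be > 0")
        if self.min_consecutive_windows < 1:
            raise ValueError("min_consecutive_windows must be >= 1")
        if self.max_gap_windows < 0:
            raise ValueError("max_gap_windows must be >= 0")


DEFAULT_CALL_CONFIG = CallConfig(
    loss_threshold=-0.5, gain_threshold=0.5,
    min_consecutive_windows=3, max_gap_windows=1,
)


def call_segments(track: RatioTrack, config: CallConfig = DEFAULT_CALL_CONFIG) -> list[CnvSegment]:
    """Call maximal runs of windows beyond threshold as segments.

    A run is a set of passing windows separated by at most
    ``max_gap_windows`` non-passing windows (undefined windows neither
    extend nor break a run, up to the same gap budget); a run survives if it
    contains at least ``min_consecutive_windows`` windows from first to last
    passing window.  ``mean_log2`` is the mean over defined windows in the
    run's span.
    """
    segments: list[CnvSegment] = []
    for chrom in track.grid.genome.names:
        values = track.log2_ratio[chrom]
        for direction, passes in (
            ("loss", values <= config.loss_threshold),
            ("gain", values >= config.gain_threshold),
        ):
            passes = np.where(np.isnan(values), False, passes)
            idx = np.flatnonzero(passes)
            if idx.size == 0:
                continue
            # group passing windows whose gaps are within budget
            runs: list[list[int]] = [[int(idx[0])]]
            for i in idx[1:]:
                if i - runs[-1][-1] - 1 <= config.max_gap_windows:
                    runs[-1].append(int(i))
                else:
                    runs.append([int(i)])
            for run in runs:
                first, last = run[0], run[-1]
                span = last - first + 1
                if span < config.min_consecutive_windows:
                    continue
                window_values = values[first : last + 1]
                mean = float(np.nanmean(window_values))
                # a bridged gap window of opposite sign can, in principle,
                # flip the run mean; fall back to the passing windows alone
                if (direction == "loss") != (mean <= 0):
                    mean = float(np.nanmean(values[run]))
                start, _ = track.grid.window_bounds(chrom, first)
                _, end = track.grid.window_bounds(chrom, last)
                segments.append(
                    CnvSegment(chrom, start, end, direction, span, mean)
                )
    segments.sort(key=lambda s: (track.grid.genome.names.index(s.chrom), s.start_bp))
    return segments


def intersect_segments(
    per_pool_segments: Sequence[Sequence[CnvSegment]],
    direction: str,
    min_pools: int | None = None,
) -> list[CnvSegment]:
    """Genomic intersection of same-direction segments across pools.

    Returns the regions covered by a *direction* segment in at least
    ``min_pools`` of the input lists (default: all of them, the strict
    "shared" definition).  Output boundaries are the intersected
    coordinates; ``mean_log2`` of an output segment is the mean of the
    overlapping source segments' means, and ``n_windows`` is re-derived
    from the source segments covering the region.
    """
    if len(per_pool_segments) < 2:
        raise ValueError("intersection needs >= 2 segment lists")
    k = len(per_pool_segments) if min_pools is None else min_pools
    if not 1 <= k <= len(per_pool_segments):
        raise ValueError("min_pools out of range")

    by_chrom: dict[str, list[tuple[int, int, int, CnvSegment]]] = {}
    for pool_idx, segs in enumerate(per_pool_segments):
        for seg in segs:
            if seg.direction != direction:
                continue
            by_chrom.setdefault(seg.chrom, []).append(
                (seg.start_bp, seg.end_bp, pool_idx, seg)
            )

    result: list[CnvSegment] = []
    for chrom, items in sorted(by_chrom.items()):
        # sweep over breakpoints; a region is in the intersection when the
        # number of distinct pools covering it is >= k
        bounds = sorted({b for s, e, _, _ in items for b in (s, e)})
        pending: list[tuple[int, int]] = []
        merged: list[tuple[int, int]] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            covering = {p for s, e, p, _ in items if s < hi and e > lo}
            if len(covering) >= k:
                pending.append((lo, hi))
        # merge adjacent covered pieces
        for lo, hi in pending:
            if merged and merged[-1][1] == lo:
                merged[-1] = (merged[-1][0], hi)
            else:
                merged.append((lo, hi))
        for lo, hi in merged:
            sources = [seg for s, e, _, seg in items if s < hi and e > lo]
            # sort so the float accumulation is invariant to pool order
            mean = float(np.mean(sorted(seg.mean_log2 for seg in sources)))
            n_windows = max(seg.n_windows for seg in sources)
            result.append(CnvSegment(chrom, lo, hi, direction, n_windows, mean))
    result.sort(key=lambda s: (s.chrom, s.start_bp))
    return result


def annotate_bands(segment: CnvSegment, bands: Iterable[CytoBand]) -> CnvSegment:
    """Fill in the names of all cytobands overlapping the segment (>= 1 bp).

    Band names come back in genomic order.  If the chromosome has no bands
    at all the list stays empty (a warning is logged).
    """
    chrom_bands = bands_for_chrom(bands, segment.chrom)
    if not chrom_bands:
        import logging
        logging.getLogger("poolcnv").warning(
            "no cytobands available for %s; segment left unannotated", segment.chrom
        )
        return replace(segment, bands=())
    names = tuple(
        b.band_name
        for b in chrom_bands
        if b.start_bp < segment.end_bp and b.end_bp > segment.start_bp
    )
    return replace(segment, bands=names)


def segment_span_mb(segment: CnvSegment) -> float:
    """Segment span in megabases: (end - start) / 1e6."""
    return (segment.end_bp - segment.start_bp) / 1e6


def count_genes(segment: CnvSegment, genes: Sequence[tuple[str, int, int]]) -> int:
    """Number of gene intervals (chrom, start, end, 0-based half-open)
    overlapping the segment by >= 1 bp."""
    return sum(
        1 for chrom, start, end in genes
        if chrom == segment.chrom and start < segment.end_bp and end > segment.start_bp
    )


def load_gene_intervals(source: PathLike) -> list[tuple[str, int, int]]:
    """Load gene intervals from BED (>=3 cols) or GFF3 (type == 'gene').

    GFF3's 1-based inclusive coordinates are converted to the internal
    0-based half-open convention.
    """
    path = os.fspath(source)
    genes: list[tuple[str, int, int]] = []
    with open(path) as handle:
        lines = handle.readlines()
    is_gff = path.lower().endswith((".gff", ".gff3")) or any(
        line.startswith("##gff-version") for line in lines[:5]
    )
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if is_gff:
            if len(fields) < 9 or fields[2] != "gene":
                continue
            genes.append((fields[0], int(fields[3]) - 1, int(fields[4])))
        else:
            if len(fields) < 3:
                continue
            genes.append((fields[0], int(fields[1]), int(fields[2])))
    return genes


# ---------------------------------------------------------------------------
# serialization

def write_segments_bed(segments: Iterable[CnvSegment],
                       dest: Union[PathLike, TextIO]) -> None:
    """BED6: name = comma-joined band list, score = 1000*|mean_log2| clipped."""
    if not hasattr(dest, "write"):
        with open(os.fspath(dest), "w") as handle:
            write_segments_bed(segments, handle)
        return
    for seg in segments:
        name = ",".join(seg.bands) if seg.bands else seg.direction
        score = min(1000, int(round(1000 * abs(seg.mean_log2))))
        strand = "-" if seg.direction == "loss" else "+"
        dest.write(f"{seg.chrom}\t{seg.start_bp}\t{seg.end_bp}\t{name}\t{score}\t{strand}\n")


def write_segments_table(
    segments: Iterable[CnvSegment],
    dest: Union[PathLike, TextIO],
    genes: Sequence[tuple[str, int, int]] | None = None,
) -> None:
    """Report-style TSV: chrom, bands, '<start> M-<end> M', span, [gene count].

    Coordinates are printed in megabases, 1-based-style display rounding
    (cytogenetic convention), matching how gross losses are usually tabled.
    """
    if not hasattr(dest, "write"):
        with open(os.fspath(dest), "w") as handle:
            write_segments_table(segments, handle, genes)
        return
    header = "chrom\tdirection\tbands\tlocation\tspan_mb"
    if genes is not None:
        header += "\tn_genes"
    dest.write(header + "\n")
    for seg in segments:
        loc = f"{seg.start_bp / 1e6:g} M–{seg.end_bp / 1e6:g} M"
        row = (f"{seg.chrom}\t{seg.direction}\t{' '.join(seg.bands)}\t{loc}"
               f"\t{segment_span_mb(seg):g}")
        if genes is not None:
            row += f"\t{count_genes(seg, genes)}"
        dest.write(row + "\n")
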