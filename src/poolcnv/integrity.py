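"""Chromosome-scale coverage diagnostics.

The integrity score of chromosome i is its mapped-read density,

    score_i = reads_in_chromosome_i / (length_i / 1000)      [reads/kB]

a deliberately coarse whole-chromosome gain/loss indicator: under uniform
coverage all chromosomes score alike, a lost chromosome scores low, a gained
one high.  The companion diagnostic regresses per-chromosome read counts on
chromosome lengths (in Mbp); uniform data is almost perfectly linear, and
the r-squared of that fit summarizes how well a dataset behaves.  Because a
single male Y (or a low-coverage acrocentric) can dominate such a fit, the
fit can be computed with chromosomes excluded — the excluded chromosomes
are still scored, just omitted from the regression.

A median/MAD outlier rule turns the visual "this chromosome sits off the
line" judgment into a testable call; the rule is a toolkit addition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import stats

from .genome_io import GenomeIndex

PathLike = Union[str, os.PathLike]


@dataclass
class IntegrityScores:
    """Per-chromosome reads/kB plus the linearity fit over included chromosomes."""

    scores: dict[str, float]
    slope: float
    intercept: float
    r_squared: float
    excluded_chroms: tuple[str, ...] = ()


def integrity_scores(
    counts_per_chromosome: Mapping[str, int],
    genome: GenomeIndex,
    exclude: Sequence[str] = (),
) -> IntegrityScores:
    """Score every chromosome and fit reads ~ length over the non-excluded ones.

    Excluded chromosomes are omitted from the regression but still scored.
    """
    for chrom in counts_per_chromosome:
        genome.length_of(chrom)  # raises on unknown chromosome
    scores: dict[str, float] = {}
    for chrom, length in genome.entries:
        if length == 0:
            raise ValueError(f"chromosome {chrom} has length 0")
        n = int(counts_per_chromosome.get(chrom, 0))
        scores[chrom] = n / (length / 1000.0)
    if len(genome) - len(set(exclude)) >= 3:
        slope, intercept, r2 = linearity_fit(counts_per_chromosome, genome, exclude)
    else:
        # too few points for a meaningful regression; scores stand alone
        slope = intercept = r2 = float("nan")
    return IntegrityScores(scores, slope, intercept, r2, tuple(exclude))


def linearity_fit(
    counts_per_chromosome: Mapping[str, int],
    genome: GenomeIndex,
    exclude: Sequence[str] = (),
) -> tuple[float, float, float]:
    """Ordinary least squares of per-chromosome read count on length in Mbp.

    Returns (slope, intercept, r_squared); slope is in reads per Mbp.
    Needs at least 3 chromosomes after exclusion.
    """
    excluded = set(exclude)
    points = [
        (length / 1e6, int(counts_per_chromosome.get(chrom, 0)))
        for chrom, length in genome.entries
        if chrom not in excluded
    ]
    if len(points) < 3:
        raise ValueError(
            f"linearity fit needs >= 3 chromosomes, got {len(points)} after exclusion"
        )
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        # degenerate: constant counts or constant lengths carry no linear signal
        return 0.0, float(np.mean(y)), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def fit_with_without(
    counts_per_chromosome: Mapping[str, int],
    genome: GenomeIndex,
    chrom: str = "chrY",
) -> dict[str, tuple[float, float, float]]:
    """The paired fit: all chromosomes vs. the same fit with one excluded.

    Mirrors the standard with/without-Y comparison for male-containing
    pools, where the single-copy Y drags the all-chromosome fit.
    """
    return {
        "with": linearity_fit(counts_per_chromosome, genome),
        "without": linearity_fit(counts_per_chromosome, genome, [chrom]),
    }


def outlier_chromosomes(scores: IntegrityScores, k_mad: float = 3.0,
                        min_rel_deviation: float = 0.10) -> list[str]:
    """Chromosomes whose score sits far from the median score.

    A chromosome is flagged when its deviation from the median exceeds
    both ``k_mad`` normal-consistent MADs (MAD * 1.4826, the usual robust
    sigma estimate) and ``min_rel_deviation`` times the median.  The
    relative floor matters because karyotypes offer few data points: with a
    handful of chromosomes the MAD is so noisy that sampling fluctuation
    alone would regularly clear a pure k*MAD cut, while any real
    whole-chromosome dosage change (a single-copy Y against diploid
    autosomes is a 50% deficit) clears a 10% floor by a wide margin.

    With MAD == 0 (all scores identical up to the median) any deviation
    beyond the relative floor flags; fully identical scores flag nothing.
    Needs >= 4 scored chromosomes.
    """
    values = np.array(list(scores.scores.values()), dtype=float)
    names = list(scores.scores.keys())
    if len(values) < 4:
        raise ValueError("outlier detection needs >= 4 scored chromosomes")
    median = float(np.median(values))
    mad = float(np.median(np.abs(values - median)))
    flagged = []
    for name, value in zip(names, values):
        deviation = abs(value - median)
        if deviation <= min_rel_deviation * abs(median):
            continue
        if mad == 0.0:
            if deviation > 0.0:
                flagged.append(name)
        elif deviation > k_mad * 1.4826 * mad:
            flagged.append(name)
    return flagged


# ---------------------------------------------------------------------------
# reporting

def write_scores_tsv(scores: IntegrityScores, dest: Union[PathLike, "os.PathLike"]) -> None:
    import io

    if not hasattr(dest, "write"):
        with open(os.fspath(dest), "w") as handle:
            write_scores_tsv(scores, handle)
        return
    dest.write("chrom\tscore_reads_per_kb\texcluded_from_fit\n")
    excluded = set(scores.excluded_chroms)
    for chrom, value in scores.scores.items():
        dest.write(f"{chrom}\t{value:.6g}\t{int(chrom in excluded)}\n")
    dest.write(f"#fit\tslope={scores.slope:.6g}\tintercept={scores.intercept:.6g}"
               f"\tr_squared={scores.r_squared:.6g}\n")


def plot_linearity(
    counts_per_chromosome: Mapping[str, int],
    genome: GenomeIndex,
    dest: PathLike,
    exclude: Sequence[str] = (),
    title: str = "reads vs chromosome size",
) -> None:
    """Scatter of reads vs chromosome size (Mbp) with the OLS line and r²."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    excluded = set(exclude)
    chroms = [c for c, _ in genome.entries if c not in excluded]
    x = np.array([genome.length_of(c) / 1e6 for c in chroms])
    y = np.array([counts_per_chromosome.get(c, 0) for c in chroms], dtype=float)
    slope, intercept, r2 = linearity_fit(counts_per_chromosome, genome, exclude)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, color="#33567d")
    xs = np.linspace(x.min(), x.max(), 2)
    ax.plot(xs, slope * xs + intercept, color="#b03030", lw=1)
    ax.annotate(f"$r^2$ = {r2:.4f}", xy=(0.05, 0.92), xycoords="axes fraction")
    ax.set_xlabel("chromosome size (Mbp)")
    ax.set_ylabel("mapped reads")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(os.fspath(dest))
    plt.close(fig)


def plot_score_bars(scores: IntegrityScores, dest: PathLike,
                    title: str = "integrity score") -> None:
    """Bar chart of reads/kB per chromosome, in genome order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(scores.scores.keys())
    values = [scores.scores[n] for n in names]
    fig, ax = plt.subplots(figsize=(max(5, 0.35 * len(names)), 4))
    ax.bar(range(len(names)), values, color="#33567d")
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=90, fontsize=7)
    ax.set_ylabel("reads / kB")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(os.fspath(dest))
    plt.close(fig)
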