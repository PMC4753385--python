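# Methods

## The model

`poolcnv` detects chromosomal gains and losses from read depth alone, at
coverages far too low for per-base variant calling. The unit of analysis is
the fixed-length window (default 40 kb, 0-based half-open tiling; the last
window of a chromosome may be short). For a tumor read set S and a
reference read set R counted on the same grid, the per-window statistic is

    log2_ratio(w) = log2( S(w) / R(w) )

after optional library-size normalization (R scaled by total(S)/total(R),
on by default). Under pure multinomial sampling the expectation of the
ratio tracks pooled dosage: a region at d copies per cell averaged over the
pool, against a diploid baseline, has expected ratio log2(d/2) — hence −1
for a hemizygous deletion in all pool members, log2(0.75) ≈ −0.415 for a
deletion in 2 of 4 members, +log2(1.5) ≈ 0.585 for a 3-copy gain.
Pooling is integral to the model: the window dosage is the *average* copy
number across the pooled genomes, which is what makes recurrent events
visible and private ones faint.

The reference R is *in silico*: read start positions drawn uniformly over
all valid starts of the genome sequence (chromosome chosen proportional to
its count of valid starts, position uniform within it, sampling with
replacement). This models what a perfectly uniform sequencing run of a
karyotypically normal genome would look like, with no GC, mappability or
error structure. Reads may be counted at their sampled positions directly,
or emitted as FASTQ for an external mapper; the two paths differ in
low-mappability regions, and the direct path is what the test-suite uses.

## Assumptions and what the tests do and do not show

The synthetic pools are generated under a piecewise-constant dosage model:
each pool member samples reads with local rate proportional to its copy
number (2 outside engineered CNVs), with multinomial noise only. This is
exactly the model under which the log2-ratio statistic is unbiased, so the
recovery tests demonstrate *correctness of the arithmetic and the
pipeline*, not robustness to real-data artifacts. Real libraries add GC
bias, mappability loss, uneven fragmentation and breakpoint-spanning reads,
all deliberately absent here; on real data windows are noisier and
thresholds may need loosening.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window_bp | 40 000 | bp | the window length the analysis is built around; small enough to localize gross events, large enough for tens-to-hundreds of reads per window at low coverage |
| read_length_bp | 75 | bp | typical single-end short-read length for the targeted instrument class |
| n_reads (reference) | — | reads | set to the sample's filtered read count so the normalization factor is ≈ 1 |
| min_mean_quality | 20 | Phred | conventional Q20 mean-quality floor |
| min_entropy_bits | 1.0 | bits | a mononucleotide entropy of 1 bit separates repeats/homopolymers (≤ ~1) from random-ish sequence (→ 2) |
| max_dust_score | 7 | — | DUST-style triplet score `10·Σc(c−1)/2 / (T−1)`; ~0 for random reads, ~33 for a dinucleotide repeat; 7 rejects strong repeats only |
| uniqueness_rule | tag_based | — | NH tag, Bowtie2-style XS evidence, or duplicate query names decide multiplicity; `mapq_threshold` (MAPQ ≥ 30) is the documented proxy when no multiplicity information survives |
| pseudocount | 0 | reads | zero keeps extreme losses extreme; zero-count windows become explicit undefined (NaN) markers rendered as gaps |
| loss/gain thresholds | −0.5 / +0.5 | log₂ | between the neutral band (null windows stay within ±0.1 at ~100 reads/window) and the weakest event of interest (−0.415) |
| min_consecutive_windows | 3 | windows | one 40-kb window alone is within noise reach; 3 (120 kb) is not, at the depths targeted |
| max_gap_windows | 1 | windows | lets a single undefined or neutral window bridge a run without merging distant events |
| k_mad | 3 | — | outlier cut in normal-consistent MADs (MAD × 1.4826) |
| min_rel_deviation | 0.10 | fraction of median | see below |

All filter and calling thresholds are toolkit choices — the analysis
protocol this implements names the filters and the window length but not
numeric cutoffs — and every one is exposed in the API and CLI.

## Numerical and design choices

- **Coordinates** are 0-based half-open internally (BED-native; SAM's
  1-based POS converted on read); human-facing output is printed 1-based /
  megabase style. Chromosome naming is strict — "chr1" ≠ "1" — because
  silent harmonization corrupts band lookups.
- **Window assignment** is by read start. Midpoint or overlap-fraction
  rules differ only for boundary-straddling reads; start-assignment is the
  simplest rule that assigns each read exactly once.
- **Short terminal windows** are kept and flagged, not length-rescaled:
  sample and reference share the grid, so the ratio in a short window is
  still fair. The flag lets downstream consumers exclude them.
- **Undefined windows** (zero count on either side with pseudocount 0)
  neither extend nor break a segment run, within the same gap budget as
  neutral windows; segment means are taken over defined windows only.
- **Integrity fit** regresses raw read counts on index lengths in Mbp
  (ordinary least squares). Degenerate inputs — constant counts or
  constant lengths — return r² = 0 rather than erroring; fewer than 3
  chromosomes is a hard error for the fit itself, and `integrity_scores`
  then records a NaN fit while still scoring every chromosome. Lengths are
  index lengths, not N-excluded effective lengths (an option exists, since
  either convention is defensible).
- **Outlier rule.** The whole-chromosome outlier call flags scores whose
  deviation from the median exceeds both 3 normal-consistent MADs and 10%
  of the median. The relative floor exists because a karyotype offers few
  data points: with ~5–24 chromosomes the MAD is noisy enough that pure
  k·MAD cuts flag clean data regularly, while every real whole-chromosome
  dosage change (≥ 25% deviation even for a single extra copy in one of
  four pooled genomes) clears 10% comfortably. With MAD = 0, any deviation
  beyond the floor flags; identical scores flag nothing.
- **Intersection** of per-pool segments is a breakpoint sweep: a region
  belongs to the shared set when same-direction segments from at least k
  pools cover it (k = all pools by default). Output means average the
  contributing segments' means after sorting, so results are invariant to
  pool order bit-for-bit.
- **Rendering** is deterministic SVG (fixed two-decimal coordinate
  formatting, insertion-ordered attributes); every element carries an id
  (`band:<chrom>:<name>`, `win:<chrom>:<index>`) so documents are testable
  structurally, and golden-file byte identity is meaningful. PNG export is
  left to any external rasterizer.

## Problem sizes in the tests

The standard fixture is a 5-chromosome, 1.6-Mb toy genome (40 windows of
40 kb), a 200 000-read in-silico reference, and pools of 4 members at
50 000 reads each — about 5 000 reads per window, where null log2 ratios
stay within ±0.1 and engineered events are recovered within ±0.15 of their
dosage expectation. Oracle-equivalence checks (window counting, interval
intersection, complexity scores) run 100 randomized fixtures against
independent brute-force implementations.

## Known limitations

- No GC-content or mappability correction, no smoothing, no statistical
  segmentation (HMM/CBS): the method is thresholded windows read against a
  band map, by design.
- The in-silico reference cannot model platform biases; on real data,
  systematically biased windows will show nonzero ratios in both
  directions that no reference sampling removes.
- Gene counts per segment depend entirely on the annotation file supplied;
  none is bundled.
- The uniqueness filter approximates the original extraction of
  single-mapping reads; with aligners that emit neither NH/XS tags nor
  secondary records, only the MAPQ proxy is available.
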