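# poolcnv

Copy-number analysis for **low-coverage, pooled-DNA whole-genome sequencing**.

When DNA from several tumors is pooled and sequenced shallowly, per-sample
variant calling is off the table — but recurrent chromosomal gains and
losses still leave a dosage footprint in read depth. `poolcnv` implements
that style of analysis end to end:

1. **In-silico reference** — instead of sequencing a matched normal, sample
   reads uniformly at random from the reference genome sequence itself.
2. **Read filtering** — drop low-quality reads (mean Phred), low-complexity
   reads (Shannon entropy or a DUST-style triplet score), and reads that
   map more than once.
3. **Window log₂ ratios** — tile every chromosome with fixed 40-kb windows,
   count reads per window in both datasets, and compute per window

   ```
   log2_ratio = log2( reads_sample / reads_reference )
   ```

   The statistic is symmetric: +2 and −2 correspond to 4:1 and 1:4 dosage,
   both a fold change of 4. A hemizygous deletion carried by every pool
   member shows up as log₂ ≈ −1; carried by half the pool, as
   log₂(0.75) ≈ −0.415.
4. **Integrity score** — a chromosome-scale diagnostic,
   `score_i = reads_i / (length_i / 1000)` in reads/kB, plus an OLS fit of
   per-chromosome read counts against chromosome size (uniform data is
   almost perfectly linear; r² is the summary) and a robust outlier call
   for whole-chromosome dosage anomalies (e.g. a single-copy Y).
5. **Segment calling and pool intersection** — maximal runs of windows
   beyond a threshold become loss/gain segments; segments present in every
   pool are the "shared" events, annotated with cytogenetic band names.
6. **Ideograms** — SVG chromosome ideograms (Giemsa-stained bands,
   centromere pinch) with the per-window ratio track drawn alongside, one
   panel per chromosome for a whole-genome panorama.

A bundled synthetic-data generator (toy genomes, banded karyotypes, pooled
read sets with engineered CNVs) makes the entire pipeline testable with no
downloads.

## Worked example

```sh
# a 2-chromosome toy genome; a pool of 4 with a deletion on chr1
poolcnv simulate --lengths 400000,200000 --seed 5 --pool-size 4 \
    --per-member-reads 40000 --cnv "chr1:40000-240000:1:0,1,2,3" \
    --out-fasta toy.fa --out-cytobands bands.txt --out-bed pool.bed

# matched in-silico reference (same library size as the pool)
poolcnv sample-reference toy.fa --n-reads 160000 --seed 6 --out-bed ref.bed

# call segments against the reference
poolcnv call pool.bed ref.bed --genome toy.fa --cytobands bands.txt \
    --out-table segments.tsv
cat segments.tsv
```

prints

```
chrom	direction	bands	location	span_mb
chr1	loss	p12	0.04 M–0.24 M	0.2
```

i.e. the engineered one-copy deletion (chr1:40,000–240,000, all four pool
members) is recovered at exactly its 40-kb-window boundaries, spans 0.2 Mb,
and overlaps the toy karyotype's p12 band. `poolcnv draw` renders the same
comparison as an ideogram panorama; `poolcnv integrity` reports reads/kB
per chromosome with the linearity fit; `poolcnv intersect` reduces per-pool
segment BEDs to the shared events. Every subcommand is a thin wrapper over
the `poolcnv` Python API (`import poolcnv`).

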