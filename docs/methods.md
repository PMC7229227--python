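# Methods

## The percent-spliced statistic

For a splice junction `J = (contig, [s, e))` (0-based half-open; the
skipped interval is the intron), two counts are taken from gapped
alignments restricted to CIGAR `M`/`N` operations:

* **split reads** — reads whose alignment skips exactly `[s, e)` with at
  least `min_overhang` (default 4) aligned bases on each side of the
  skip;
* **junction-overlapping reads** — split reads at `J`, plus reads with a
  contiguous aligned block spanning the junction boundary with
  `min_overhang` aligned bases on each side.

Splicing efficiency is `split / overlapping`.  A zero denominator is
reported as *undefined*, never as 0: no overlapping reads is absence of
evidence, not evidence of retention.

**Which boundary defines "overlapping"?**  The denominator uses a single
fixed boundary — the left genomic boundary — by default, with
`right`, `either` and `both` available behind a flag.  The reason is
statistical: under per-molecule splicing, a spliced molecule offers one
window of width `R − 2·overhang + 1` in which a read is split at `J`,
and a retention molecule offers a window of exactly the same width
around any *single* boundary in which a read spans it contiguously.
With single-boundary counting every junction-overlapping read is
therefore an i.i.d. Bernoulli(e) trial of the molecule's splice status
and the statistic is unbiased.  Counting *either* boundary gives a
retention molecule two disjoint windows for introns longer than a read,
deflating the statistic to roughly `e / (2 − e)` (0.5 becomes 0.33);
`both` is only satisfiable by split reads once the intron exceeds the
read length.  The package's recovery tests quantify this and the
default follows from them.

## Cryptic-intron calling

A junction is called cryptic iff all of:

1. unannotated — no exact (contig, interval) match to an annotated
   intron (an optional ±N bp window exists but defaults to 0: splice
   sites are base-precise);
2. absent from the reference condition — the same interval does not
   appear among reference-condition junctions with
   ≥ `min_reference_support` (default 1) split reads;
3. inefficiently spliced — efficiency strictly `< 0.05` (the threshold
   is a parameter; the boundary value 5 % is *not* cryptic);
4. adequately covered — ≥ `min_depth` (default 20) junction-overlapping
   reads.  Low-depth or undefined-efficiency junctions are reported as
   *insufficient evidence*, never as cryptic, so 0/3 artifacts cannot
   become calls.

Donor/acceptor dinucleotides (first/last two intronic bases, reverse-
complemented on the minus strand) are validated against GT..AG
(optionally also GC..AG) and reported.  Canonical sites are *not*
required for the cryptic verdict by default — consensus sites are a
property the biology asserts of these introns, not a filter the calling
rule needs — but a `require_canonical` flag exists.  For junctions of
unknown strand, strand is inferred from whichever orientation yields
consensus sites, else left `"."`.

## Small-RNA profiles and loss calls

Reads are length-filtered to the Dicer-product window [21, 24] nt
(inclusive; configurable — descriptions of siRNA size ranges vary by a
nucleotide, and the filter bounds are the operative definition).  The
full-range input length histogram is always reported: a broad 15–30 nt
profile is the signature of degradation fragments rather than siRNAs.

Coverage piles up every base of each retained read (a `five_prime` mode
counts strand-aware 5′ ends instead), separately per strand, multiplied
by `10⁶ / total_mapped`.  `total_mapped` is the library's total mapped
read count *before* length filtering, so filtering changes track mass
but not the normaliser.  Tracks are written as SGR (one file per
strand, 1-based positions) and bedGraph (bottom strand negative, for
above/below-axis display).

`compare_loss` sums RPM per strand over a region in two genotypes and
reports the log2 ratio (pseudocount 0.01 RPM).  The **abolished** flag
compares the *mean per-base RPM* over the region with a floor (default
1 RPM) and requires a 10× contrast: abolished iff
`mean_b < floor` and `mean_a ≥ 10 × floor`.  The mean per-base value is
used rather than the summed region mass because it is independent of
locus width and library size — it is the height of the browser track —
whereas a fixed floor on summed mass would change meaning with every
region.  Both are reported.

## IP enrichment

*RIP subtraction.*  Tracks must share contig, binning and normalisation
(RPKM at 50-bp bins by default; RPKM = `count · 10⁹ / (total · bin)`).
The enrichment track is `max(0, tagged − untagged)` per bin; the count
of negative residuals is reported, and the subtraction is invariant to
adding a constant to both tracks.

*RIME scoring.*  Each protein gets
`r = log2((PSM_target + pc) / (PSM_control + pc))` with pseudocount
`pc = 1` (PSM tables contain zeros; one spectral count is the smallest
observable unit).  The null is estimated from the observed ratio
distribution itself — in an IP experiment the bulk of identified
proteins are nonspecific binders — using the median and the MAD scaled
by 1.4826, so planted or real enriched outliers do not inflate the null
scale.  The p-value is the standard-normal upper tail of the robust
z-score (default), or the empirical upper-tail fraction
`#{r_j ≥ r_i}/n` behind a flag.  The normal-tail variant yields
calibrated p-values when null counts are in the tens per protein
(Kolmogorov–Smirnov uniformity holds at α = 0.01 across seeded runs in
the test suite) and, unlike pure ranks, distinguishes the extremity of
the top hits; the empirical variant is distribution-free but grainy at
`1/n`.  At least 20 proteins are required, and a degenerate
(zero-scale) ratio distribution is an error.

## The synthetic-data generator

The generator emulates the data layers of a fission-yeast silencing
study, emitting *already-aligned* records: no sequencing-error, quality,
duplicate or aligner model (alignment is upstream of every analysis here,
and its omission keeps recovery tests exact).  All randomness flows from
a single seed; fixed seed ⇒ byte-identical files.

* **Genome and genes.** Random ACGT contig (≥ 1 kb) carrying planted
  gene models: exon chains with intron gaps, GT..AG planted on the
  transcribed strand of every intron (deliberately non-consensus CC..GG
  on request).  Default toy geometry: 150 bp exons, 60 bp introns,
  introns bounded to [30, 1000] bp (fission-yeast-like short introns),
  50 bp reads.
* **Spliced reads.** Each transcript molecule excises intron *i* with
  probability equal to that intron's programmed efficiency,
  independently across introns (no co-splicing model; independence is
  the minimal assumption).  Reads start uniformly along the spliced or
  unspliced molecule; a read crossing an excised intron carries a skip
  of exactly the intron length.  `depth` is mean read-start coverage
  per molecule position; per-intron realised molecule counts are
  returned as ground truth.
* **Small RNAs.** Lengths from a configurable distribution (siRNA mode:
  21–24 nt peak; degradation mode: uniform 15–30 nt), strand from a
  Bernoulli mix, positions uniform over a locus.
* **RIP pair.** Per-bin Poisson background (mean 20 per 50-bp bin) in
  both tracks; the tagged mean is multiplied by the fold (default 5×)
  inside enrichment regions.
* **PSM tables.** Null proteins draw target and control counts i.i.d.
  from a gamma-Poisson with mean 40 and dispersion 0.1 — tens of PSMs
  per protein, as for the abundant nonspecific binders that dominate
  IgG-control pulldowns; enriched proteins have the target mean
  multiplied by the effect (default 8×, 10 of 500 proteins).  The null
  mean matters: robust-z normal-tail p-values are well calibrated in
  this count regime but become anticonservative for very sparse tables
  (mean ~10), where the empirical mode is preferable.

**Study fixture.**  `make_fixtures` emits a five-gene bundle — two
efficient annotated introns (92 %, 95 %), three cryptic introns planted
at 2–3 % excision (0 % in the wild-type condition, where intact RNA
degradation outcompetes splicing), one gene carrying both kinds, plus
small-RNA sets for three genotypes, a RIP pair and a PSM table.  The
small-RNA BED files are subsetted to the simulated loci; RPM
normalisation uses a declared library total of 2 × 10⁶ reads (a typical
small-RNA run), recorded beside the data.  In the silencing mutants the
reads remaining at the silenced locus are genome-wide scattered
broad-length degradation fragments, not siRNAs.

**What the simulation does not capture.**  Multi-mapping (pericentromeric
repeats are represented by unique-placement control loci), sequencing
error, coverage biases, paired ends, co-splicing correlation, and
genome-scale annotation complexity.  Passing tests therefore demonstrate
the correctness of the counting rules and the statistical behaviour of
the estimators under the stated model — not robustness to alignment
artifacts in real libraries.

## Statistical design of the validation studies

* **Binomial recovery** uses single-intron loci with 50,000 molecules at
  depth 28, i.e. ~1,200 junction-overlapping reads at a per-molecule
  junction read rate of ~0.02.  Keeping that rate low matters: reads
  sharing a molecule share its splice outcome, and the variance of the
  ratio estimator is inflated by `(1 + λ)` for a per-molecule rate λ.
  At λ ≈ 0.02 the junction reads are effectively independent trials and
  the estimate falls within `3·√(e(1−e)/n)` of the programmed value in
  ≥ 99 % of replicates.
* **Classification panel**: 50 cryptic introns at 1–3 % excision and 50
  annotated introns at 90–100 %, 2,000 molecules, depth 25 (~1,100
  junction reads per intron).  The 1 % lower edge keeps the expected
  split-read count ≈ 10, so a planted intron essentially cannot vanish
  from the junction set; the 3 % upper edge sits 3 cluster-adjusted
  standard errors below the 5 % threshold.
* Problem sizes throughout (≤ 1,000 reads for oracle equivalence, 204
  recovery replicates, 2,000-protein null tables) were chosen so the
  complete suite and the acceptance script each run in tens of seconds
  on one CPU while leaving the statistical margins above.

## Numerical and bookkeeping choices

* Coordinates are 0-based half-open internally everywhere; GFF3
  (1-based inclusive) and SGR (1-based) are converted only at I/O.
* Identical duplicate reads count independently (raw-count semantics,
  no deduplication).
* Skips outside [min_intron, max_intron] = [30, 10 000] are ignored and
  tallied in a diagnostics report, not silently dropped.
* Junction tables format floats with `%.6g`; manifests contain the
  package version, a config hash, the full parameter dump and input
  SHA-256s, and deliberately no timestamps — reruns with equal config
  and seed are byte-identical.  Per-stage timings go to the run log
  only.
* Track values are floored at 0 after background subtraction for
  display parity; raw negative-bin counts are reported alongside.
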