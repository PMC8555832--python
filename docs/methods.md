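# Methods

## Coordinate conventions and transcript models

All internal coordinates are 0-based: genomic intervals half-open,
transcript offsets inclusive. GTF input (1-based inclusive) is converted on
parse. A `TranscriptModel` stores exons ordered 5′→3′ in transcript
orientation (descending genomic coordinates on the minus strand) and the
CDS as transcript offsets with the **stop codon included** —
`cds_end_t` is the last stop-codon nucleotide — because every downstream
quantity (junction distances, footprint anchors) is measured from the stop
codon. CDS features in GTF conventionally exclude the stop codon; the
parser unions CDS and `stop_codon` features. A transcript without an
annotated stop codon (no `stop_codon` feature, and no supplied sequence
whose terminal CDS codon is UAA/UAG/UGA) is dropped, as is any transcript
whose stop-inclusive CDS is not a multiple of 3 or shorter than 6 nt.

## Representative isoforms

Isoforms are grouped by stop-codon identity — (chrom, strand, genomic
position of the last stop-codon nucleotide) — and one representative is
kept per group: the longest CDS, ties broken by the longest transcript,
then by the lexicographically smallest transcript id. The final tie-break
is this package's determinism guarantee; the first two rules are the
standard selection for NMD analyses.

## The 50-nt rule and uORFs

For each exon–exon junction 3′ of the stop codon, the junction distance is
the spliced-transcript distance from the last stop-codon nucleotide to the
last nucleotide of the exon preceding the junction. A transcript is
**EJC-dependent** if any distance strictly exceeds `d_ejc` (default 50 nt;
the literature quotes 50–55 nt, so the threshold is a parameter). Both
conventions left open by the literature — strictness of the inequality and
which end of the stop codon anchors the measurement — are fixed and
documented here: strict `>`, measured from the *last* stop-codon
nucleotide.

The uORF flag is deliberately broad: any AUG with its first nucleotide in
the 5′UTR and out of frame with the annotated start
((`cds_start_t` − i) mod 3 ≠ 0) counts, with no requirement for an in-frame
stop; AUGs whose codon extends into the CDS qualify; in-frame upstream
AUGs never do. T and U are interchangeable on input.

## Quantification and occupancy

Unique-assignment counting replaces EM-based quantification: a read whose
alignments point at more than one transcript contributes nothing. This is a
deliberate simplification validated only on synthetic data with unique
mappings. TPM uses effective lengths of the whole transcript (RNA) or the
stop-inclusive CDS (footprints), with no fragment-length correction.
Occupancy per condition is (mean RPF TPM + c)/(mean RNA TPM + c) with
pseudocount c = 0.5 TPM (0 for pure normalization); replicates are averaged
within condition before the ratio.

## Differential occupancy test

Counts are normalized by median-of-ratios size factors per assay. Per
transcript and group, the NB dispersion (variance = μ + αμ²) is estimated
by the method of moments with floor α ≥ 0.01, averaged across the two
groups weighted by degrees of freedom, and shrunk 50/50 toward the 10%
trimmed mean of its abundance bin (20 quantile bins). The log2 fold change
log2((m_B + 0.5)/(m_A + 0.5)) is tested against a normal with delta-method
standard error; the occupancy change is lfc_RPF − lfc_mRNA with standard
errors combined in quadrature (assuming independent RNA and RPF libraries —
separate preparations), two-sided normal p, and BH-adjusted q with
significance at q < 0.1 by default.

This is **not** a re-implementation of DESeq2 or Xtail; its validity
surface is calibration and recovery on NB simulations. Two quantified
limitations:

- *Power at high dispersion.* At dispersion α = 0.05, n = 3 and mean 500,
  the sampling sd of lfc_occ is √(4·(1/500 + 0.05)/3)/ln 2 ≈ 0.38, so a
  planted 2-fold occupancy effect sits ~2.6 sd from zero and no test can
  exceed ~75% power at nominal 0.05. The power property test therefore runs
  at α = 0.02, where ≥ 80% power at q < 0.1 is attainable; calibration and
  recovery tests use the default α = 0.05.
- *Normalization contamination.* Median-of-ratios size factors absorb part
  of any one-sided planted effect: with 10% of transcripts carrying a 2×
  RPF effect the recovered median lfc_occ is ~0.92 rather than 1.0; at a 5%
  planted fraction the bias is ≲ 0.05. Recovery checks plant 200 effects
  among 4000 transcripts for this reason. Class-shift tests are unaffected
  (the contamination shifts class and background alike).

## NMD-target meta-calling

Per transcript, each contrast contributes its BH-adjusted p-value if its
fold change agrees in sign with the expected direction (up for NMD-factor
knockdown, down for rescue) and p = 1 otherwise (also when the transcript
is missing from a contrast). The k values are combined by Fisher's method
(upper χ²₂ₖ tail of −2Σln p, zeros clipped to 1e-300) and by the sum of
p-values (Irwin–Hall CDF of Σp). The meta p-value is the **maximum** of the
two — a conservative choice made because the combination rule in the
original description is not spelled out; both components are reported so
alternatives can be audited. Combining *adjusted* p-values is
statistically non-standard but is the reproduced procedure; `use_raw_p`
switches to raw p-values. Calls use meta-p < 0.05. The directionality gate
is this package's own addition.

Both combinations are exact under the null (uniform combined p for i.i.d.
uniform inputs); the maximum is stochastically conservative.

## Junction filtering

Candidate introns are distinct (chrom, donor, acceptor) CIGAR `N` gaps.
`n_support` counts reads carrying exactly that gap; `n_spanning` counts
reads whose alignment covers the last exonic base on both sides (donor−1
and acceptor), spliced or contiguous — the denominator definition is this
package's choice, since alternatives (full-length reads only) are equally
defensible. Motifs are read on the sense strand (reverse complement on
minus-strand junctions); only GU-AG passes by default. Nanopore preset:
support ≥ 2 and fraction ≥ 1%. Short-read preset: support ≥ 5, no fraction
test. Filters are monotone in `min_support`.

## Footprint geometry

Profiles histogram footprint 5′ ends relative to the last stop-codon
nucleotide over a (−120, +30) window. The terminal offset is the modal
position in [−45, 0], reported as a positive upstream distance, ties broken
toward the anchor. The period is the lag (default range 20–40 nt)
maximizing the unpadded autocorrelation of the mean-subtracted upstream
counts, reported only when the score beats the 95th percentile of a
seeded within-profile permutation null (1000 shuffles); the original
observation was descriptive, so the significance gate is this package's
own. Defaults encode mammalian geometry: 30-nt protected footprint,
terminal 5′ end 18 nt upstream of the anchor, queued ribosomes packed one
footprint length apart.

## Screen counting

Reads are matched by the first exact occurrence of a constant anchor
sequence (a required parameter — vector-specific) followed by a 20-nt
spacer exact-matched to the library; matched + unmatched + no-anchor always
equals total. One-mismatch rescue (unambiguous hits only) exists but is off
by default. Gene summaries use the median depth-normalized guide lfc
(log2((sorted+0.5)/(input+0.5)) on reads-per-million) and a Mann–Whitney
test of each gene's guides against the non-targeting guides with BH across
genes — deliberately simple and not equivalent to RRA-style aggregation.

## Synthetic data: what it does and does not emulate

The generator plants exactly the structure the analysis tests: junction
distances straddling 50 nt (exact class counts via permutation), shared
stop codons between isoform pairs (the second isoform's annotated CDS is
30 nt shorter), AUGs planted in or out of frame in otherwise AUG-scrubbed
5′UTRs, NB counts (default α = 0.05) with occupancy effects multiplying
footprint means only and mRNA effects multiplying both assays, spliced
alignments with planted noise classes (1-read gaps, non-GU-AG motifs,
sub-1% fractions), stacked-ribosome 5′ ends with Poisson background, and
multinomial screen reads tilted by planted gene effects. Sequences are
uniform random apart from planted motifs; there is no codon usage, GC bias,
fragment-length distribution or sequencing-error model, so passing tests
demonstrate algorithmic correctness and statistical calibration, not
robustness to real-library artifacts. All draws flow through one
`numpy.random.default_rng(seed)`, giving byte-identical files per seed.

Default problem sizes (200–500 genes, 3 replicates, 2000–4000 transcripts
in calibration runs, 20k screen reads) are chosen so the full suite and the
pipeline run comfortably on a laptop while keeping Monte-Carlo error well
inside the asserted tolerances.

## Pipeline

`run_pipeline` executes simulate → annotate → quant → differential →
meta-call → class statistics (plus optional junction, footprint and screen
stages) and writes a manifest with the package version, a hash of the full
configuration, the seed, and SHA-256 of every output; reruns with identical
config produce identical bytes. Unknown configuration keys are rejected
before any stage runs.
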