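# Methods

This note documents the models behind `mobilnc`, the defaults and why they
were chosen, the numerical decisions, and the limits of what the synthetic
benchmark demonstrates.

## The detection model

The object of study is a parasite–host pair (dodder on soybean is the
motivating system) connected by haustoria, sequenced as three bulk RNA-seq
libraries: parasite stem, host stem, and the interface segment containing
both species' tissue. Detection of mobile RNA is a read-classification
problem over two reference genomes:

* a read matching the native genome (alone or together with the foreign
  one) is **native** — shared matches are deliberately resolved in favour
  of native origin, so mobility is never inflated by conserved sequence;
* a read matching only the foreign genome is **mobile**;
* a read matching neither is **filtered**.

The library-level *foreign-read proportion* is `mobile / (mobile +
native)`; filtered reads are excluded from the denominator. For an empty
library the proportion is undefined and reported as NaN, never 0. The
interface has no native species, so its reads are labelled by origin
(parasite / host / ambiguous) and never enter mobility calls — mobility is
computed from pure stem tissues only.

A transcript of species A is called **mobile** when at least
`min_mobile_fragments` (default 1) mobile-labelled fragments from species
B's stem library are assigned to it. The default reflects
presence/absence detection; on real data a single read is fragile and the
threshold is exposed. Paired reads: a genome counts as matched when at
least one mate matches; pairs whose mates match strictly opposite genomes
are contradictory and are filtered into a dedicated conflict log.

## The internal matcher

The matcher is a transparent stand-in for a spliced short-read aligner,
adequate because the synthetic genomes are i.i.d. uniform and hence
cleanly divergent (the probability of a shared exact 31-mer between two
random multi-megabase genomes is negligible). Design:

* canonical k-mer index (k = 31), seeds sampled every 16 bp plus a final
  seed flush with the read end — any exonic stretch ≥ 47 bp seeds;
* co-linear chaining across diagonals permits introns up to 50 kb; the
  breakpoint between adjacent diagonals minimises mismatches, with a
  2-mismatch-equivalent bonus for breakpoints whose skipped region carries
  a canonical splice motif (GT..AG, or CT..AC for the opposite strand);
* read ends beyond the outermost seeds are extended greedily and stop at
  the first mismatching base; everything beyond is soft-clipped. A read
  must remain ≥ 50% aligned, and interior mismatches (tolerated through
  seed-gap comparison) must stay within `max_mismatch_rate` (default
  0.05) of the aligned length.

Stringent end extension is what makes the mature-form signature exact: a
mobile read is drawn from the spliced transcript, so an alignment that
dragged chance-matching bases past a junction would deposit spurious
intronic coverage. The generator cooperates (see below), and with
error-free reads the foreign-tissue coverage of every mobile transcript
has *exactly* zero intronic depth. With sequencing errors a substitution
adjacent to a junction can, rarely, mimic the intron's first base and leak
a base or two; this is an aligner-level ambiguity no heuristic can remove.

For real data the internal matcher is bypassed: `ingest_alignments` takes
two name-matched SAM/BAM files (one per genome) and applies the same rule
table, with "matched" meaning ≥ 1 primary alignment at mapping quality
≥ 1 (configurable).

## The synthetic experiment

The generator emulates the study conditions, not any particular dataset:

* **Genomes** — i.i.d. uniform sequences (default 1 Mb per species), one
  chromosome each, 70 protein-coding and 50 lncRNA loci per species placed
  without overlap on both strands. Randomness stands in for real
  inter-species divergence and makes assignment ground truth clean.
* **Transcript architecture** — exon counts are drawn from categorical
  distributions; the lncRNA default puts 55% of mass on two exons and 25%
  on one, and mRNAs spread over 1–20 exons with ~6% above 16. Spliced
  lengths are gamma-distributed (shape 4) with means 1458 bp (lncRNA) and
  2133 bp (mRNA), matching the feature summaries reported for the
  dodder–soybean catalog. Introns are exponential (mean 300 bp, min 60).
* **Biotype ground truth** — every mRNA carries an embedded ATG..stop ORF
  of ≥ 300 nt; every lncRNA sequence is rejection-sampled until its
  longest six-frame ORF is below 300 nt *and* below half its length, so
  the transcript is non-coding under both the ORF-length and ORF-coverage
  rules by construction. The 300 nt boundary gives the coding classifier a
  real margin to exercise (a 200 bp boundary would sit on top of the
  descriptive histogram bin edges).
* **Junction hygiene** — introns carry canonical splice motifs; intron
  interiors are rejection-sampled so no shifted junction placement both
  matches the exon sequence and recreates a motif, and exon split points
  are nudged ≤ 3 bp so the base flanking each junction differs from the
  adjacent motif base. These guarantees make junction placement and end
  extension deterministic and exact for error-free reads.
* **Expression and mobility** — one log-normal abundance per transcript
  (σ = 1). Each species' mobile-eligible set (default 30% of transcripts)
  is sampled without replacement with probability ∝
  abundance^`abundance_mobility_bias` (default 1), encoding the
  observation that abundant transcripts move preferentially; foreign reads
  are then drawn abundance-weighted from that set. The *emitted* mobile
  set — transcripts that actually contributed ≥ 1 foreign read — is the
  recoverable ground truth for sensitivity/specificity; at low mobile
  fractions the eligible set is necessarily under-sampled, so recovery is
  defined against what was emitted.
* **Libraries** — default 100,000 read pairs of 2 × 150 bp per tissue.
  Host-stem libraries draw 1.5% of pairs from parasite transcripts and
  parasite-stem libraries 0.17% from host transcripts (the two reported
  tissue-level read proportions of the motivating system, which are inputs
  here, not reproduced claims). The interface mixes the species 50:50 — a
  free parameter, since no measured mixture exists for that tissue.
  Foreign reads always come from the spliced mature sequence; native reads
  come from the pre-RNA with probability 0.15 when the transcript has
  introns. Reads start uniformly on the template; there is no
  fragment-size model because no statistic downstream depends on one. Both
  mates cover the same template interval (mate 2 reverse-complemented).
  Substitution errors are applied per base (default 0.001); indels and
  quality-score realism are out of scope.
* **Determinism** — one root seed; each stage and tissue draws from its
  own deterministically spawned stream, so identical configs give
  byte-identical FASTA/GFF3/FASTQ output.

## lncRNA identification

Candidates pass five filters, each recorded separately: class code in
{i, x, u, o, e}; spliced length ≥ 200 nt; ≥ 2 exons; maximum FPKM over
tissues ≥ 0.1 (a transcript expressed anywhere remains a candidate — the
scope of the FPKM floor is a genuine open choice and "any tissue" is the
permissive reading); and no coding potential.

Class codes follow cuffcompare-style semantics. Against a single
reference transcript the code is decided by a cascade: identical exon
chain (=); contained in one intron, either strand (i); exonic overlap on
the opposite strand (x); same-strand single-exon candidate reaching from
an exon into a flanking intron (e, pre-mRNA-like); any other same-strand
partial exonic overlap (o). Across references the highest-precedence code
wins (= > i > x > o > e > u); a candidate overlapping a reference span
while triggering none of these (e.g. a spliced candidate threading
through introns) is "other" and excluded by filter 1. Positional types
map u → lincRNA, x → antisense, i → intronic, o/e → sense.

The coding-potential rule replaces a three-tool published vote and a
protein-domain scan with one transparent criterion: longest forward-frame
ATG..stop ORF (stop included; forward frames only because the library
protocol is strand-specific, with a six-frame flag for non-stranded data);
coding iff ORF ≥ 300 nt, or ORF coverage ≥ 0.5 of the transcript, or the
translated ORF matches a user-supplied amino-acid regular expression (the
domain-scan stand-in). All thresholds are arguments.

## Quantification choices

* FPKM = `fragments × 10⁹ / (total_mapped_fragments × spliced_length)` —
  the standard definition, fixed here because the quantity is cited
  without a formula in the motivating work. Fragments overlapping n
  transcripts' exons (same strand) are split 1/n; fragments in no exon go
  to an intergenic bucket that still counts in the denominator.
* Logs use a pseudo-FPKM of 10⁻³ (stated wherever logs appear);
  abundance summaries use log₂(FPKM+1); heatmap z-scores use
  log₂ or log₁₀ with rows of zero variance emitted as zeros and flagged.
* Transfer-table percentages are recomputed from counts on demand and
  rounded half-up to the printed precision — 1 decimal at ≥ 1%, 2 decimals
  below 1% (the convention visible in the printed table, e.g. 7.8% next
  to 0.74%); cross-species ratios round to 2 decimals.
* The interface regression is OLS of log₁₀(FPKM+10⁻³) in the foreign stem
  on the same quantity at the interface, over mobile transcripts with
  positive FPKM in both tissues; < 3 such transcripts is an error, not a
  silent zero.

## Target prediction

* **Cis** — a gene is a cis target when the gap between the two
  transcripts' genomic spans is strictly below the window (default
  100 kb, anchored on the full span rather than the TSS); overlap counts
  as distance 0; strand is recorded but does not gate eligibility.
* **Trans** — the hybridisation score is a local alignment of the lncRNA
  against the reverse complement of the mRNA with pair scores GC = 3,
  AU = 2, G:U wobble = 1 (arbitrary units) and a gap/mismatch penalty of
  4; dG is minus the best local score and ndG divides by the shorter
  length. Pairs with ndG ≤ −0.1 are reported, strongest first. The two
  hybridisation orientations give identical optima, so one alignment
  suffices. This energy model is a deliberately simple, documented
  stand-in for a published hybridisation predictor; externally computed
  pair tables can be ingested instead. Note the score's length behaviour:
  local-alignment noise grows only logarithmically, so for
  transcript-length sequences random pairs sit well above the cutoff,
  while short (< ~300 nt) random pairs can cross it — the cutoff is
  calibrated for transcripts, not oligos.
* **Co-transfer** — a pair is co-transferred when the lncRNA and its
  target gene are both mobile (same direction, which is the conservative
  reading of co-movement); counts are summarised per mode.
* **Enrichment** — one-sided hypergeometric over-representation,
  enriched at raw p < 0.05 to match the stated criterion, with a
  Benjamini–Hochberg column alongside for rigour. The calibration
  experiment uses a 50,000-gene background, 5,000-gene sets and broad
  slim-style terms (10,000–20,000 genes) so the discrete null is
  near-continuous; its exact attainable level at nominal 0.05 is 0.048.
* **TF families** are table-driven (gene → family TSV), replacing an
  external prediction service; networks are exported as SIF plus a
  node-attribute table (lncRNA / mRNA / TF roles) for Cytoscape.

## Problem sizes used in the reproduction script

The script runs the full pipeline at 100,000 read pairs per tissue on
1 Mb genomes with 240 transcripts — large enough that the binomial error
on a 1.5% fraction is ~0.04 percentage points and every designated mobile
transcript is exercised, while one run stays under a minute. Feature
distributions are measured on a dedicated 2,000-lncRNA genome pair, and
enrichment calibration on 200 null replicates × 20 terms.

## What the synthetic benchmark does not show

Random genomes have no homology, repeats, paralogy or shared conserved
domains, so cross-genome ambiguity — the dominant error source on real
parasite–host data — is absent by construction; perfect recovery here
validates the logic, not real-data accuracy. There is no transcript
assembly: transcript models are taken as given (or simulated), while real
pipelines inherit assembler artefacts. The coding classifier and the
hybridisation score are transparent stand-ins and will not numerically
match CPC/CNCI/CPAT or LncTar outputs. Real-data catalog counts (numbers
of identified or mobile lncRNAs, target-pair counts, enriched-term lists)
depend on the deposited sequencing data and external databases and are
not recomputed here; the package reproduces the *arithmetic* on the
printed tallies and the *directional* findings on synthetic data.
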