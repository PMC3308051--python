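# Methods

## The problem the package models

Tetraploid wheat-like genomes (AABB) carry two diverged copies of most
genes.  Exon capture against a cDNA reference built from a *single*
representative homoeolog per gene collapses reads from both subgenomes (and
any paralogs that survive uniqueness filtering) onto one coordinate frame.
Variant discovery must then separate three signal classes that look
identical in a single accession — inter-genomic divergence (GSS), lineage
polymorphism (SNP), and paralog co-alignment artifacts — and must recognise
structural signals (copy-number differences, whole-gene absence, loss of one
homoeologous copy) from depth and allele-representation patterns.

## Synthetic tetraploid generator

`synthetic_tetraploid` generates the study conditions end to end and records
every planted feature, so each downstream detector can be scored exactly.

* **Genes.**  Each cDNA is 4% 5'UTR, 65% CDS, 31% 3'UTR by default
  (configurable); the CDS is a clean ORF — ATG start, internal stops removed
  by rejection sampling, one terminal stop — because effect annotation needs
  unambiguous frames.  Gene lengths are uniform on 900–1500 bp.
* **Divergence.**  The B homoeolog derives from the ancestral (A) sequence
  by per-base substitution at d = 0.02 in CDS (UTR divergence defaults to
  the same d; the paper gives no separate figure, so it is a single
  configurable knob).  Mutations are substitutions only; the indel pipeline
  is out of scope.  The start codon is protected so both copies annotate.
* **Accessions.**  Two lines, a cultivated-like `Ld` and a wild-like `Td`,
  carry lineage SNPs at 1.3/2.0/1.6 per kb (CDS/5'UTR/3'UTR), each SNP on
  one randomly chosen subgenome copy.  SNP and GSS coordinates are disjoint
  by construction (the default design flag).
* **Structure.**  Configurable counts of paralogous genes (an extra copy at
  5% divergence present in both lines), full or partial homoeolog deletions
  (partial = a contiguous block ≥ 50% of the gene, emulating observed
  partial losses), reciprocal deletions (each line loses a different
  subgenome's copy), whole-gene PAV, and duplicated families (extra copies
  at 0.5% divergence in one line).  Event classes occupy disjoint genes.
* **Reads.**  Genomic copies carry 1–3 introns of 60–200 bp (sequences
  diverged at d between subgenomes), and 40-bp single-end reads are drawn
  from the *genomic* sequence, so a predictable fraction of reads straddles
  exon–intron junctions.  Per-copy read counts are Poisson with mean
  λ·eff·L/ℓ (λ = 13 by default, ℓ the post-tag fragment length), giving
  per-base depth ≈ λ·eff.  The efficiency multiplier eff = 0.5^(d/0.02)
  encodes the observed two-fold capture loss per 2% bait divergence.
  Accession tags (default `AT` for Ld, `CCAGT` for Td) are prepended inside
  the 40-bp read, as in tag-sequenced libraries.  Qualities are constant
  phred 35 with substitution errors injected at 0.2% per base — quality
  modelling is not the subject here; 0.2% approximates a post-chastity
  short-read error floor.  One seed makes FASTA/FASTQ/truth byte-identical.

What the generator does *not* emulate: selection (planted mutations are
neutral, so non-synonymous changes outnumber synonymous ~3:1, the reverse of
selected real data), indels, quality decay along reads, GC-dependent capture
efficiency, and fragment-level duplicates.  Tests passing on this generator
therefore validate the *procedure's bookkeeping and discrimination logic*,
not its behaviour under real base-caller noise.

## Read preparation

Demultiplexing assigns each read to the longest matching tag prefix (an
empty tag defines a no-tag class), rejecting reads with any phred < 15 in
the first four bases, then trims the tag.

The aligner reproduces `-m 1 -n 2`-style semantics without external
binaries: an ungapped end-to-end placement is valid if it has ≤ 2 mismatches
in the first 28 bases (the seed, taken on the read as sequenced) and ≤ 3
mismatches overall; a read is reported only when exactly one placement on
either strand qualifies, otherwise it is suppressed as ambiguous
(`multi_hit`) or unmatched (`no_hit`).  Candidate placements are enumerated
exactly via a 9-mer pigeonhole index (≤ 2 seed mismatches leave at least one
of three disjoint 9-mers intact), which the tests verify against a
brute-force scanner.

Unaligned reads enter the iterative trim-and-realign loop: one base is
removed from the 3' end (preferred) or the 5' end, the read is re-aligned,
and the process recurses breadth-first over trim states until a unique
placement appears or the read falls below 30 bp.  Breadth-first order
returns the placement reachable with the fewest trims, 3' on ties; the 3'
preference follows the sequencing-chemistry convention that 3' quality
decays first.  Ambiguous states are pruned — trimming can only remove
mismatches, so every placement valid for a read remains valid for its
sub-reads and ambiguity cannot resolve by trimming.  In the workflow the
loop runs with a tightened budget (≤ 1 mismatch): the loop's purpose is to
isolate the exonic portion of a junction read, and a looser budget lets
shifted placements that still contain intronic bases win.

## Pileup and coverage

Per-target, per-accession (L, 5) count matrices over A/C/G/T/N.  MDC is the
median depth over *all* target bases, zero-coverage bases included (the
breadth statistics imply zero-inclusive medians); the combined MDC is the
median of per-base summed depths and is the default input to the high-MDC
filter (a flag switches to per-accession).  Before counting, the workflow
clips 4 bases from each end of every alignment: residual intronic bases on
junction reads that aligned within the mismatch budget concentrate at read
ends and otherwise create systematic artifact alleles around exon
boundaries; terminal clipping (the read-position-filter idea familiar from
VarScan-era pipelines) removes that support at a small uniform cost in
depth.  `expected_mdc` and `fold_enrichment` are the corresponding
bookkeeping ratios.

## Variant classification

A position becomes a variable site when its pooled second allele has ≥ 2
reads **and** reaches ≥ 2 reads and ≥ 10% allele frequency within at least
one accession.  The within-accession requirement implements the site-entry
invariant (a read apiece in each line is a stray-mismatch signature, not a
variant), and the frequency gate resolves the open question about the
variant caller's frequency threshold: without it, pairs of identical
sequencing errors under deep columns dominate the SNP false-positive rate;
10% is half the conventional default, loose enough not to touch true
capture-biased GSSs (alternative-allele frequency ≈ 1/3).

Classification of a site: more than two supported alleles → `triallelic`;
any IVS whose log2(ref/alt) ratio falls outside the per-accession
[−upper, +upper] band → `ratio_out_of_range` (the lower bound defaults to
−upper since only upper values are conventionally quoted); IVS in both
accessions → GSS; IVS in one with the other monomorphic (≤ 1 discordant
read tolerated as sequencing error) at depth ≥ 8 → SNP, oriented by the
inter-genomic comparison (shared allele ancestral, unshared derived, the
IVS-bearing accession the derived lineage); monomorphic side too shallow →
`low_mono_coverage`.  A pooled-variable site where *neither* accession is an
IVS — each line monomorphic for a different allele, the footprint of
reciprocal homoeolog loss — is set aside as `no_ivs` and handled by the
structural detectors.

**Threshold calibration.**  `calibrate_ratio_thresholds` returns the largest
u such that among sites with ratio ≤ u the known-false fraction is ≤ 5%,
scanning the merged observed values (the paper's own values, 1.6 for Ld and
1.0 for Td, are the `ClassifierConfig` defaults and correspond to *its*
data).  The workflow recalibrates per accession from its own validated
sets — ratios at planted GSS positions as true IVSs, ratios at variable
sites inside known multi-copy genes as false — mirroring the Sanger-based
calibration on re-sequenced genes.

**Flank rescue.**  A SNP call may be a GSS whose diverged second-variant
reads simply failed alignment.  The rescue builds a 40-bp reference window
centred on the site (±20 bp; centring maximises overlap for 40-bp reads,
the window shrinks with a warning at target edges) with the missing variant
substituted, and scans the monomorphic accession's *unaligned* reads, both
strands, for a match with ≤ 3 mismatches covering the site; a hit demotes
the call to `flank_rescued`.  Restricting the pool to unaligned reads is
both faster and sharper: a read carrying the missing variant that *did*
align would already have contributed to the pileup.

**High-MDC filter.**  The cutoff is the 99th percentile (linear
interpolation) of combined MDCs over known single-copy genes, or an explicit
override; exclusion is inclusive at the boundary (MDC ≥ cutoff).

**Error model.**  `expected_missed_variant_sites` returns
min(1, 2e^(−λ))·d·L.  The quoted closed form multiplies by 2 a probability
that already contains the factor 2; the implementation uses the single
factor, which reproduces the printed estimate (0.3 at λ = 13, d·L = 70,000).

## Structural variation

Only targets with ≥ 70% of bases covered at least once enter the depth and
variant-pattern detectors; PAV is assessed on every target (MDC 0 in one
line, ≥ 10 in the other).  Windows are 500 bp at 250-bp step (a target
shorter than one window forms a single window and the four-window
requirement scales down to the windows available); the window statistic is
the delta-method normal approximation z = ln r/√(1/x + 1/y) on the
library-normalised count ratio, with a 0.5 continuity correction for zero
counts — a self-contained, asymptotically equivalent replacement for the
external ratio test the original analysis deferred to, with α = 0.001 by
default (the original significance level is not printed; the value is
exposed in configuration).  Significant windows must agree in sign: a single
event cannot be simultaneously gain and loss.  Mechanism inference compares
the target's variable-site count with the mean over non-CNV targets: zero
sites → deletion in the lower-coverage line; above baseline → duplication in
the higher-coverage line (flagged low-confidence within one √baseline of
it); otherwise ambiguous.

Homoeolog deletions use allele representation at a gene's variable sites
(≥ 3 comparable sites; a fraction on one or two sites would trigger
trivially).  Per site, each accession is *single* if exactly one of the
site's two alleles has reads there.  A gene is a homoeolog deletion in an
accession when > 70% (strict) of comparable sites have that accession single
while the other shows both.  When instead both accessions are single at
> 70% of sites — necessarily for different alleles, or the sites would not
be variable — the retained alleles are phase-voted by whether the accession
matches the reference base; a ≥ 70% consistent split calls a reciprocal
deletion.  (A literal per-site "single while the other shows two" predicate
is identically zero in the reciprocal case, so the both-single fraction is
tracked separately.)  SNP calls on targets called as homoeolog or reciprocal
deletions are demoted (`homoeolog_deletion_target`): at such genes the
single-variant pattern reflects the lost copy, not lineage mutation.

## Effect annotation

Gene models are contiguous UTR5|CDS|UTR3 spans in cDNA coordinates with
codon-aligned CDS.  Codon context comes from the reference sequence with the
ancestral/derived allele substituted, translated under the standard nuclear
code (the targets are nuclear cDNAs): equal amino acids → synonymous
(including stop→stop, which leaves the protein unchanged), derived stop →
stop gain, ancestral stop → stop loss (ORF restoration), else
non-synonymous.  GSS changes are oriented reference-allele → alternative
under the reference homoeolog's frame.  Densities are counts per covered
kilobase by lineage × region.  GO enrichment contrasts per-gene
non-synonymous vs synonymous counts in- versus out-of-term with two-sided
Fisher exact tests and Benjamini–Hochberg step-up control at FDR < 0.05 —
the conventional reading of "FDR" in annotation-era pipelines; degenerate
margins are skipped with a log entry.

## Assay QC

32-mers pack into a 64-bit word at 2 bits/base; windows containing
ambiguous bases are skipped (the 2-bit alphabet has no ambiguity code) and
counting is strand-specific by default, matching a cDNA-versus-genome
screen (a canonical flag merges reverse complements).  A target's abundance
is the median index frequency over its windows; targets above the 99th
percentile of abundances are flagged repetitive (the original screening
percentile is not printed; 99 matches the MDC filter's convention).  The GC
screen flags baits outside [0.35, 0.65].

## Numerical and design choices

* Percentiles use linear interpolation (`numpy.percentile` default).
* Allele-rank ties break by A<C<G<T order; alignment ties (same mismatch
  count) cannot occur for reported reads, which must be unique.
* The reference homoeolog alternates A/B by gene index — deterministic and
  balanced, emulating single-copy bait selection.
* `simulate_ivs_ratio_mixture` models calibration draws directly at the
  count level: true IVSs binomial around 1:1 with a 0.55 reference bias,
  false IVSs at 3:1 (0.75), depths Poisson(13) conditioned on both variants
  observed.
* Problem sizes: the recovery suite runs 15 genes at λ = 30 (the paralog-free
  recovery operating point) and the full synthetic run 200 genes at λ = 13
  with all event classes; the calibration experiment uses 20,000 true +
  5,000 false sites per draw so the Monte-Carlo error on the measured
  false-IVS rate is a few tenths of a percentage point.

## Known limitations

* Ungapped alignment only; indels neither simulated nor called.
* The simulator's uniform intron placement and constant qualities
  understate real junction and error heterogeneity.
* Reciprocal-deletion phase voting uses the reference base as a proxy for
  subgenome phase; genes with many paralog-derived sites could defeat it.
* GO enrichment consumes an existing gene→GO map; it does not produce
  annotations.
* The depth-ratio CNV detector shares the usual weakness for small
  multigene families: modest ratio shifts drown in per-target variance.
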