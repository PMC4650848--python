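# Methods

This note documents the models, parameter choices and numerical decisions
behind `polymut`, and what the bundled synthetic validation does and does
not demonstrate about real data.

## Read preparation

A read is retained iff it begins with one of the sample barcodes (4–8 bp,
unique, prefix-free; matched exactly, no mismatch rescue) immediately
followed by the *Ape*KI cut-site remnant `CWGC` (W ∈ {A, T}). Reads with
an `N` in the first 72 bases of the original read (8 bp maximum barcode +
64 analysed bases; the scan is applied on original-read coordinates),
and reads whose post-remnant sequence matches ≥ 12 bases of the common
adapter (adapter/adapter dimers), are discarded. Survivors are truncated
to 64 bases including the initial remnant; shorter reads are dropped
rather than padded so the analysis length stays uniform. The filter is a
partition: every input read lands in exactly one of
{no-barcode, no-remnant, N, dimer, too-short, retained}, and the trimmer
is idempotent.

## Alignment

Reads map to the unigene transcriptome with a k-mer (k = 16) seed index
and banded edit-distance extension (edlib, combined edit budget
`max_mismatches + max_indel` = 8 on 64-bp reads), both strands. Design
points:

* **Homoeologs co-map by design.** The three subgenome copies of a gene
  are expected to align to its one unigene contig; no attempt is made to
  split them at alignment time. Disentangling is the classifier's job.
* **Mapping quality** is a declared heuristic, not a probability: 60 for
  a sole candidate placement, 0 on a tie, otherwise
  `min(60, 20 + 10·(second_best − best))`. Unique perfect hits therefore
  score ≥ 30 and ambiguous ones < 30, which is all the downstream
  MQ ≥ 30 filter consumes.
* **Indel canonicalization.** Plain edit distance cannot distinguish a
  contiguous 2-bp deletion from two split 1-bp deletions, and a terminal
  edit is representable as either a substitution or a gap at equal cost.
  Placements containing gaps are therefore re-aligned with affine gap
  penalties (match +2 / mismatch −4 / open −6 / extend −1) over a window
  at least as long as the read, edge gaps are stripped, and terminal
  insertions are rewritten as substitutions when reference bases exist.
  Pileup indel observations are additionally left-aligned against the
  reference and ignored when anchored within 5 bases of a read end.
* **Adapter read-through** (fragments shorter than the read) is handled
  by an exact-prefix scan for the common adapter followed by 3' soft
  clipping.

SAM is read and written through pysam with read groups carrying the
sample, so BWA or any SAM-producing aligner can replace this stage.

## Genotype calling

Pileup aggregates per-sample allele observations per covered reference
position (insertions attached to the preceding base, deletions spanning
their bases, both left-aligned; base-quality floor 13, the conventional
mpileup default). At most two alleles are kept per site (reference plus
the most frequent alternate; others are dropped with a logged tally).

Per sample, the caller is deliberately **diploid** despite hexaploidy:
log-likelihoods for 0/0, 0/1, 1/1 treat each read as drawn from one of
two chromatids with base-error probability `e = 10^(−Q/10)` and
`P(b|a) = 1−e` if `b = a`, else `e/3`. GT is the maximum-posterior
genotype under a uniform prior; GQ = −10·log10(posterior of the other
genotypes), integer, capped at 99; QUAL = −10·log10 P(all covered samples
0/0); MQ is the RMS mapping quality of covering reads. The consequence of
the diploid model — a fixed homoeologous difference looks heterozygous in
every sample, an EMS heterozygote is a ~1/6-fraction 0/1 in one sample —
is precisely the cross-sample signal the classifier uses. QUAL under this
definition is monotone in alternate-allele support, and posteriors agree
exactly with brute-force enumeration over chromatid assignments (tested
to depth 12).

SNVs called within 5 bp of an indel call are suppressed (the classic
SnpGap rule): gap realignment scatters substitution artifacts around true
indels.

## Classification

Applied to sites passing the retention filters (QUAL ≥ 30, DP ≥ 10,
MQ ≥ 30, ≥ 2 samples with reads; tallied sequentially in that order):

1. **intervarietal** — every covered sample is 1/1;
2. **singleton deviator** — exactly one covered sample deviates from the
   uniform homozygous genotype (0/0 or 1/1) of all others; samples
   without coverage are ignored in the uniformity test. The candidate
   additionally requires the *distinguishing allele* (the one the
   deviator carries and the background lacks) to be absent from every
   other sample's reads: an induced mutation is private to one plant at
   the read level, whereas a homoeologous site undercalled in the other
   plants still leaves alternate reads there. A mutant deviator with
   GQ ≥ 30 (stringent) or ≥ 20 (redefined) is an EMS call (SNP or INDEL
   by allele lengths; zygosity class 0/1 = het, otherwise hom, including
   the 0/0-singleton-among-1/1 case). A wild-type deviator is routed to
   error-rate accounting, never to EMS;
3. **homoeologous** — alternate allele called in ≥ 2 samples;
4. **filtered** otherwise (reason recorded).

The ordering makes the classes an exact partition of retained sites, and
relaxing the GQ threshold from 30 to 20 can only move sites *into* the
EMS class (monotonicity). The singleton test precedes the homoeologous
test because a 0/0 singleton against a uniform 1/1 background would
otherwise be unreachable.

The **error rate** is estimated on wild-type plants: denominator =
retained variants with wild-type reads present; numerator = those where a
wild-type plant is the sole deviator passing the same GQ threshold a
mutant would need; reported in percent.

## Characterization

* Directed substitution counts are kept on the reference strand as called
  (no strand collapsing); transition = purine↔purine or
  pyrimidine↔pyrimidine. Percentages are reported both as shares of all
  SNPs and within the transition/transversion class, to 1 decimal.
* The **longest ORF** is the longest stop-codon-free codon stretch over
  all six frames, with no ATG requirement (recorded in output so an
  ATG-anchored variant can be swapped in); ties break deterministically
  by frame order, then leftmost. A SNP inside it is classified by codon
  translation under the standard code; outside, non-coding.
* **Coverage/depth**: percent coverage divides covered bases by unigene
  length; regions are maximal covered intervals; average depth divides
  reads in retained regions by the number of retained regions, after
  dropping regions with fewer than `min_depth` (10) reads. Saturation
  curves pool samples in ascending order of mapped reads and recompute
  from scratch at each step.
* **Frequency/extrapolation**: kb-per-mutation = covered bp / mutations /
  1000 (1 decimal). The effective count rounds
  `SNPs × nonsyn_fraction × (1 − error_rate)`; division by the coverage
  fraction and scaling by total/covered unigenes truncate, with the
  full-coverage intermediate carried unrounded into the genome-wide step
  (the only convention under which the three printed values of the
  published chain agree).

## Physical mapping

Each chromosome arm of the seven wheat homoeologous groups splits into
deletion-bin regions R1 (proximal), R2, R3 (distal) with a known count of
anchor ESTs; the packaged TSV carries all 42 regions (5,500 mapped ESTs).
Unigenes are assigned to regions by best local alignment against the
anchor ESTs (≥ 95 % identity over ≥ 200 aligned bases by default — an
identity/length stand-in for a stringent E-value cutoff; score ties
across regions leave a unigene unassigned). Region loads divide observed
mutations by mapped ESTs, rounded to 2 decimals; arm and chromosome sums
are computed on the *unrounded* loads and then rounded — the convention
under which the published normalization table reproduces exactly,
including its two rows where summing the rounded values would differ by
0.01.

## Synthetic data generator

The generator emulates the study design so every stage is testable with
known answers:

* **Reference and homoeology.** `n_unigenes` (default 200) random
  unigenes of 300–900 bp; three copies per unigene diverged by planting
  sites at rate 1.5 × `homoeolog_divergence` (default 0.01), each on
  exactly one copy, so the expected *pairwise* copy divergence equals the
  configured value. Intervarietal substitutions (rate 5 × 10⁻⁴, the
  density implied by study-scale counts per covered bp) are applied to
  all copies. *Ape*KI `GCWGC` sites are written into each unigene every
  150 bp — at desk scale the natural ~1/512 bp site density would leave
  most short unigenes fragment-free — and digestion then scans the actual
  mutated chromatid sequences, so mutations that create or destroy sites
  change fragmentation exactly as they would in a real digest.
  Methylation sensitivity is not modelled (every site cuts).
* **EMS load.** Each mutant plant receives exactly 40 SNPs and 5 INDELs
  (1–3 bp deletions at 64 % frequency, 1–4 bp insertions) by default.
  The true per-plant load before detection is not knowable from published
  detection counts, so these defaults are calibration knobs chosen once
  to give a few hundred events — enough statistical power for
  recall/precision estimates at the 200-unigene scale — at a realistic
  one-per-few-kb density. 43 % of SNPs are G→A/C→T (the observed GC→AT
  share); non-spectrum draws exclude that pairing so the planted fraction
  is exact in expectation. 89 % of events are heterozygous, placed on one
  of the two chromatids of one homoeologous copy; homozygous events hit
  both chromatids of one copy. Events never collide with homoeologous or
  intervarietal sites, cut-site footprints, or each other (6 bp guard),
  and indel footprints are validated *after* left-alignment, which can
  shift an anchor onto a neighbouring position.
* **Sequencing.** Each fragment locus of a plant draws a
  Poisson(`mean_depth_per_fragment`, default 20) read count, split as
  independent Poissons over 3 copies × 2 chromatids × 2 orientations
  (the sum is exactly Poisson); per-base depth near a fragment end is
  therefore ~10 per plant on single-orientation stretches. Fragments
  shorter than 64 bp are dropped (library size selection; this also keeps
  adapter sequence out of the trimmed analysis window). Reads are barcode
  + remnant-led fragment prefix padded with common adapter to 100 bp;
  substitution errors are injected anywhere in the read at
  `base_error_rate` (default 0.1 %) with quality 2–15 (correct bases
  Q40), so the quality floor and the caller's error model are both
  exercised. 5 % junk reads (bad barcode, bad remnant, embedded N,
  adapter dimer) exercise the preparation filters. A fixed seed gives
  byte-identical FASTA/FASTQ/TSV output.

**What passing the synthetic validation shows — and what it does not.**
It shows the cross-sample discrimination logic is correct: planted
homoeologous and intervarietal sites are recovered as such, planted EMS
events at well-supported sites are recovered with their carrier, and
wild-type plants produce a near-zero error rate at the configured error
level. It does not establish performance on real GBS data, where read
depth is far more dispersed across plants and loci, PCR duplicates cannot
be removed from single-end data, entire homoeologous copies can drop out
of coverage (the mechanism behind homozygous-looking 1/1 mutation calls;
with the generator's uniform copy sampling, essentially all detected EMS
calls are 0/1), error profiles are position- and context-dependent, and
the reference transcriptome is redundant and incomplete. Overall recall
on the synthetic design (~0.3 at the defaults) is a statement about
coverage and allele-fraction detection limits, not about the classifier;
recall among filter-passing sites is the classifier's own metric.

## Known limitations

* Residual alignment-representation ambiguity can survive the affine
  canonicalization when a true insertion sits where reads systematically
  end; its mismatch representation occasionally yields a satellite SNV
  call in the carrier plant (observed at the few-per-hundred level in
  precision across seeds).
* The diploid genotype model is inherited by design; a polyploid
  (allele-dosage) model is future work.
* Shared induced mutations (the same lesion in two plants) are
  undetectable by construction of the singleton rule, and structural
  variants beyond 4 bp indels are out of scope.
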