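# Methods

## The problem and the statistic

Allele-specific expression is usually quantified by phasing reads against
parental genotypes. When no genotypes exist, transcript SNPs can stand in:
if both parental alleles of a gene are transcribed, each heterozygous site
appears in the RNA as a mixture near 50/50; if only one allele is
transcribed, the site appears essentially homozygous and produces either no
variant call or one near 100% frequency. The pipeline therefore counts, per
transcript and sample, the heterozygous sites that carry *bi-allelic*
evidence, and normalises by mature transcript length:

    SNP/kb = 1000 · n_confident_SNPs / transcript_length_bp

Low SNP/kb relative to neighbouring non-imprinted genes indicates
mono-allelic (imprinted-like) expression; SNP/kb near the parental SNP
density indicates bi-allelic expression. The statistic is comparative, not
absolute: a gene whose parents happen to be homozygous also scores 0, which
is why inference is done across many genes at several loci and against
non-imprinted neighbours in the same samples.

## Variant calling

Pileups are computed from primary alignments only (unmapped, secondary and
supplementary reads are skipped), walking each read's CIGAR so insertions
and deletions contribute nothing; only aligned matches are tallied. Base
qualities enter the caller solely through the mean quality of
alternate-supporting bases; no BAQ-style adjustment or duplicate removal is
applied — single-embryo libraries are whole-transcriptome amplified, and
deduplication would distort allele fractions.

A site yields at most one call: the most frequent non-reference base, ties
broken in A < C < G < T order (sites are treated as bi-allelic SNPs). A
call is emitted when all three inclusive thresholds hold: supporting reads
≥ `min_reads2` (10), frequency ≥ `min_var_freq` (1%), mean supporting
quality ≥ `min_avg_qual` (Phred 20). Inclusive semantics follow the
documented behaviour of the VarScan options these thresholds mirror.

## The filter chain and its boundary semantics

| filter | rule | boundary |
|---|---|---|
| site depth | depth > 25 | strict (25 excluded, 26 kept) |
| variant frequency | 20% ≤ VF ≤ 80% | inclusive at both ends |
| SNPs per transcript | n ≥ 3 | inclusive (3 retained) |
| gene reads, summed over samples | ≥ 5000 | inclusive |

The depth rule is deliberately strict while the read gate is inclusive; the
two were specified with different wording ("more than" vs "or more") and
the distinction is preserved. Retention at exactly 3 SNPs follows the
worked example of a transcript with exactly 3 SNPs whose SNP frequency is
reported.

Two consequences of the ≥3-SNP rule deserve emphasis:

* **Discarding SNPs, not transcripts.** A transcript with 1–2 surviving
  SNPs has its SNPs treated as putative artefacts (PCR/sequencing error),
  so its *effective* SNP frequency is 0 — the transcript stays in the
  analysis. This is essential: a mono-allelic gene almost never reaches 3
  confident SNPs, and excluding such transcripts outright would remove
  precisely the observations that carry the imprinting signal from the
  group comparison. Summaries expose both the raw `snp_per_kb` with a
  `retained` flag and the `effective_snp_per_kb` used downstream.
* **Locus aggregation.** Locus-level SNP/kb is recomputed from totals:
  SNPs summed over retained members, lengths summed over *all* analysed
  members. A member whose sparse calls were discarded still contributes
  scanned sequence to the denominator (this is also the only reading under
  which a ten-gene locus can report 27 SNPs — nine genes at ≥3 would be
  the maximum compatible split). Locus/class combinations with no retained
  member are omitted rather than reported as 0/total, since they carry no
  calibrated evidence either way.

`mean_variant_frequency` is the unweighted mean over a transcript's
confident SNPs. Read-weighted averaging was considered and rejected: depth
varies by position for technical reasons (edge effects, mappability), and
weighting by it would let coverage artefacts move an allelic quantity.

## Group comparison

The response is the effective SNP/kb of every gene × sample combination
passing the read gate. The linear model is

    snp_per_kb ~ group * imprinted + sex + sampling_date + library_date

with all factors categorical, covariates as main effects only (five samples
per group cannot support covariate interactions), and Type II sums of
squares — invariant to factor order and robust to the mild unbalance left
by gated genes; users wanting Type I/III can pass `typ`. Factors with a
single observed level are dropped from the formula; a rank-deficient design
raises an error naming the aliased terms rather than silently dropping
them. A constant response returns p = 1 for every term by convention.

Tukey's HSD is applied to the four group × imprinting cell means, because
that is where the scientific question lives: mono-allelic imprinted
expression appears as a depressed imprinted-cell mean *within one group*.
The Tukey adjustment is familywise over the six pairwise contrasts.

Sex is called from counts: a sample is male iff its mean CPM over
user-supplied Y-linked marker genes reaches a threshold (default 1 CPM).
The marker lists are inputs, not constants, since informative X/Y genes
depend on genome annotation.

## Longitudinal DEG comparison

Pure set algebra over two supplied DEG tables (gene, logFC, logCPM, FDR),
one per transition. Significance is FDR < cut, strict; "unique to A" means
significant in A and *not significant* in B — a gene absent from B's table
(typically CPM-filtered before fitting) counts as not significant there and
is flagged `absent_from_B` in the output so both readings stay auditable.
High-confidence subsets re-threshold the unique sets at FDR < 0.01 in their
own table. The CPM filter keeps genes with ≥ 1 CPM in strictly more than
`min_samples` samples, on raw library-size CPM (no TMM; normalisation
belongs to the upstream DEG fit, which this module never re-does).

## The synthetic generator

What it emulates: single-exon diploid transcripts of 1–10 kb; parental
haplotypes differing at Poisson(density · L / 1000) positions, default 1
SNP/kb (between-breed pig crosses observed at 0.4–2 SNP/kb transcript, on
the order of the human ~1-in-300-bp heterozygosity); reads of 100 bp at
~200× mean coverage with uniform (edge-truncated) starts; per-base error
0.5% with truncated-Normal(30, 3) Phred scores clipped to [2, 41] so the
quality filter is exercisable in both directions; ten samples in two groups
of five with balanced sex and two balanced two-level batch factors laid out
to avoid aliasing; imprinted genes mono-allelic (allelic ratio 1.0) in the
configured groups — the study-like default is MT+ only — and everything
else bi-allelic at 0.5.

Heterozygous sites are planted independently per gene *and per sample*:
each embryo has its own parents, so parental heterozygosity is not shared
between samples. This matters statistically — shared sites would make a
gene's response nearly identical across all ten samples and distort the
calibration of the sample-level group test.

Two routes produce data. The read-level route materialises aligned SAM
records against an emitted FASTA reference (the paternal haplotype, so
maternal alleles appear as alternate bases) and is byte-deterministic under
a seed. The pileup-level shortcut draws, at each planted site, depth ~
Poisson(coverage) and alternate reads ~ Binomial(depth, p) with
p = r(1 − e) + (1 − r)e/3 for allelic ratio r and error e — marginally the
same law the read route induces at a site, verified by a goodness-of-fit
cross-check. The shortcut powers multi-seed ANOVA studies (a thousand
simulated studies in minutes on one core). It does not emulate error pileup
at non-heterozygous positions: with ≥10 supporting reads at ≥20% frequency
required, error-only columns cannot reach a call at realistic error rates,
so their omission does not affect any scored quantity.

The expression generator draws negative-binomial counts (dispersion 0.1,
lognormal baseline means) for oocytes and two blastocyst arms, plants
±2.5 log2 fold changes on genes designated unique-to-A, unique-to-B or
common, and fits a deliberately plain per-gene Welch t-test on log2 CPM
with Benjamini–Hochberg correction to produce DEG tables. This fitter
exists to give the set-comparison module truth-labelled inputs with
realistic FDR behaviour; it makes no claim to the moderated-GLM machinery
real analyses use, and real DEG tables are consumed as-is.

What passing tests on synthetic data do **not** show: robustness to
alignment artefacts (multi-mapping, reference bias at variant sites),
splicing, indels, PCR duplication structure, overdispersed allele counts
from bursty transcription, or allelic imbalance short of full
mono-allelicity. The generator is a calibration instrument for the
statistics, not a sequencing emulator.

## Problem sizes and determinism

All simulations are seeded through `numpy.random.default_rng`; identical
configurations give identical outputs, byte-identical for file-writing
paths. The repeated-study checks use 20 imprinted + 20 neighbour genes and
10 samples per study (100 seeds for the imprinting-recovery property, 1000
for the null calibration of the group term; the observed null rejection
rate at α = 0.05 is ~5%), and truth-recovery of the DEG set algebra uses
400-gene tables over 50 seeds — sizes chosen so the full property suite
runs in a couple of minutes on a single core while keeping every Monte
Carlo bound comfortably away from its threshold.

## Known limitations

* No parent-of-origin assignment: without genotypes the method sees
  *whether* both alleles are expressed, never *which* parent's allele is
  silenced.
* Homozygous parents are invisible: SNP/kb conflates mono-allelic
  expression with low parental heterozygosity at the single-gene level;
  only multi-locus, within-sample contrasts are interpretable.
* The ANOVA treats gene × sample observations as exchangeable within
  cells; gene identity is not modelled as a factor (with per-sample
  planting the responses are independent, and the null calibration
  confirms the size of the test under the generator's assumptions, but
  strong shared gene effects in real data would call for a mixed model).
* The site-depth, frequency and count thresholds are sharp; no attempt is
  made to propagate calling uncertainty into the SNP/kb statistic.
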