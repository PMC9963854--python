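# biallelic

Genotype-free allele-specific expression analysis for embryo RNA-seq.

Imprinted genes are expressed predominantly from one parental allele. When
the parental genotypes are unavailable — as for embryos produced from
abattoir-sourced oocytes and commercial sperm — allele-specific expression
can still be read directly from the transcripts: at a heterozygous site, a
bi-allelically expressed gene shows both alleles at roughly 50% of reads,
while a mono-allelically expressed (imprinted) gene shows essentially one
allele, so its heterozygous sites never pass a bi-allelic evidence filter.
Counting the surviving SNPs per kilobase of transcript turns this into a
scalar statistic: **SNP frequency, SNP/kb = 1000 · n_SNPs / L**, low for
mono-allelic and near the parental SNP density for bi-allelic expression.

The package implements that pipeline end to end, plus the longitudinal
differential-expression set comparison used to isolate condition-specific
transition genes, for anyone analysing single-embryo RNA-seq (the motivating
design: *Sus scrofa* blastocysts produced by ICSI with (MT+) or without
(MT−) mitochondrial supplementation, five per group).

## Pipeline

1. **Pileup + variant calling** (`biallelic.pileup`) — per-site base/quality
   tallies from SAM/BAM via pysam, then VarScan-style calls with inclusive
   thresholds: mean alt quality ≥ 20, variant frequency ≥ 1%, ≥ 10
   supporting reads.
2. **Bi-allelic evidence filters** (`biallelic.scoring`) — keep sites with
   depth > 25 and variant frequency in [20%, 80%]; discard transcripts with
   fewer than 3 surviving SNPs (likely amplification/sequencing artefacts);
   gate genes at ≥ 5000 reads summed over all samples; compute SNP/kb per
   transcript and per locus.
3. **Group statistics** (`biallelic.stats`) — sex determination from
   Y-linked marker CPM; factorial ANOVA (Type II) of SNP/kb over
   supplementation group × imprinting status with sex and batch-date
   covariates; Tukey HSD over the four group × status cells.
4. **Longitudinal DEG comparison** (`biallelic.degsets`) — CPM ≥ 1
   filtering, FDR < 0.1 significant sets per transition, common/unique set
   algebra and FDR < 0.01 high-confidence subsets (Venn counts).
5. **Synthetic data** (`biallelic.simulate`) — diploid transcripts with
   Poisson-planted parental SNPs, allele-aware reads (SAM + FASTA) or
   pileup-level shortcuts, and negative-binomial count matrices with
   planted transition fold changes, so the whole chain is testable without
   sequencing archives.

## Worked example

The defining arithmetic: an imprinted-candidate transcript of 7560 bp in
which three confident SNPs survive the filter chain scores

```python
>>> import biallelic as b
>>> round(b.snp_frequency(3, 7560), 2)
0.4
```

0.40 SNP/kb — against, say, 0.92 SNP/kb (27 SNPs / 29,281 bp) for its
non-imprinted neighbours: a mono-allelic signature.

A full synthetic study, with imprinted genes mono-allelic only in the MT+
group:

```python
import biallelic as b
from biallelic.stats import response_table, anova_snp_frequency

cfg = b.SimConfig(n_imprinted_genes=20, n_neighbour_genes=20, seed=1)
ds = b.simulate_allelic_dataset(cfg)
res = anova_snp_frequency(response_table(ds.summaries, ds.meta))
print(res.anova.round(4))
```

```
                         sum_sq     df        F  PR(>F)
C(group)                12.5458    1.0  42.0967  0.0000
C(imprinted)            21.4437    1.0  71.9532  0.0000
C(sex)                   0.3617    1.0   1.2138  0.2713
C(sampling_date)         0.6377    1.0   2.1398  0.1443
C(library_date)          0.8394    1.0   2.8167  0.0941
C(group):C(imprinted)   23.0552    1.0  77.3604  0.0000
Residual               117.1230  393.0      NaN     NaN
```

The group × imprinting interaction is the planted signal. Tukey HSD on the
four cells localises it: the imprinted vs non-imprinted contrast is
significant within MT+ (`res.tukey_p("MT+:imprinted", "MT+:non-imprinted")`
≈ 1e-13, mean difference 0.94 SNP/kb) and not within MT− (p ≈ 0.996),
i.e. mono-allelic imprinted expression is recovered only in the group where
it was simulated.

The same stages are scriptable from the shell via the `biallelic` console
command (`simulate`, `call`, `score`, `stats`, `compare`); see
`biallelic --help`.

## Documentation

`docs/methods.md` describes the model, the filter semantics (which bounds
are strict and why), the simulator's assumptions and limits, and the
numerical choices.
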