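"""Bi-allelic evidence filter chain and transcript/locus SNP-frequency statistics.

The chain, applied to variant calls from a single sample:

1. per-gene depth gate — a gene is analysed only if its read count summed
   over all samples reaches ``min_gene_reads_total`` (default 5000,
   inclusive);
2. per-site filter — keep calls with depth strictly above ``min_site_depth``
   (default 25) and variant frequency inside the inclusive window
   ``[vf_low, vf_high]`` (default 20-80%), the signature of a heterozygous
   site expressed from both alleles;
3. per-transcript filter — transcripts with fewer than
   ``min_snps_per_transcript`` (default 3) surviving SNPs carry no
   trustworthy bi-allelic evidence: such sparse calls are consistent with
   amplification/sequencing artefacts, so the transcript's effective SNP
   frequency is zero.

The summary statistic is SNP frequency: confident SNPs per kb of mature
transcript.  Mono-allelically expressed (imprinted) genes show ~0 SNP/kb
because heterozygous sites read out at ~0% or ~100% variant frequency and
are removed by the 20-80% window; bi-allelic genes show SNP/kb near the
true parental SNP density.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    AllelicFilter,
    GeneModel,
    LocusAggregate,
    TranscriptAllelicSummary,
    VariantCall,
)


def snp_frequency(n_snps: int, transcript_length_bp: int) -> float:
    """SNP frequency in SNPs per kb of transcript: ``1000 * n / L``."""
    if transcript_length_bp <= 0:
        raise ValueError(f"transcript length must be positive, got {transcript_length_bp}")
    if n_snps < 0:
        raise ValueError("SNP count cannot be negative")
    return 1000.0 * n_snps / transcript_length_bp


def gate_gene_depth(
    per_gene_read_counts: Mapping[str, Mapping[str, int]],
    filt: AllelicFilter | None = None,
) -> set[str]:
    """Genes whose reads summed over samples reach the total-read gate (inclusive)."""
    filt = filt or AllelicFilter()
    eligible = set()
    for gene_id, per_sample in per_gene_read_counts.items():
        total = sum(per_sample.values())
        if total < 0:
            raise ValueError(f"{gene_id}: negative read count")
        if total >= filt.min_gene_reads_total:
            eligible.add(gene_id)
    return eligible


def filter_biallelic_snps(
    calls: Iterable[VariantCall], filt: AllelicFilter | None = None
) -> list[VariantCall]:
    """Keep calls with depth > min_site_depth and VF within [vf_low, vf_high]."""
    filt = filt or AllelicFilter()
    return [
        c
        for c in calls
        if c.depth > filt.min_site_depth
        and filt.vf_low <= c.variant_frequency <= filt.vf_high
    ]


def summarize_transcript(
    gene: GeneModel,
    sample_id: str,
    confident_snps: Sequence[VariantCall],
    filt: AllelicFilter | None = None,
) -> TranscriptAllelicSummary:
    """Summarise one transcript in one sample from its confident SNPs.

    ``mean_variant_frequency`` is the unweighted mean over the transcript's
    confident SNPs (0 when there are none).  ``retained`` is true when the
    confident-SNP count reaches ``min_snps_per_transcript``.
    """
    filt = filt or AllelicFilter()
    if gene.transcript_length_bp <= 0:
        raise ValueError(f"{gene.gene_id}: transcript length must be positive")
    for snp in confident_snps:
        if snp.chromosome != gene.chromosome or not (gene.start < snp.position <= gene.end):
            raise ValueError(
                f"SNP {snp.chromosome}:{snp.position} outside gene {gene.gene_id}"
            )
    n = len(confident_snps)
    return TranscriptAllelicSummary(
        gene_id=gene.gene_id,
        sample_id=sample_id,
        n_confident_snps=n,
        transcript_length_bp=gene.transcript_length_bp,
        snp_per_kb=snp_frequency(n, gene.transcript_length_bp),
        mean_variant_frequency=(
            float(np.mean([c.variant_frequency for c in confident_snps])) if n else 0.0
        ),
        retained=n >= filt.min_snps_per_transcript,
        imprinted=gene.imprinted,
        locus_id=gene.locus_id,
    )


def aggregate_locus(
    summaries: Iterable[TranscriptAllelicSummary],
    models: Sequence[GeneModel],
) -> list[LocusAggregate]:
    """Aggregate transcripts per locus x sample x gene class.

    Every analysed member contributes its transcript length, but only
    retained members contribute SNPs — a member whose sparse calls were
    discarded still spans sequence in which no trustworthy SNP was found,
    so its length belongs in the denominator.  The locus SNP frequency is
    recomputed from the totals, not averaged over members.  Locus/class
    combinations with no retained member at all are omitted.
    """
    known = {m.gene_id for m in models}
    buckets: dict[tuple[str, str, str], list[TranscriptAllelicSummary]] = defaultdict(list)
    for s in summaries:
        if s.gene_id not in known:
            raise ValueError(f"summary references unknown gene {s.gene_id}")
        gene_class = "imprinted" if s.imprinted else "non-imprinted"
        buckets[(s.locus_id, s.sample_id, gene_class)].append(s)

    out = []
    for (locus_id, sample_id, gene_class), members in sorted(buckets.items()):
        if not any(m.retained for m in members):
            continue
        total_snps = sum(m.n_confident_snps for m in members if m.retained)
        total_len = sum(m.transcript_length_bp for m in members)
        out.append(
            LocusAggregate(
                locus_id=locus_id,
                sample_id=sample_id,
                gene_class=gene_class,
                total_snps=total_snps,
                total_length_bp=total_len,
                snp_per_kb=snp_frequency(total_snps, total_len),
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[TranscriptAllelicSummary]) -> pd.DataFrame:
    """Long-format table of transcript summaries (one row per gene x sample)."""
    rows = [
        {
            "gene_id": s.gene_id,
            "sample_id": s.sample_id,
            "n_confident_snps": s.n_confident_snps,
            "transcript_length_bp": s.transcript_length_bp,
            "snp_per_kb": s.snp_per_kb,
            "effective_snp_per_kb": s.effective_snp_per_kb,
            "mean_variant_frequency": s.mean_variant_frequency,
            "retained": s.retained,
            "imprinted": s.imprinted,
            "locus_id": s.locus_id,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def aggregates_to_frame(aggregates: Iterable[LocusAggregate]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": a.locus_id,
            "sample_id": a.sample_id,
            "gene_class": a.gene_class,
            "total_snps": a.total_snps,
            "total_length_bp": a.total_length_bp,
            "snp_per_kb": a.snp_per_kb,
        }
        for a in aggregates
    ]
    return pd.DataFrame(rows)
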