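"""Core domain types shared across the pileup, scoring and statistics layers.

Coordinate conventions used throughout the package:

* gene annotations (BED6) are 0-based, half-open ``[start, end)``;
* pileup and variant positions are 1-based, inclusive (the ``samtools
  mpileup`` convention).

The conversion between the two lives in :func:`bed_to_pileup_span` and
nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

#: Canonical base ordering; ties between candidate alternate alleles are
#: broken in this order.
BASES = ("A", "C", "G", "T")


def bed_to_pileup_span(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to a 1-based inclusive span."""
    if end <= start:
        raise ValueError(f"empty or inverted interval [{start}, {end})")
    return start + 1, end


@dataclass(frozen=True)
class GeneModel:
    """A transcript with genomic coordinates and imprinting annotation.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    ``transcript_length_bp`` is the mature (spliced) transcript length; for
    the single-exon models used in simulation it equals ``end - start``.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    transcript_length_bp: int = 0
    imprinted: bool = False
    locus_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        length = self.transcript_length_bp or (self.end - self.start)
        object.__setattr__(self, "transcript_length_bp", length)
        if not (0 < self.transcript_length_bp <= self.end - self.start):
            raise ValueError(
                f"{self.gene_id}: transcript length {self.transcript_length_bp} "
                f"outside (0, {self.end - self.start}]"
            )


@dataclass
class PileupSite:
    """Per-position base and quality tallies from aligned reads.

    ``position`` is 1-based.  ``base_quals`` holds the Phred qualities of the
    reads supporting each base, parallel to ``base_counts``.
    """

    chromosome: str
    position: int
    ref_base: str
    base_counts: Dict[str, int] = field(default_factory=dict)
    base_quals: Dict[str, list] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return int(sum(self.base_counts.values()))

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"pileup position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class VariantCall:
    """A detected non-reference site.

    ``variant_frequency`` is a percentage in [0, 100], computed exactly as
    ``100 * alt_reads / depth`` before any display rounding.
    """

    chromosome: str
    position: int
    ref_base: str
    alt_base: str
    depth: int
    alt_reads: int
    variant_frequency: float
    mean_alt_quality: float

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads cannot exceed depth")
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        if not 0.0 <= self.variant_frequency <= 100.0:
            raise ValueError("variant_frequency must be a percentage in [0, 100]")


@dataclass(frozen=True)
class CallerThresholds:
    """Variant-caller emission thresholds (VarScan-style, all inclusive).

    ``min_var_freq`` is a fraction (0.01 = 1%); variant frequencies on
    emitted calls are percentages.
    """

    min_avg_qual: float = 20.0
    min_var_freq: float = 0.01
    min_reads2: int = 10
    min_base_qual_for_tally: int = 0

    def __post_init__(self) -> None:
        if min(self.min_avg_qual, self.min_var_freq, self.min_reads2, self.min_base_qual_for_tally) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_var_freq <= 1.0:
            raise ValueError("min_var_freq is a fraction in [0, 1]")


@dataclass(frozen=True)
class AllelicFilter:
    """Bi-allelic-evidence filter chain parameters.

    ``min_site_depth`` is a *strict* lower bound (default keeps depth > 25);
    the variant-frequency window ``[vf_low, vf_high]`` is inclusive at both
    ends; the per-gene read gate ``min_gene_reads_total`` (summed over all
    samples) is inclusive.
    """

    min_site_depth: int = 25
    vf_low: float = 20.0
    vf_high: float = 80.0
    min_snps_per_transcript: int = 3
    min_gene_reads_total: int = 5000
    gate_neighbour_genes: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.vf_low < self.vf_high <= 100.0:
            raise ValueError("need 0 <= vf_low < vf_high <= 100")
        if min(self.min_site_depth, self.min_snps_per_transcript, self.min_gene_reads_total) < 0:
            raise ValueError("count thresholds must be non-negative")


@dataclass(frozen=True)
class TranscriptAllelicSummary:
    """Per gene x sample allelic-expression summary.

    ``snp_per_kb`` is ``1000 * n_confident_snps / transcript_length_bp`` at
    full precision.  ``retained`` marks transcripts whose confident-SNP count
    reaches the per-transcript minimum; transcripts below it are treated as
    carrying no trustworthy bi-allelic evidence (their SNPs are plausibly
    amplification or sequencing artefacts), so their effective SNP frequency
    for group statistics is zero.
    """

    gene_id: str
    sample_id: str
    n_confident_snps: int
    transcript_length_bp: int
    snp_per_kb: float
    mean_variant_frequency: float
    retained: bool
    imprinted: bool = False
    locus_id: str = ""

    @property
    def effective_snp_per_kb(self) -> float:
        """SNP frequency entering downstream statistics (0 when not retained)."""
        return self.snp_per_kb if self.retained else 0.0


@dataclass(frozen=True)
class LocusAggregate:
    """Locus-level SNP frequency for one sample and gene class."""

    locus_id: str
    sample_id: str
    gene_class: str  # "imprinted" | "non-imprinted"
    total_snps: int
    total_length_bp: int
    snp_per_kb: float


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata for the factorial comparison.

    Dates are opaque categorical labels, never parsed as time.
    """

    sample_id: str
    group: str
    sex: str = "unknown"
    sampling_date: str = ""
    library_date: str = ""

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group label must be non-empty")


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result."""

    gene_id: str
    log_fc: float
    log_cpm: float
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.gene_id}: FDR {self.fdr} outside [0, 1]")


def truncated_normal_phred(
    rng: np.random.Generator, n: int, mean: float, sd: float = 3.0,
    lo: int = 2, hi: int = 41,
) -> np.ndarray:
    """Draw integer Phred scores from Normal(mean, sd) truncated to [lo, hi]."""
    q = np.rint(rng.normal(mean, sd, size=n))
    return np.clip(q, lo, hi).astype(np.int64)
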