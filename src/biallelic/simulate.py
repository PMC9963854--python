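"""Synthetic data generation: ground-truth diploid transcriptomes and DEG studies.

Two generators live here.

The allelic generator emulates what the allele-specific expression pipeline
consumes: single-exon diploid transcripts whose two parental haplotypes
differ at Poisson-planted heterozygous sites (~0.3-2 SNP/kb), reads drawn
from the maternal haplotype with a configurable allelic ratio (1.0 or 0.0
for mono-allelic imprinted expression, 0.5 for bi-allelic), per-base
sequencing error with truncated-normal Phred qualities, and a ten-sample
two-group design (5 MT- and 5 MT+ blastocysts) with sex and batch
covariates.  Reads can be materialised as aligned SAM records against an
emitted reference, or — for large sweeps — collapsed directly to per-site
pileups, which is distributionally identical at the planted heterozygous
sites (allele counts are Binomial in either route).

The expression generator produces negative-binomial count matrices for an
oocyte group and two blastocyst groups with planted transition
log-fold-changes, fits a plain Welch t-test on log2 CPM with BH correction
to produce the two DEG tables the set-comparison module consumes, and adds
X/Y marker genes so sex can be recovered from counts.

Ground truth (planted sites, true ratios, true DEG classes) is emitted
alongside the data and is never read by the scoring modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import sam_header
from .pileup import call_variants
from .scoring import filter_biallelic_snps, summarize_transcript
from .types import (
    AllelicFilter,
    BASES,
    CallerThresholds,
    GeneModel,
    PileupSite,
    SampleMeta,
    TranscriptAllelicSummary,
    truncated_normal_phred,
)

#: Locus topology emulated by the generator: six imprinting loci spread over
#: four chromosomes, each holding one or more imprinted genes plus
#: non-imprinted neighbours.
LOCUS_CHROMOSOMES = ("chr1", "chr1", "chr6", "chr6", "chr9", "chr14")


@dataclass(frozen=True)
class SimConfig:
    """Conditions of the simulated blastocyst allelic-expression study.

    Defaults reproduce the study design: 5 samples per group (MT- and MT+),
    10 imprinted and 73 neighbour genes over six loci, transcripts of
    1-10 kb, parental heterozygosity of 1 SNP/kb (within the 0.4-2 SNP/kb
    range transcripts show when parents differ at roughly the human one-in-
    300-bp scale), imprinted genes fully mono-allelic, bi-allelic genes at
    a 50/50 allelic ratio, ~200x coverage of 100 bp reads with 0.5% per-base
    error around Phred 30.
    """

    n_samples_per_group: int = 5
    n_imprinted_genes: int = 10
    n_neighbour_genes: int = 73
    transcript_len_range: tuple[int, int] = (1000, 10000)
    parental_snp_density: float = 1.0
    allelic_ratio_imprinted: float = 1.0
    allelic_ratio_biallelic: float = 0.5
    mean_coverage: float = 200.0
    read_len: int = 100
    base_error_rate: float = 0.005
    base_quality_mean: float = 30.0
    #: groups whose imprinted genes are mono-allelic; the study-like default
    #: is mono-allelic imprinting in MT+ only (MT- imprinted genes behave
    #: bi-allelically).  Use ("MT-", "MT+") for canonical imprinting in both
    #: groups, or () for an all-bi-allelic null.
    mono_allelic_groups: tuple[str, ...] = ("MT+",)
    batch_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group <= 0:
            raise ValueError("n_samples_per_group must be positive")
        if self.n_imprinted_genes < 0 or self.n_neighbour_genes < 0:
            raise ValueError("gene counts cannot be negative")
        if self.n_imprinted_genes + self.n_neighbour_genes == 0:
            raise ValueError("need at least one gene")
        lo, hi = self.transcript_len_range
        if not 0 < lo <= hi:
            raise ValueError("invalid transcript length range")
        if self.read_len <= 0 or self.mean_coverage <= 0:
            raise ValueError("read_len and mean_coverage must be positive")
        for r in (self.allelic_ratio_imprinted, self.allelic_ratio_biallelic):
            if not 0.0 <= r <= 1.0:
                raise ValueError("allelic ratios must lie in [0, 1]")
        if not 0.0 <= self.base_error_rate <= 0.1:
            raise ValueError("base_error_rate must lie in [0, 0.1]")
        if self.parental_snp_density < 0:
            raise ValueError("parental_snp_density cannot be negative")


@dataclass(frozen=True)
class HaplotypePair:
    """Two parental transcript sequences and their differing positions.

    Positions are 0-based transcript coordinates.  The paternal haplotype
    doubles as the alignment reference, so maternal-only reads produce ~100%
    variant frequency at planted sites and 50/50 mixtures produce ~50%.
    """

    maternal: str
    paternal: str
    het_positions: tuple[int, ...]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def make_gene_models(config: SimConfig) -> list[GeneModel]:
    """Lay out imprinted and neighbour genes across six loci on four chromosomes.

    Genes are single-exon (mature transcript length equals genomic span)
    and placed sequentially with fixed 10 kb spacers; the layout is a pure
    function of the config, so identical configs give identical models.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.transcript_len_range
    n_total = config.n_imprinted_genes + config.n_neighbour_genes
    lengths = rng.integers(lo, hi + 1, size=n_total)

    n_loci = min(len(LOCUS_CHROMOSOMES), max(config.n_imprinted_genes, 1))
    offsets: Dict[str, int] = {}
    models: list[GeneModel] = []
    for i in range(n_total):
        imprinted = i < config.n_imprinted_genes
        if imprinted:
            gene_id = f"IMP{i + 1:03d}"
            locus = i % n_loci
        else:
            j = i - config.n_imprinted_genes
            gene_id = f"NBR{j + 1:03d}"
            locus = j % n_loci
        chrom = LOCUS_CHROMOSOMES[locus]
        start = offsets.get(chrom, 0)
        length = int(lengths[i])
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=chrom,
                start=start,
                end=start + length,
                strand="+" if i % 2 == 0 else "-",
                transcript_length_bp=length,
                imprinted=imprinted,
                locus_id=f"locus{locus + 1}",
            )
        )
        offsets[chrom] = start + length + 10_000
    return models


def plant_parental_snps(
    model: GeneModel,
    density: float,
    rng: np.random.Generator | int,
) -> HaplotypePair:
    """Draw a haplotype pair differing at Poisson(density * L / 1000) sites."""
    if density < 0:
        raise ValueError("SNP density cannot be negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    length = model.transcript_length_bp
    paternal = _random_sequence(rng, length)
    n_sites = min(int(rng.poisson(density * length / 1000.0)), length)
    positions = np.sort(rng.choice(length, size=n_sites, replace=False))
    maternal = paternal.copy()
    # substitute a uniformly chosen different base at each het site
    maternal[positions] = (maternal[positions] + rng.integers(1, 4, size=n_sites)) % 4
    to_str = np.array(list("ACGT"))
    return HaplotypePair(
        maternal="".join(to_str[maternal]),
        paternal="".join(to_str[paternal]),
        het_positions=tuple(int(p) for p in positions),
    )


_COMPLEMENTARY_OFFSETS = None


def simulate_reads(
    haplotypes: HaplotypePair,
    allelic_ratio: float,
    config: SimConfig,
    rng: np.random.Generator | int,
    reference_name: str = "ref",
) -> list[pysam.AlignedSegment]:
    """Draw aligned reads from the two haplotypes.

    Each read comes from the maternal haplotype with probability
    ``allelic_ratio``, starts uniformly along the transcript
    (edge-truncated), has every base flipped to a random different base
    with probability ``base_error_rate``, and carries truncated-normal
    Phred qualities.  Reads are full-length matches (``<read_len>M``)
    against the paternal-haplotype reference.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    length = len(haplotypes.paternal)
    if config.read_len > length:
        raise ValueError(f"read length {config.read_len} exceeds transcript length {length}")
    n_reads = max(1, round(config.mean_coverage * length / config.read_len))
    starts = rng.integers(0, length - config.read_len + 1, size=n_reads)
    from_maternal = rng.random(n_reads) < allelic_ratio

    base_to_int = {b: i for i, b in enumerate(BASES)}
    mat = np.array([base_to_int[b] for b in haplotypes.maternal], dtype=np.int8)
    pat = np.array([base_to_int[b] for b in haplotypes.paternal], dtype=np.int8)
    to_str = np.array(list("ACGT"))

    header = sam_header({reference_name: length})
    reads = []
    for i in range(n_reads):
        start = int(starts[i])
        source = mat if from_maternal[i] else pat
        bases = source[start : start + config.read_len].copy()
        if config.base_error_rate > 0:
            err = rng.random(config.read_len) < config.base_error_rate
            n_err = int(err.sum())
            if n_err:
                bases[err] = (bases[err] + rng.integers(1, 4, size=n_err)) % 4
        quals = truncated_normal_phred(rng, config.read_len, config.base_quality_mean)
        seg = pysam.AlignedSegment(header)
        seg.query_name = f"r{i:06d}"
        seg.flag = 0
        seg.reference_name = reference_name
        seg.reference_start = start
        seg.mapping_quality = 60
        seg.cigarstring = f"{config.read_len}M"
        seg.query_sequence = "".join(to_str[bases])
        seg.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in quals)
        )
        reads.append(seg)
    return reads


def simulate_het_site_pileups(
    model: GeneModel,
    n_sites: int,
    allelic_ratio: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[PileupSite]:
    """Collapse read simulation to pileups at planted heterozygous sites.

    At a heterozygous site covered at depth ``d``, the alternate (maternal)
    allele count is Binomial(d, p) with
    ``p = r * (1 - e) + (1 - r) * e / 3`` for allelic ratio ``r`` and
    per-base error ``e`` — identical to the read-level route marginally,
    without materialising reads.  Site depths are Poisson(mean_coverage).
    Error pileup at non-heterozygous positions is not emulated: with the
    default caller thresholds (>=10 supporting reads at >=20% frequency)
    such sites cannot reach a variant call at realistic error rates.
    """
    length = model.transcript_length_bp
    n_sites = min(n_sites, length)
    positions = np.sort(rng.choice(length, size=n_sites, replace=False))
    p_alt = allelic_ratio * (1.0 - config.base_error_rate) + (
        1.0 - allelic_ratio
    ) * config.base_error_rate / 3.0
    depths = rng.poisson(config.mean_coverage, size=n_sites)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

    sites = []
    for k in range(n_sites):
        depth = int(depths[k])
        if depth == 0:
            continue
        alt_n = int(rng.binomial(depth, p_alt))
        ref_base = BASES[ref_idx[k]]
        alt_base = BASES[alt_idx[k]]
        counts = {ref_base: depth - alt_n}
        quals: Dict[str, list] = {}
        if alt_n:
            counts[alt_base] = alt_n
            quals[alt_base] = truncated_normal_phred(
                rng, alt_n, config.base_quality_mean
            ).tolist()
        sites.append(
            PileupSite(
                chromosome=model.chromosome,
                position=model.start + int(positions[k]) + 1,
                ref_base=ref_base,
                base_counts=counts,
                base_quals=quals,
            )
        )
    return sites


def make_sample_meta(config: SimConfig) -> list[SampleMeta]:
    """Ten-sample (default) two-group design with balanced covariates.

    Sex and the two batch factors (sampling date, library date) are laid
    out in fixed balanced patterns chosen to avoid aliasing with the group
    factor or each other.
    """
    n = config.n_samples_per_group
    sexes = ["M", "F"]
    sampling = ["d1", "d1", "d2", "d2"]
    library = ["L1", "L2", "L2", "L1"]
    meta = []
    for g, group in enumerate(("MT-", "MT+")):
        for i in range(n):
            k = g * n + i
            meta.append(
                SampleMeta(
                    sample_id=f"B{k + 1:02d}",
                    group=group,
                    sex=sexes[(i + g) % 2],
                    sampling_date=sampling[k % 4],
                    library_date=library[k % 4],
                )
            )
    return meta


@dataclass
class AllelicDataset:
    """A simulated study: models, metadata, summaries, and ground truth."""

    config: SimConfig
    models: list[GeneModel]
    meta: list[SampleMeta]
    summaries: list[TranscriptAllelicSummary]
    gene_read_counts: Dict[str, Dict[str, int]]
    truth: pd.DataFrame = field(repr=False)

    @property
    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.meta],
                "group": [m.group for m in self.meta],
                "sex": [m.sex for m in self.meta],
                "sampling_date": [m.sampling_date for m in self.meta],
                "library_date": [m.library_date for m in self.meta],
            }
        )


def simulate_allelic_dataset(
    config: SimConfig,
    thresholds: CallerThresholds | None = None,
    allelic_filter: AllelicFilter | None = None,
) -> AllelicDataset:
    """Run the generator and the scoring chain end to end at pileup level.

    Heterozygous sites are planted independently per gene and per sample:
    each blastocyst arises from its own pair of parents (abattoir oocytes
    fertilised with commercial sperm), so parental heterozygosity is not
    shared between embryos.  The per-site pileups feed the package's own
    caller and filter chain; ground truth is returned separately and never
    consumed by scoring.
    """
    thresholds = thresholds or CallerThresholds()
    allelic_filter = allelic_filter or AllelicFilter()
    rng = np.random.default_rng(config.seed)
    models = make_gene_models(config)
    meta = make_sample_meta(config)

    batch_mult = {"d1": 1.0, "d2": 1.0}
    if config.batch_effect_sd > 0:
        batch_mult = {
            "d1": float(np.exp(rng.normal(0.0, config.batch_effect_sd))),
            "d2": float(np.exp(rng.normal(0.0, config.batch_effect_sd))),
        }

    summaries = []
    truth_rows = []
    gene_read_counts: Dict[str, Dict[str, int]] = {}
    for model in models:
        n_reads = round(config.mean_coverage * model.transcript_length_bp / config.read_len)
        gene_read_counts[model.gene_id] = {m.sample_id: n_reads for m in meta}
        for sample in meta:
            mono = model.imprinted and sample.group in config.mono_allelic_groups
            ratio = (
                config.allelic_ratio_imprinted if mono else config.allelic_ratio_biallelic
            )
            density = config.parental_snp_density * batch_mult[sample.sampling_date]
            n_sites = int(rng.poisson(density * model.transcript_length_bp / 1000.0))
            sites = simulate_het_site_pileups(model, n_sites, ratio, config, rng)
            calls = call_variants(sites, thresholds)
            confident = filter_biallelic_snps(calls, allelic_filter)
            summaries.append(
                summarize_transcript(model, sample.sample_id, confident, allelic_filter)
            )
            truth_rows.append(
                {
                    "gene_id": model.gene_id,
                    "sample_id": sample.sample_id,
                    "true_allelic_ratio": ratio,
                    "n_planted_sites": n_sites,
                    "mono_allelic": mono,
                }
            )
    return AllelicDataset(
        config=config,
        models=models,
        meta=meta,
        summaries=summaries,
        gene_read_counts=gene_read_counts,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Expression study: counts and DEG tables for the longitudinal comparison


@dataclass(frozen=True)
class DEGSimConfig:
    """Conditions of the simulated oocyte-to-blastocyst expression study.

    Defaults: 5 oocytes plus 5 blastocysts per arm, 2000 genes with
    negative-binomial counts (dispersion 0.1) around lognormal baseline
    means, transition log2 fold changes of +/-2.5 planted on genes unique
    to one transition or common to both, and three Y- and X-linked marker
    genes (~50 CPM in males) for sex determination.
    """

    n_oocytes: int = 5
    n_blast_per_group: int = 5
    n_genes: int = 2000
    n_unique_a: int = 30
    n_unique_b: int = 30
    n_common: int = 60
    log_fc: float = 2.5
    dispersion: float = 0.1
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.0
    y_marker_cpm: float = 50.0
    n_y_markers: int = 3
    n_x_markers: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_oocytes, self.n_blast_per_group, self.n_genes) <= 0:
            raise ValueError("sample and gene counts must be positive")
        if self.n_unique_a + self.n_unique_b + self.n_common > self.n_genes:
            raise ValueError("more planted effects than genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class DEGStudy:
    """Simulated counts, fitted DEG tables, and ground-truth labels."""

    config: DEGSimConfig
    counts: pd.DataFrame
    meta: pd.DataFrame
    deg_a: pd.DataFrame  # oocyte -> MT- blastocyst transition
    deg_b: pd.DataFrame  # oocyte -> MT+ blastocyst transition
    truth: pd.Series  # gene -> {unique_to_A, unique_to_B, common, null, marker}
    y_markers: list[str]
    x_markers: list[str]


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def fit_deg_table(
    counts: pd.DataFrame,
    baseline_samples: Sequence[str],
    contrast_samples: Sequence[str],
) -> pd.DataFrame:
    """Plain per-gene differential expression: Welch t on log2 CPM, BH FDR.

    This is the package's lightweight DEG fitter for synthetic studies; it
    is not a reimplementation of the moderated GLM machinery real analyses
    use, and real DEG tables are consumed as-is by the set-comparison
    module.
    """
    lib = counts.sum(axis=0)
    log_cpm = np.log2(counts * 1e6 / lib + 1.0)
    a = log_cpm[list(baseline_samples)].to_numpy()
    b = log_cpm[list(contrast_samples)].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "logFC": b.mean(axis=1) - a.mean(axis=1),
            "logCPM": log_cpm.mean(axis=1),
            "FDR": fdr,
        }
    ).reset_index(drop=True)


def simulate_counts_and_degs(config: DEGSimConfig) -> DEGStudy:
    """Simulate the three-group expression study and fit both transitions."""
    rng = np.random.default_rng(config.seed)

    oocytes = [f"OO{i + 1:02d}" for i in range(config.n_oocytes)]
    blast_a = [f"BA{i + 1:02d}" for i in range(config.n_blast_per_group)]
    blast_b = [f"BB{i + 1:02d}" for i in range(config.n_blast_per_group)]
    samples = oocytes + blast_a + blast_b
    stage = ["oocyte"] * len(oocytes) + ["blastocyst"] * (len(blast_a) + len(blast_b))
    group = ["oocyte"] * len(oocytes) + ["MT-"] * len(blast_a) + ["MT+"] * len(blast_b)
    # single oocytes carry no Y; blastocysts alternate male/female
    sex = ["F"] * len(oocytes) + ["M", "F"] * ((len(blast_a) + len(blast_b) + 1) // 2)
    sex = sex[: len(samples)]

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    labels = np.array(["null"] * config.n_genes, dtype=object)
    idx = rng.permutation(config.n_genes)
    a_idx = idx[: config.n_unique_a]
    b_idx = idx[config.n_unique_a : config.n_unique_a + config.n_unique_b]
    c_idx = idx[
        config.n_unique_a + config.n_unique_b
        : config.n_unique_a + config.n_unique_b + config.n_common
    ]
    labels[a_idx] = "unique_to_A"
    labels[b_idx] = "unique_to_B"
    labels[c_idx] = "common"

    base_mu = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)
    )
    signs = rng.choice([-1.0, 1.0], size=config.n_genes)
    shift = 2.0 ** (signs * config.log_fc)

    mu_a = base_mu.copy()
    mu_b = base_mu.copy()
    for i in np.concatenate([a_idx, c_idx]):
        mu_a[i] = base_mu[i] * shift[i]
    for i in np.concatenate([b_idx, c_idx]):
        mu_b[i] = base_mu[i] * shift[i]

    cols = {}
    for s in oocytes:
        cols[s] = _nb_counts(rng, base_mu, config.dispersion)
    for s in blast_a:
        cols[s] = _nb_counts(rng, mu_a, config.dispersion)
    for s in blast_b:
        cols[s] = _nb_counts(rng, mu_b, config.dispersion)
    counts = pd.DataFrame(cols, index=genes)

    # sex marker genes: Y markers silent in females, X markers in everyone
    y_markers = [f"YMARK{i + 1}" for i in range(config.n_y_markers)]
    x_markers = [f"XMARK{i + 1}" for i in range(config.n_x_markers)]
    lib = counts.sum(axis=0)
    marker_rows = {}
    for m in y_markers:
        marker_rows[m] = [
            rng.poisson(config.y_marker_cpm * lib[s] / 1e6) if sx == "M" else 0
            for s, sx in zip(samples, sex)
        ]
    for m in x_markers:
        marker_rows[m] = [rng.poisson(config.y_marker_cpm * lib[s] / 1e6) for s in samples]
    markers = pd.DataFrame(marker_rows, index=samples).T
    counts = pd.concat([counts, markers])

    deg_a = fit_deg_table(counts, oocytes, blast_a)
    deg_b = fit_deg_table(counts, oocytes, blast_b)

    truth = pd.Series(
        list(labels) + ["marker"] * (len(y_markers) + len(x_markers)),
        index=genes + y_markers + x_markers,
        name="truth",
    )
    meta = pd.DataFrame(
        {"sample_id": samples, "stage": stage, "group": group, "sex": sex}
    )
    return DEGStudy(
        config=config,
        counts=counts,
        meta=meta,
        deg_a=deg_a,
        deg_b=deg_b,
        truth=truth,
        y_markers=y_markers,
        x_markers=x_markers,
    )
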