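import numpy as np
import pytest

from biallelic.types import GeneModel, PileupSite


@pytest.fixture
def rng():
    return np.random.default_rng(20230214)


def make_site(
    ref_counts=0,
    alt_counts=0,
    ref_base="A",
    alt_base="G",
    alt_qual=30,
    position=100,
    chromosome="chr1",
):
    """A pileup site with uniform alternate-base qualities."""
    counts, quals = {}, {}
    if ref_counts:
        counts[ref_base] = ref_counts
        quals[ref_base] = [alt_qual] * ref_counts
    if alt_counts:
        counts[alt_base] = alt_counts
        quals[alt_base] = [alt_qual] * alt_counts
    return PileupSite(
        chromosome=chromosome,
        position=position,
        ref_base=ref_base,
        base_counts=counts,
        base_quals=quals,
    )


def make_gene(gene_id="G1", length=1000, imprinted=False, locus_id="locus1", chromosome="chr1", start=0):
    return GeneModel(
        gene_id=gene_id,
        chromosome=chromosome,
        start=start,
        end=start + length,
        transcript_length_bp=length,
        imprinted=imprinted,
        locus_id=locus_id,
    )
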