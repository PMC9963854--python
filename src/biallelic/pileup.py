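"""Per-site base tallies from aligned reads and VarScan-style variant calls.

The pileup walks each primary alignment's CIGAR through pysam's aligned
pairs, so insertions and deletions contribute nothing to the tallies and
only aligned matches are counted.  All caller thresholds are inclusive
(>=), reproducing the documented semantics of the VarScan options
``--min-avg-qual`` / ``--min-var-freq`` / ``--min-reads2``.  No duplicate
removal is performed: whole-transcriptome-amplified single-embryo libraries
would lose genuine allele counts to dedup.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .io import VARIANT_COLUMNS
from .types import BASES, CallerThresholds, GeneModel, PileupSite, VariantCall

logger = logging.getLogger(__name__)


def _iter_region_reads(
    reads: Iterable[pysam.AlignedSegment], region: GeneModel
) -> Iterable[pysam.AlignedSegment]:
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.reference_name != region.chromosome:
            continue
        if read.reference_end is None or read.reference_start is None:
            continue
        if read.reference_end <= region.start or read.reference_start >= region.end:
            continue
        yield read


def pileup(
    reads: str | os.PathLike | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    region: GeneModel,
    reference: Mapping[str, str],
    min_base_quality: int = 0,
) -> list[PileupSite]:
    """Tally bases per covered position of ``region``.

    ``reads`` may be a SAM/BAM path, an open ``AlignmentFile``, or any
    iterable of aligned segments.  ``reference`` maps chromosome name to
    sequence and supplies the reference base at each site.  Returns one
    :class:`PileupSite` per covered position, ascending, 1-based.
    """
    close_after = False
    if isinstance(reads, (str, os.PathLike)):
        reads = pysam.AlignmentFile(str(reads), check_sq=False)
        close_after = True
    if isinstance(reads, pysam.AlignmentFile):
        names = set(reads.references or ())
        if names and region.chromosome not in names:
            if close_after:
                reads.close()
            raise ValueError(f"chromosome {region.chromosome!r} absent from alignment header")
        stream = reads.fetch(until_eof=True)
        handle = reads
    else:
        stream = iter(reads)
        handle = None

    if region.chromosome not in reference:
        raise ValueError(f"chromosome {region.chromosome!r} absent from reference")
    ref_seq = reference[region.chromosome]

    counts: dict[int, dict[str, int]] = {}
    quals: dict[int, dict[str, list]] = {}
    try:
        for read in _iter_region_reads(stream, region):
            try:
                pairs = read.get_aligned_pairs(matches_only=True)
            except (ValueError, SystemError) as exc:  # malformed CIGAR
                logger.warning("skipping read %s: %s", read.query_name, exc)
                continue
            seq = read.query_sequence
            qual = read.query_qualities
            if seq is None:
                logger.warning("skipping read %s: no sequence", read.query_name)
                continue
            for qpos, rpos in pairs:
                if rpos < region.start or rpos >= region.end:
                    continue
                base = seq[qpos].upper()
                q = 0 if qual is None else qual[qpos]
                if q < min_base_quality:
                    continue
                site_counts = counts.setdefault(rpos, {})
                site_counts[base] = site_counts.get(base, 0) + 1
                quals.setdefault(rpos, {}).setdefault(base, []).append(int(q))
    finally:
        if close_after and handle is not None:
            handle.close()

    sites = []
    for rpos in sorted(counts):
        sites.append(
            PileupSite(
                chromosome=region.chromosome,
                position=rpos + 1,
                ref_base=ref_seq[rpos].upper() if rpos < len(ref_seq) else "N",
                base_counts=counts[rpos],
                base_quals=quals[rpos],
            )
        )
    return sites


def call_variants(
    sites: Sequence[PileupSite], thresholds: CallerThresholds | None = None
) -> list[VariantCall]:
    """Emit the most frequent non-reference base at each qualifying site.

    A call is emitted iff all three inclusive thresholds hold:
    ``alt_reads >= min_reads2``, ``alt_reads / depth >= min_var_freq`` and
    mean Phred quality of the alt-supporting bases ``>= min_avg_qual``.
    Candidate alternate bases tie-break in A < C < G < T order; only the
    single most frequent non-reference base is considered (sites are treated
    as bi-allelic SNPs).
    """
    thr = thresholds or CallerThresholds()
    calls = []
    for site in sites:
        depth = site.depth
        if depth == 0:
            continue
        best_base, best_count = None, 0
        for base in BASES:
            if base == site.ref_base:
                continue
            count = site.base_counts.get(base, 0)
            if count > best_count:
                best_base, best_count = base, count
        if best_base is None or best_count == 0:
            continue
        if best_count < thr.min_reads2:
            continue
        if best_count / depth < thr.min_var_freq:
            continue
        mean_qual = float(np.mean(site.base_quals.get(best_base, [0])))
        if mean_qual < thr.min_avg_qual:
            continue
        calls.append(
            VariantCall(
                chromosome=site.chromosome,
                position=site.position,
                ref_base=site.ref_base,
                alt_base=best_base,
                depth=depth,
                alt_reads=best_count,
                variant_frequency=100.0 * best_count / depth,
                mean_alt_quality=mean_qual,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Variant table I/O

def variants_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chromosome, c.position, c.ref_base, c.alt_base,
             c.depth, c.alt_reads, c.variant_frequency, c.mean_alt_quality)
            for c in calls
        ],
        columns=VARIANT_COLUMNS,
    )


def write_variant_tsv(calls: Sequence[VariantCall], path: str | os.PathLike) -> None:
    variants_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_variant_tsv(path: str | os.PathLike) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return [
        VariantCall(
            chromosome=row.chromosome,
            position=int(row.position),
            ref_base=row.ref_base,
            alt_base=row.alt_base,
            depth=int(row.depth),
            alt_reads=int(row.alt_reads),
            variant_frequency=float(row.variant_frequency),
            mean_alt_quality=float(row.mean_alt_quality),
        )
        for row in df.itertuples(index=False)
    ]


def write_vcf(
    calls: Sequence[VariantCall], path: str | os.PathLike, reference_name: str = "ref"
) -> None:
    """Write calls as a minimal VCF 4.2 with DP/AD/FREQ in the INFO field."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##reference={reference_name}\n")
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting reads">\n')
        out.write('##INFO=<ID=FREQ,Number=1,Type=Float,Description="Variant frequency (%)">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = f"DP={c.depth};AD={c.alt_reads};FREQ={c.variant_frequency:.2f}"
            out.write(
                f"{c.chromosome}\t{c.position}\t.\t{c.ref_base}\t{c.alt_base}\t"
                f"{c.mean_alt_quality:.0f}\tPASS\t{info}\n"
            )
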