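"""Readers and writers for the package's on-disk interchange formats.

Standard formats go through standard libraries: FASTA through Biopython,
SAM/BAM through pysam, tabular files through pandas.  BED6 is 0-based
half-open; the imprinting annotation (gene_id, imprinted, locus_id,
transcript_length_bp) is a separate TSV so the BED stays standard.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GeneModel

VARIANT_COLUMNS = [
    "chromosome", "position", "ref_base", "alt_base",
    "depth", "alt_reads", "variant_frequency", "mean_alt_quality",
]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# SAM

def sam_header(references: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": int(length)} for name, length in references.items()],
        }
    )


def write_sam(
    path: str | os.PathLike,
    references: Mapping[str, int],
    reads: Iterable[pysam.AlignedSegment],
) -> None:
    """Write coordinate-sorted reads to a SAM file."""
    header = sam_header(references)
    ordered = sorted(reads, key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in ordered:
            out.write(read)


# ---------------------------------------------------------------------------
# Gene annotation: BED6 + imprinting TSV

def write_bed6(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    rows = [
        (m.chromosome, m.start, m.end, m.gene_id, 0, m.strand)
        for m in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_imprint_table(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "imprinted": [int(m.imprinted) for m in models],
            "locus_id": [m.locus_id for m in models],
            "transcript_length_bp": [m.transcript_length_bp for m in models],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(bed_path: str | os.PathLike, imprint_path: str | os.PathLike) -> list[GeneModel]:
    """Join a BED6 annotation with its imprinting TSV into GeneModel objects."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chromosome", "start", "end", "gene_id", "score", "strand"],
        dtype={"chromosome": str, "gene_id": str},
    )
    imp = pd.read_csv(imprint_path, sep="\t", dtype={"gene_id": str, "locus_id": str})
    merged = bed.merge(imp, on="gene_id", how="left", validate="one_to_one")
    models = []
    for row in merged.itertuples(index=False):
        models.append(
            GeneModel(
                gene_id=row.gene_id,
                chromosome=row.chromosome,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                transcript_length_bp=int(row.transcript_length_bp),
                imprinted=bool(row.imprinted),
                locus_id=str(row.locus_id),
            )
        )
    return models


# ---------------------------------------------------------------------------
# Generic TSV helpers

def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_deg_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a DEG table with columns gene_id/logFC/logCPM/FDR."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "logFC", "logCPM", "FDR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table {path} missing columns: {sorted(missing)}")
    return df


def read_sample_meta(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("sample metadata needs at least sample_id and group columns")
    return df
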