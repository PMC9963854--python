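"""Longitudinal DEG set comparison: CPM filtering and transition set algebra.

Two differential-expression tables — one per oocyte-to-blastocyst
transition — are intersected and differenced on their significant gene
sets.  "Unique to A" means significant in table A (FDR below the cut,
strict) and not significant in table B at the same cut; genes absent from
one table (e.g. filtered out before fitting) count as not significant
there and are flagged.  No fold changes or FDRs are recomputed here: the
module is pure set algebra over supplied tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .types import DEGRecord


def cpm_filter(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 4
) -> list[str]:
    """Genes with >= ``min_cpm`` CPM in strictly more than ``min_samples`` samples."""
    if counts.empty:
        raise ValueError("empty count matrix")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = counts * 1e6 / lib
    keep = (cpm >= min_cpm).sum(axis=1) > min_samples
    return list(counts.index[keep])


def _as_fdr_map(table: Iterable[DEGRecord] | pd.DataFrame) -> dict[str, float]:
    if isinstance(table, pd.DataFrame):
        if table.empty:
            return {}
        ids = table["gene_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate gene ids in DEG table: {dupes[:5]}")
        return dict(zip(ids, table["FDR"].astype(float)))
    out: dict[str, float] = {}
    for rec in table:
        if rec.gene_id in out:
            raise ValueError(f"duplicate gene id in DEG table: {rec.gene_id}")
        out[rec.gene_id] = rec.fdr
    return out


def threshold_degs(
    table: Iterable[DEGRecord] | pd.DataFrame, fdr_cut: float
) -> set[str]:
    """Genes with FDR strictly below the cut."""
    return {gene for gene, fdr in _as_fdr_map(table).items() if fdr < fdr_cut}


@dataclass(frozen=True)
class TransitionComparison:
    """Common/unique significant gene sets for two transitions.

    The three primary sets are pairwise disjoint; the high-confidence sets
    (stricter FDR within the unique set's own table) are subsets of their
    unique sets.
    """

    common: frozenset[str]
    unique_to_a: frozenset[str]
    unique_to_b: frozenset[str]
    high_conf_unique_a: frozenset[str]
    high_conf_unique_b: frozenset[str]

    def __post_init__(self) -> None:
        if self.common & self.unique_to_a or self.common & self.unique_to_b \
                or self.unique_to_a & self.unique_to_b:
            raise ValueError("primary sets must be pairwise disjoint")
        if not self.high_conf_unique_a <= self.unique_to_a:
            raise ValueError("high-confidence A set must be within unique-to-A")
        if not self.high_conf_unique_b <= self.unique_to_b:
            raise ValueError("high-confidence B set must be within unique-to-B")


def compare_transitions(
    degs_a: Iterable[DEGRecord] | pd.DataFrame,
    degs_b: Iterable[DEGRecord] | pd.DataFrame,
    fdr_cut: float = 0.1,
    high_conf_cut: float = 0.01,
) -> TransitionComparison:
    """Build the common/unique/high-confidence sets from two DEG tables."""
    fdr_a = _as_fdr_map(degs_a)
    fdr_b = _as_fdr_map(degs_b)
    sig_a = {g for g, f in fdr_a.items() if f < fdr_cut}
    sig_b = {g for g, f in fdr_b.items() if f < fdr_cut}
    unique_a = sig_a - sig_b
    unique_b = sig_b - sig_a
    return TransitionComparison(
        common=frozenset(sig_a & sig_b),
        unique_to_a=frozenset(unique_a),
        unique_to_b=frozenset(unique_b),
        high_conf_unique_a=frozenset(g for g in unique_a if fdr_a[g] < high_conf_cut),
        high_conf_unique_b=frozenset(g for g in unique_b if fdr_b[g] < high_conf_cut),
    )


def venn_counts(cmp: TransitionComparison) -> dict[str, int]:
    """Sizes of the five sets, ready for Venn rendering."""
    return {
        "common": len(cmp.common),
        "unique_to_A": len(cmp.unique_to_a),
        "unique_to_B": len(cmp.unique_to_b),
        "high_conf_unique_A": len(cmp.high_conf_unique_a),
        "high_conf_unique_B": len(cmp.high_conf_unique_b),
    }


def comparison_table(
    degs_a: Iterable[DEGRecord] | pd.DataFrame,
    degs_b: Iterable[DEGRecord] | pd.DataFrame,
    cmp: TransitionComparison,
) -> pd.DataFrame:
    """Per-gene membership table with a flag for genes absent from one table."""
    fdr_a = _as_fdr_map(degs_a)
    fdr_b = _as_fdr_map(degs_b)
    rows = []
    for gene in sorted(cmp.common | cmp.unique_to_a | cmp.unique_to_b):
        if gene in cmp.common:
            membership = "common"
        elif gene in cmp.unique_to_a:
            membership = "unique_A"
        else:
            membership = "unique_B"
        flag = ""
        if gene not in fdr_a:
            flag = "absent_from_A"
        elif gene not in fdr_b:
            flag = "absent_from_B"
        rows.append(
            {
                "gene_id": gene,
                "membership": membership,
                "fdr_A": fdr_a.get(gene, float("nan")),
                "fdr_B": fdr_b.get(gene, float("nan")),
                "high_confidence": gene in (cmp.high_conf_unique_a | cmp.high_conf_unique_b),
                "flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "membership", "fdr_A", "fdr_B", "high_confidence", "flag"],
    )
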