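"""Sex determination from marker counts and the factorial SNP-frequency ANOVA.

The group comparison models transcript SNP frequency (SNP/kb) as a linear
function of supplementation group, imprinting status, their interaction,
and categorical covariates (sex, sampling date, library date), using Type II
sums of squares — robust to the mild unbalance left by dropped transcripts.
Tukey's HSD is then applied to the four group x imprinting cell means, which
is where the biological contrast of interest lives: mono-allelic imprinted
expression shows up as a depressed imprinted-cell mean within one group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .types import SampleMeta, TranscriptAllelicSummary

COVARIATES = ("sex", "sampling_date", "library_date")


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million mapped reads, per sample (column)."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e6 / lib


def determine_sex(
    counts: pd.DataFrame,
    x_genes: Sequence[str],
    y_genes: Sequence[str],
    threshold: float = 1.0,
) -> dict[str, str]:
    """Classify each sample as male iff mean Y-marker CPM reaches ``threshold``.

    X markers are accepted for interface symmetry and validated for
    presence; the decision rests on the Y markers, whose expression is
    absent in females.
    """
    if not list(y_genes):
        raise ValueError("at least one Y-linked marker gene is required")
    for gene in list(x_genes) + list(y_genes):
        if gene not in counts.index:
            raise ValueError(f"marker gene {gene!r} absent from count matrix")
    cpm = compute_cpm(counts)
    y_mean = cpm.loc[list(y_genes)].mean(axis=0)
    return {sample: ("M" if y_mean[sample] >= threshold else "F") for sample in counts.columns}


@dataclass
class AnovaResult:
    """ANOVA table, Tukey pairwise table, and the fitted-model metadata."""

    anova: pd.DataFrame
    tukey: pd.DataFrame | None
    formula: str
    n_obs: int
    constant_response: bool = False

    def term_p(self, term: str) -> float:
        """P-value for a model term, e.g. ``C(group)`` or ``C(group):C(imprinted)``."""
        return float(self.anova.loc[term, "PR(>F)"])

    def tukey_p(self, cell_a: str, cell_b: str) -> float:
        """Tukey-adjusted p for a pair of group x imprinting cells."""
        if self.tukey is None:
            raise ValueError("Tukey table was not computed")
        t = self.tukey
        hit = t[
            ((t["group1"] == cell_a) & (t["group2"] == cell_b))
            | ((t["group1"] == cell_b) & (t["group2"] == cell_a))
        ]
        if hit.empty:
            raise KeyError(f"no Tukey contrast between {cell_a!r} and {cell_b!r}")
        return float(hit["p-adj"].iloc[0])


def response_table(
    summaries: Iterable[TranscriptAllelicSummary],
    meta: Sequence[SampleMeta],
    eligible_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Long-format ANOVA input: one row per gene x sample.

    The response is the effective SNP frequency — transcripts whose
    confident-SNP count fell below the per-transcript minimum contribute 0
    SNP/kb, since their sparse calls were discarded as putative artefacts.
    Genes failing the total-read gate (when ``eligible_genes`` is given)
    are excluded entirely.
    """
    meta_by_id: Mapping[str, SampleMeta] = {m.sample_id: m for m in meta}
    rows = []
    for s in summaries:
        if eligible_genes is not None and s.gene_id not in eligible_genes:
            continue
        m = meta_by_id[s.sample_id]
        rows.append(
            {
                "gene_id": s.gene_id,
                "sample_id": s.sample_id,
                "snp_per_kb": s.effective_snp_per_kb,
                "group": m.group,
                "imprinted": "imprinted" if s.imprinted else "non-imprinted",
                "sex": m.sex,
                "sampling_date": m.sampling_date,
                "library_date": m.library_date,
            }
        )
    return pd.DataFrame(rows)


def _aliased_terms(exog: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that add no rank to the design matrix, found incrementally."""
    aliased = []
    rank = 0
    kept = np.empty((exog.shape[0], 0))
    for j, name in enumerate(names):
        candidate = np.column_stack([kept, exog[:, j]])
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            kept, rank = candidate, new_rank
        else:
            aliased.append(name)
    return aliased


def anova_snp_frequency(
    table: pd.DataFrame,
    typ: int = 2,
    include_covariates: bool = True,
    tukey: bool = True,
    alpha: float = 0.05,
) -> AnovaResult:
    """Fit the factorial model and (optionally) Tukey HSD on the four cells.

    ``table`` is the output of :func:`response_table` (or an equivalent
    frame with columns ``snp_per_kb``, ``group``, ``imprinted`` and the
    covariates).  Covariates with fewer than two observed levels are
    dropped from the formula rather than erroring, since e.g. an all-male
    batch cannot support a sex term.  A rank-deficient design raises with
    the names of the aliased terms.
    """
    if table.empty:
        raise ValueError("empty response table")
    # factors with a single observed level carry no information and are
    # dropped from the formula (e.g. an all-male batch, or a single-class run)
    terms = []
    if table["group"].nunique() > 1:
        terms.append("C(group)")
    if table["imprinted"].nunique() > 1:
        terms.append("C(imprinted)")
    if len(terms) == 2:
        terms.append("C(group):C(imprinted)")
    if not terms:
        raise ValueError("need at least two levels in group or imprinted")
    if include_covariates:
        for cov in COVARIATES:
            if cov in table.columns and table[cov].nunique() > 1:
                terms.append(f"C({cov})")
    formula = "snp_per_kb ~ " + " + ".join(terms)

    if table["snp_per_kb"].nunique() <= 1:
        # constant response: zero between- and within-cell variance; by
        # convention every term is reported as non-significant (p = 1)
        aov = pd.DataFrame(
            {
                "sum_sq": 0.0,
                "df": np.nan,
                "F": np.nan,
                "PR(>F)": 1.0,
            },
            index=terms + ["Residual"],
        )
        return AnovaResult(
            anova=aov, tukey=None, formula=formula,
            n_obs=len(table), constant_response=True,
        )

    model = smf.ols(formula, data=table).fit()
    exog = model.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        bad = _aliased_terms(exog, model.model.exog_names)
        raise ValueError(f"rank-deficient design; aliased terms: {bad}")
    aov = sm.stats.anova_lm(model, typ=typ)

    tukey_df = None
    if tukey:
        cells = table["group"].astype(str) + ":" + table["imprinted"].astype(str)
        res = pairwise_tukeyhsd(table["snp_per_kb"].to_numpy(), cells.to_numpy(), alpha=alpha)
        summary = res.summary()
        tukey_df = pd.DataFrame(summary.data[1:], columns=summary.data[0])
        tukey_df["p-adj"] = res.pvalues
    return AnovaResult(
        anova=aov, tukey=tukey_df, formula=formula, n_obs=len(table)
    )
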