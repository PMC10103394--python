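"""Bulk differential expression vs non-tumor brain and stage-signature scoring.

The statistic of interest is the *enrichment percentage* of a lineage-stage
signature: the fraction of its genes that are significantly up-regulated in
tumors versus non-tumor (NT) brain at a joint q-value / fold-change cutoff.
Across the ordered oligodendrocyte stages OPC -> COP -> NFOL -> MFOL -> MO
this percentage declines sharply in IDH-mutant (PM) gliomas, which is the
bulk-level readout of a differentiation block before myelination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model_io import ExpressionMatrix, Thresholds, ValidationError

FC_MIN_DEFAULT = 1.5


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (shared by all modules)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene Welch t-test of group A (case) vs group B (control), log2 scale.

    ``table`` columns: t_statistic, p_value, q_value (BH over all tested
    genes), log2_fc (mean A − mean B), direction ('up'/'down'); indexed by
    gene.
    """

    table: pd.DataFrame
    group_a: list[str]
    group_b: list[str]

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def differential_expression(expr: ExpressionMatrix, group_a: list[str],
                            group_b: list[str]) -> DEResult:
    """Welch two-sample t-test per gene on a log2-scale matrix.

    Genes with zero variance in both groups get t = 0, p = 1. BH adjustment
    is over all tested genes.
    """
    if expr.scale != "log2":
        raise ValidationError("differential_expression expects a log2 matrix")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    a = expr.subset_samples(group_a).dense()
    b = expr.subset_samples(group_b).dense()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    flat = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    # Welch df is undefined when exactly one group is flat; scipy yields a
    # finite statistic there, keep it.
    p = np.nan_to_num(p, nan=1.0)
    t = np.nan_to_num(t, nan=0.0)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    table = pd.DataFrame({
        "t_statistic": t,
        "p_value": p,
        "q_value": bh_qvalues(p),
        "log2_fc": log2_fc,
        "direction": np.where(log2_fc >= 0, "up", "down"),
    }, index=expr.gene_ids)
    return DEResult(table, list(group_a), list(group_b))


def select_top_genes(de: DEResult, n: int, direction: str = "both") -> list[str]:
    """Top-*n* genes ranked by ascending p, tie-broken by descending \\|t\\|
    then lexicographic gene id; filtered to *direction* before truncation."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if n > len(de.table):
        raise ValidationError(f"n={n} exceeds the {len(de.table)} tested genes")
    if direction not in ("up", "down", "both"):
        raise ValidationError(f"unknown direction {direction!r}")
    tab = de.table
    if direction != "both":
        tab = tab[tab["direction"] == direction]
    order = tab.assign(abs_t=tab["t_statistic"].abs(), gene=tab.index).sort_values(
        ["p_value", "abs_t", "gene"], ascending=[True, False, True])
    return order.index[:n].tolist()


@dataclass
class VennCounts:
    a_only: int
    b_only: int
    both: int


def concordant_up_genes(de_codel: DEResult, de_noncodel: DEResult, n: int,
                        thresholds: Thresholds = Thresholds(),
                        ) -> tuple[list[str], VennCounts]:
    """Genes concordantly up-regulated in both PM subtypes.

    Intersection of the two top-*n* up-regulated lists restricted to genes
    passing the fold-change floor (log2_fc >= log2(fc_min)) in each
    comparison; Venn counts refer to the filtered lists.
    """
    if set(de_codel.genes) != set(de_noncodel.genes):
        raise ValidationError("DE results cover different gene universes")
    lfc = np.log2(thresholds.fc_min)

    def top_up(de: DEResult) -> set[str]:
        sel = select_top_genes(de, min(n, len(de.table)), direction="up")
        fc = de.table["log2_fc"]
        return {g for g in sel if fc[g] >= lfc}

    a, b = top_up(de_codel), top_up(de_noncodel)
    both = sorted(a & b)
    return both, VennCounts(a_only=len(a - b), b_only=len(b - a), both=len(both))


@dataclass
class EnrichmentResult:
    percentage: float
    n_enriched: int
    n_in_universe: int


def signature_enrichment_percentage(de: DEResult, signature: list[str],
                                    thresholds: Thresholds = Thresholds(),
                                    name: str = "signature") -> EnrichmentResult:
    """Percent of signature genes significantly up-regulated in the case group.

    A gene counts as enriched when q < de_q, log2_fc >= log2(fc_min) and the
    direction is 'up'; the denominator is the signature genes present in the
    DE universe.
    """
    sig = [g.upper() for g in signature]
    present = [g for g in sig if g in de.genes]
    if not present:
        raise ValidationError(f"no gene of signature {name!r} is in the DE universe")
    tab = de.table.loc[present]
    lfc = np.log2(thresholds.fc_min)
    passing = ((tab["q_value"] < thresholds.de_q)
               & (tab["log2_fc"] >= lfc)
               & (tab["direction"] == "up"))
    k, m = int(passing.sum()), len(present)
    return EnrichmentResult(100.0 * k / m, k, m)


def stage_enrichment_profile(de: DEResult, stage_signatures, stage_order: list[str],
                             thresholds: Thresholds = Thresholds()) -> pd.Series:
    """Enrichment percentage for each lineage stage, in stage order."""
    vals = {s: signature_enrichment_percentage(de, stage_signatures[s],
                                               thresholds, name=s).percentage
            for s in stage_order}
    return pd.Series(vals, name="enrichment_pct").loc[stage_order]
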