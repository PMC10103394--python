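"""Differential DNA methylation between tumor and normal cohorts.

Works on pre-normalized beta values (methylated fraction per CpG, in [0,1]).
A differentially methylated position (DMP) must jointly pass a
Benjamini–Hochberg adjusted Welch-t p-value below 0.05 and an absolute
tumor-minus-normal beta difference above 0.20 (the "methylation difference
> 20%" rule, read as percentage points of beta). Promoter-level status is a
majority vote of TSS-proximal DMPs, and cohorts are visualized by classical
(Torgerson) MDS of the top-variable CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bulk_signatures import bh_qvalues
from .data_model_io import (
    BetaMatrix,
    GeneAnnotation,
    Thresholds,
    ValidationError,
)


@dataclass
class DMPSet:
    """Per-CpG results restricted to positions passing the joint DMP filter.

    ``table`` columns: delta_beta (tumor mean − normal mean), p_value,
    q_value, status ('hyper'/'hypo'); indexed by CpG id. ``tested`` is the
    full per-CpG table before filtering.
    """

    table: pd.DataFrame
    tested: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def call_dmps(tumor: BetaMatrix, normal: BetaMatrix,
              thresholds: Thresholds = Thresholds()) -> DMPSet:
    """Welch t-test per shared CpG; keep q < dmp_q and |Δβ| > dmp_delta_beta."""
    shared = [c for c in tumor.cpg_ids if c in set(normal.cpg_ids)]
    if not shared:
        raise ValidationError("tumor and normal share no CpG")
    if tumor.values.shape[1] < 2 or normal.values.shape[1] < 2:
        raise ValidationError("each group needs at least 2 samples")
    t_df = tumor.to_frame().loc[shared]
    n_df = normal.to_frame().loc[shared]
    t_stat, p = stats.ttest_ind(t_df.to_numpy(), n_df.to_numpy(), axis=1,
                                equal_var=False)
    flat = (t_df.var(axis=1, ddof=1) == 0) & (n_df.var(axis=1, ddof=1) == 0)
    p = np.where(flat, 1.0, np.nan_to_num(p, nan=1.0))
    delta = t_df.mean(axis=1) - n_df.mean(axis=1)
    tested = pd.DataFrame({
        "delta_beta": delta,
        "p_value": p,
        "q_value": bh_qvalues(p),
        "status": np.where(delta > 0, "hyper", "hypo"),
    }, index=shared)
    keep = ((tested["q_value"] < thresholds.dmp_q)
            & (tested["delta_beta"].abs() > thresholds.dmp_delta_beta))
    return DMPSet(tested[keep].copy(), tested)


def hypermethylated_fraction(dmps: DMPSet) -> float:
    """100 × hyper / (hyper + hypo) over the called DMPs."""
    if len(dmps) == 0:
        raise ValidationError("DMP set is empty; hypermethylated fraction undefined")
    return 100.0 * float((dmps.table["status"] == "hyper").mean())


def summarize_promoter_status(dmps: DMPSet, beta: BetaMatrix,
                              annotation: GeneAnnotation,
                              gene_sets: dict[str, list[str]],
                              tss_window: int = 1500) -> pd.DataFrame:
    """Per-gene promoter methylation status from TSS-proximal DMPs.

    CpGs map to a gene when |position − TSS| <= tss_window on the same
    chromosome. A gene is 'hyper' when > 50% of its mapped DMPs are hyper
    (and >= 1 DMP exists), symmetrically 'hypo'; 'mixed' otherwise; 'none'
    with no mapped DMP. Returns a frame indexed by gene with columns
    set_name, status, n_dmps.
    """
    if tss_window <= 0:
        raise ValidationError("tss_window must be positive")
    coords = beta.cpg_coords.loc[dmps.table.index]
    rows = []
    for set_name, genes in gene_sets.items():
        for g in genes:
            gu = g.upper()
            if gu not in annotation.genes:
                rows.append((gu, set_name, "none", 0))
                continue
            grow = annotation.table.loc[gu]
            near = coords[(coords["chrom"] == grow["chrom"])
                          & ((coords["pos"] - grow["tss"]).abs() <= tss_window)]
            if len(near) == 0:
                rows.append((gu, set_name, "none", 0))
                continue
            frac_hyper = (dmps.table.loc[near.index, "status"] == "hyper").mean()
            if frac_hyper > 0.5:
                status = "hyper"
            elif frac_hyper < 0.5:
                status = "hypo"
            else:
                status = "mixed"
            rows.append((gu, set_name, status, len(near)))
    return pd.DataFrame(rows, columns=["gene", "set_name", "status", "n_dmps"]
                        ).set_index("gene")


def mds_top_variable(beta: BetaMatrix, top: int = 1000) -> pd.DataFrame:
    """2-D classical MDS of samples on the top-variance CpGs.

    CpGs are ranked by across-sample variance; classical (Torgerson) MDS is
    run on Euclidean sample distances. Output is canonicalized by flipping
    each axis so the first sample's coordinate is non-negative.
    """
    if top > len(beta.cpg_ids):
        raise ValidationError(f"top={top} exceeds the {len(beta.cpg_ids)} CpGs")
    if len(beta.sample_ids) < 3:
        raise ValidationError("MDS needs at least 3 samples")
    var = beta.values.var(axis=1)
    idx = np.argsort(-var, kind="stable")[:top]
    X = beta.values[idx, :].T  # samples x CpGs
    if np.ptp(X) == 0:
        raise ValidationError("selected CpGs are constant across samples; "
                              "geometry degenerate")
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa

    D = DistanceMatrix(squareform(pdist(X)), ids=[str(s) for s in beta.sample_ids])
    ord_res = pcoa(D, number_of_dimensions=2)
    coords = ord_res.samples.iloc[:, :2].to_numpy()
    for ax in range(coords.shape[1]):
        if coords[0, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    return pd.DataFrame(coords, index=beta.sample_ids, columns=["MDS1", "MDS2"])


def combine_beta(a: BetaMatrix, b: BetaMatrix) -> BetaMatrix:
    """Column-concatenate two beta matrices over their shared CpGs."""
    shared = [c for c in a.cpg_ids if c in set(b.cpg_ids)]
    if not shared:
        raise ValidationError("no shared CpGs to combine")
    av = a.to_frame().loc[shared]
    bv = b.to_frame().loc[shared]
    return BetaMatrix(np.concatenate([av.to_numpy(), bv.to_numpy()], axis=1),
                      shared, a.cpg_coords.loc[shared],
                      list(av.columns) + list(bv.columns))
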