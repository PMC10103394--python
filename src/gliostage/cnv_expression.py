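"""Expression-based inference of arm-level copy-number changes in single cells.

A gain or loss of a whole chromosome arm shifts the expression of *every*
gene on that arm by roughly the dosage ratio, while single-gene fluctuations
average out. The method therefore (1) expresses each cell's log expression
relative to the mean of designated non-malignant reference cells, (2) clips
extreme per-gene values (per-platform bound), (3) smooths along genomic
coordinates with a centered moving average within each chromosome, and
(4) re-centers each cell by its median smoothed value. Arm means of the
smoothed profile are then thresholded into gain / neutral / loss calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import ExpressionMatrix, GeneAnnotation, ValidationError

LN2 = np.log(2.0)


@dataclass
class CNVProfile:
    """Per-cell smoothed relative profile and per-arm summaries.

    ``values``: genes x cells smoothed log2 ratios (genes ordered by
    genomic coordinate, as in ``gene_order``). ``arm_means``: arms x cells.
    """

    values: np.ndarray
    gene_order: list[str]
    cell_ids: list[str]
    arm_means: pd.DataFrame


def _moving_average_truncated(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0, truncated at the edges."""
    n = x.shape[0]
    half = window // 2
    cs = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)[:, None]


def infer_cnv(normalized: ExpressionMatrix, reference_cells: list[str],
              annotation: GeneAnnotation, window: int = 101,
              clip: float = 1.0) -> CNVProfile:
    """Smoothed relative copy-number profile for every cell.

    *normalized* holds log-normalized expression (log1p of library-scaled
    counts); genes are centered by the reference-cell mean, converted to
    log2, clipped to ±*clip*, ordered by (chrom, start), smoothed with a
    centered *window*-gene moving average within each chromosome, and each
    cell is re-centered by its median smoothed value.
    """
    if len(reference_cells) < 20:
        raise ValidationError(f"need >= 20 reference cells, got {len(reference_cells)}")
    missing_ref = set(reference_cells) - set(normalized.sample_ids)
    if missing_ref:
        raise ValidationError(f"reference cells absent from matrix: "
                              f"{sorted(missing_ref)[:3]}")
    covered = [g for g in normalized.gene_ids if g in annotation.genes]
    if len(covered) < 0.5 * normalized.n_genes:
        raise ValidationError(
            f"annotation covers only {len(covered)}/{normalized.n_genes} genes "
            "(<50%)")
    ann = annotation.table.loc[covered]
    # gene id as final key: coordinate ties must not depend on input order
    order = (ann.assign(_gene=ann.index)
             .sort_values(["chrom", "start", "_gene"]).index.tolist())

    sub = normalized.subset_genes(order)
    X = sub.dense()
    ref_idx = pd.Index(normalized.sample_ids).get_indexer(reference_cells)
    rel = (X - X[:, ref_idx].mean(axis=1, keepdims=True)) / LN2
    rel = np.clip(rel, -clip, clip)

    chrom = ann.loc[order, "chrom"].to_numpy()
    smoothed = np.empty_like(rel)
    for c in pd.unique(chrom):
        mask = chrom == c
        if mask.sum() < window:
            raise ValidationError(
                f"window={window} exceeds the {int(mask.sum())} annotated genes "
                f"on {c}; use a smaller window")
        smoothed[mask] = _moving_average_truncated(rel[mask], window)
    smoothed -= np.median(smoothed, axis=0, keepdims=True)

    arm = (ann.loc[order, "chrom"].astype(str).str.replace("chr", "", regex=False)
           + ann.loc[order, "arm"]).to_numpy()
    arm_means = pd.DataFrame(
        {a: smoothed[arm == a].mean(axis=0) for a in pd.unique(arm)},
        index=normalized.sample_ids).T
    return CNVProfile(smoothed, order, list(normalized.sample_ids), arm_means)


def call_arm_events(profile: CNVProfile, gain_cut: float = 0.2,
                    loss_cut: float = -0.2) -> pd.DataFrame:
    """Threshold per-arm means into calls; cells x arms of {gain,loss,neutral}."""
    if not loss_cut < 0 < gain_cut:
        raise ValidationError("thresholds must satisfy loss_cut < 0 < gain_cut")
    m = profile.arm_means.T  # cells x arms
    calls = pd.DataFrame("neutral", index=m.index, columns=m.columns)
    calls = calls.mask(m > gain_cut, "gain").mask(m < loss_cut, "loss")
    return calls


def cells_with_event(calls: pd.DataFrame) -> pd.Series:
    """Boolean per cell: carries at least one non-neutral arm call."""
    return (calls != "neutral").any(axis=1)
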