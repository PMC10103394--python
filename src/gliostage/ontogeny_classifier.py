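"""Two-tier transcriptome classification of adult diffuse glioma.

Tier 1 splits a cohort into EM (EGFR-module) vs PM (PDGFRA-module) classes by
clustering on the EM+PM signature genes. Tier 2 splits the PM samples into
1p19q-codeleted vs non-codeleted oligodendroglioma/astrocytoma classes by
clustering on a packaged 152-gene classifier and orienting the two clusters
by expression dosage: hemizygous loss of 1p/19q lowers the expression of
classifier genes residing on those arms, so the cluster with the lower mean
expression of 1p/19q classifier genes is the codeleted one.

Both tiers use the same deterministic recipe: restrict to signature genes,
median-center each gene across samples, agglomerative (Ward) clustering on
1 − Pearson correlation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .bulk_signatures import DEResult, differential_expression, select_top_genes
from .data_model_io import (
    ExpressionMatrix,
    GeneAnnotation,
    SignatureCollection,
    ValidationError,
)


class OrientationError(ValidationError):
    """Cluster orientation is undecidable; supply reference centroids."""


@dataclass
class SubtypeCall:
    sample_id: str
    tier1: str                    # EM | PM
    tier2: str                    # codel | noncodel | not_applicable
    confidence: float             # margin to the assigned cluster centroid

    def __post_init__(self) -> None:
        if self.tier1 not in ("EM", "PM"):
            raise ValidationError(f"tier1 must be EM or PM, got {self.tier1!r}")
        if self.tier2 != "not_applicable" and self.tier1 != "PM":
            raise ValidationError("tier2 is only defined for PM samples")
        if self.confidence < 0:
            raise ValidationError("confidence must be >= 0")


def cluster_by_signature(expr: ExpressionMatrix, signature: list[str],
                         k: int = 2) -> pd.Series:
    """Ward clustering of samples on 1 − Pearson over median-centered
    signature genes; returns sample -> cluster label (1..k), deterministic."""
    if expr.n_samples < 2 * k:
        raise ValidationError(f"need at least {2 * k} samples for k={k}")
    sig = [g.upper() for g in signature]
    present = [g for g in sig if g in set(expr.gene_ids)]
    if len(present) < 10:
        missing = len(sig) - len(present)
        raise ValidationError(
            f"only {len(present)} signature genes found in the matrix "
            f"({missing} missing); need at least 10")
    X = expr.subset_genes(present).dense()
    X = X - np.median(X, axis=1, keepdims=True)
    if k == 1:
        return pd.Series(1, index=expr.sample_ids, name="cluster")
    corr = np.corrcoef(X.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=expr.sample_ids, name="cluster")


def _cluster_centroid_margin(X: np.ndarray, labels: np.ndarray,
                             sample_idx: int) -> float:
    """|corr to own centroid − corr to the other centroid| for one sample."""
    own = labels[sample_idx]
    margins = {}
    for lab in np.unique(labels):
        mask = labels == lab
        mask_excl = mask.copy()
        if lab == own and mask.sum() > 1:
            mask_excl[sample_idx] = False
        centroid = X[:, mask_excl].mean(axis=1)
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(X[:, sample_idx], centroid)[0, 1]
        margins[lab] = 0.0 if np.isnan(r) else r
    others = [v for lab, v in margins.items() if lab != own]
    return abs(margins[own] - max(others)) if others else 0.0


def orient_1p19q_clusters(expr: ExpressionMatrix, labels: pd.Series,
                          classifier: list[str], annotation: GeneAnnotation,
                          ) -> list[SubtypeCall]:
    """Label the two classifier clusters as codel / noncodel by 1p/19q dosage.

    The cluster with the lower mean expression of classifier genes annotated
    to arms 1p or 19q is called codeleted; per-sample confidence is the
    absolute difference of the two cluster means (log2 units). Raises
    :class:`OrientationError` when the difference is zero — no silent guess.
    """
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError(f"expected exactly 2 clusters, got {len(uniq)}")
    cls = [g.upper() for g in classifier]
    on_arms = set(annotation.genes_on_arms(["1p", "19q"]))
    dosage_genes = [g for g in cls if g in on_arms and g in set(expr.gene_ids)]
    if len(dosage_genes) < 5:
        raise OrientationError(
            f"only {len(dosage_genes)} classifier genes map to 1p/19q under the "
            "given annotation; supply reference centroids instead")
    sub = expr.subset_genes(dosage_genes)
    means = {lab: sub.subset_samples(labels.index[labels == lab].tolist())
             .dense().mean() for lab in uniq}
    margin = abs(means[uniq[0]] - means[uniq[1]])
    if margin == 0:
        raise OrientationError("clusters have identical 1p/19q dosage means; "
                               "orientation undecidable — supply reference centroids")
    codel_lab = min(means, key=means.get)
    return [SubtypeCall(s, "PM", "codel" if labels[s] == codel_lab else "noncodel",
                        confidence=margin)
            for s in labels.index]


def _module_elevation(expr: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """Per-sample mean expression of *genes* minus the sample's global mean."""
    present = [g for g in genes if g in set(expr.gene_ids)]
    if not present:
        raise ValidationError("no module gene found in the matrix")
    X = expr.dense()
    sub = expr.subset_genes(present).dense()
    return pd.Series(sub.mean(axis=0) - X.mean(axis=0), index=expr.sample_ids)


def two_tier_classify(expr: ExpressionMatrix, em_signature: list[str],
                      pm_signature: list[str], classifier: list[str],
                      annotation: GeneAnnotation,
                      min_split_margin: float = 0.5) -> list[SubtypeCall]:
    """Tier 1 (EM vs PM) then tier 2 (1p19q status) on the PM subset.

    Tier 1 clusters on the union of the EM and PM signatures; each sample's
    *module score* is its PM-module elevation minus its EM-module elevation
    (signature mean relative to the sample's transcriptome mean, log2
    units). When the two clusters' mean scores differ by at least
    *min_split_margin* the higher-scoring cluster is PM; otherwise the
    cohort is treated as homogeneous and every sample gets the class of the
    cohort-wide mean score, so an EM-only (or PM-only) cohort is not
    force-split. Tier 2 runs :func:`orient_1p19q_clusters` on the PM
    subset; a PM subset smaller than 4 samples gets tier2 = not_applicable
    with a warning.
    """
    em = {g.upper() for g in em_signature}
    pm = {g.upper() for g in pm_signature}
    if em & pm:
        raise ValidationError("EM and PM signatures must be disjoint")
    union = sorted(em | pm)
    labels = cluster_by_signature(expr, union, k=2)

    score = _module_elevation(expr, sorted(pm)) - _module_elevation(expr, sorted(em))
    cluster_score = score.groupby(labels).mean()
    if abs(cluster_score.max() - cluster_score.min()) >= min_split_margin:
        pm_lab = cluster_score.idxmax()
        tier1 = labels.map(lambda lab: "PM" if lab == pm_lab else "EM")
    else:
        tier1 = pd.Series("PM" if score.mean() > 0 else "EM",
                          index=labels.index)

    # per-sample confidence: centroid-correlation margin on the tier-1 genes
    present_union = [g for g in union if g in set(expr.gene_ids)]
    X = expr.subset_genes(present_union).dense()
    X = X - np.median(X, axis=1, keepdims=True)
    lab_arr = labels.to_numpy()
    conf1 = {s: _cluster_centroid_margin(X, lab_arr, i)
             for i, s in enumerate(expr.sample_ids)}

    calls: dict[str, SubtypeCall] = {
        s: SubtypeCall(s, tier1[s], "not_applicable", conf1[s])
        for s in expr.sample_ids}

    pm_samples = [s for s in expr.sample_ids if tier1[s] == "PM"]
    if len(pm_samples) < 4:
        import logging
        logging.getLogger("gliostage").warning(
            "PM subset has %d samples (<4); tier-2 classification skipped",
            len(pm_samples))
        return [calls[s] for s in expr.sample_ids]

    pm_sub = expr.subset_samples(pm_samples)
    labels2 = cluster_by_signature(pm_sub, classifier, k=2)
    for call in orient_1p19q_clusters(pm_sub, labels2, classifier, annotation):
        calls[call.sample_id] = call
    return [calls[s] for s in expr.sample_ids]


def derive_1p19q_classifier(expr: ExpressionMatrix, codel_samples: list[str],
                            noncodel_samples: list[str],
                            p_cut: float = 1e-16) -> tuple[list[str], DEResult]:
    """Derive a fresh dosage classifier from a labeled PM cohort.

    Utility mirroring how the packaged classifier was built: genes whose
    codel-vs-noncodel Welch t-test p-value falls below *p_cut* (default
    1e-16), both directions, ranked by significance.
    """
    de = differential_expression(expr, codel_samples, noncodel_samples)
    n_pass = int((de.table["p_value"] < p_cut).sum())
    if n_pass == 0:
        return [], de
    return select_top_genes(de, n_pass, direction="both"), de


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame([{"sample_id": c.sample_id, "tier1": c.tier1,
                          "tier2": c.tier2, "confidence": c.confidence}
                         for c in calls]).set_index("sample_id")
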