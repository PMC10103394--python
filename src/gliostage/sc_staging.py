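"""Single-cell QC, clustering, marker annotation, malignancy and staging.

The workflow mirrors a standard droplet scRNA-seq pipeline: QC filter
(cells with < 200 transcripts, then genes detected in < 3 cells, removed),
library-size normalization to 10k + log1p, selection of the 500 most
variable genes, z-scaling, PCA, kNN graph and Leiden clustering. Clusters
are typed by marker panels; malignant cells are recognized jointly by
SOX2 over-expression and the presence of arm-level CNV; proliferating cells
by concomitant detection of all proliferation markers (MKI67, TOP2A, CCNB2,
CDK1 by default). Cluster profiles are finally staged against reference
oligodendrocyte-lineage transcriptomes by Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .data_model_io import (
    ExpressionMatrix,
    SignatureCollection,
    Thresholds,
    ValidationError,
)

logger = logging.getLogger("gliostage")

IMMUNE_OR_DIFFERENTIATED = {"microglia", "macrophage", "t_cell", "oligodendrocyte"}

_PANEL_TO_TYPE = {
    "PRE_OPC": "pre-OPC", "OPC": "OPC", "COP": "COP",
    "OLIGODENDROCYTE": "oligodendrocyte", "ASTROCYTE": "astrocyte",
    "APC": "APC", "T_CELL": "T_cell", "MICROGLIA": "microglia",
    "MACROPHAGE": "macrophage",
}
_TYPE_LOWER = {v.lower(): v for v in _PANEL_TO_TYPE.values()}


@dataclass
class CellAnnotation:
    cell_id: str
    cluster: int
    cell_type: str
    malignant: bool = False
    proliferating: bool = False
    panel_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class QCReport:
    removed_cells: list[str]
    removed_genes: list[str]


def qc_filter(counts: ExpressionMatrix,
              thresholds: Thresholds = Thresholds(),
              ) -> tuple[ExpressionMatrix, QCReport]:
    """Drop cells with total UMIs < 200, then genes detected in < 3 cells."""
    if counts.scale != "raw_counts":
        raise ValidationError("qc_filter expects raw UMI counts")
    X = counts.values
    totals = np.asarray(X.sum(axis=0)).ravel()
    keep_cells = totals >= thresholds.min_transcripts_per_cell
    if not keep_cells.any():
        raise ValidationError(
            f"all cells fall below {thresholds.min_transcripts_per_cell} "
            "transcripts; nothing left after QC")
    Xc = X[:, keep_cells]
    detected = np.asarray((Xc > 0).sum(axis=1)).ravel()
    keep_genes = detected >= thresholds.min_cells_per_gene
    out = ExpressionMatrix(
        Xc[keep_genes, :],
        [g for g, k in zip(counts.gene_ids, keep_genes) if k],
        [c for c, k in zip(counts.sample_ids, keep_cells) if k],
        scale="raw_counts")
    report = QCReport(
        removed_cells=[c for c, k in zip(counts.sample_ids, keep_cells) if not k],
        removed_genes=[g for g, k in zip(counts.gene_ids, keep_genes) if not k])
    return out, report


def log_normalize(counts: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization to *target_sum* followed by log1p."""
    if counts.scale != "raw_counts":
        raise ValidationError("log_normalize expects raw counts")
    X = counts.dense().astype(float)
    totals = X.sum(axis=0, keepdims=True)
    totals[totals == 0] = 1.0
    return ExpressionMatrix(np.log1p(X / totals * target_sum), counts.gene_ids,
                            counts.sample_ids, scale="log2")


def proliferating_cells(matrix: ExpressionMatrix,
                        prolif_genes: list[str]) -> pd.Series:
    """Concomitant rule: every proliferation marker detected (> 0) in the cell."""
    gene_index = pd.Index(matrix.gene_ids)
    present = [g.upper() for g in prolif_genes if g.upper() in gene_index]
    if not present:
        raise ValidationError("no proliferation-panel gene in the matrix")
    P = matrix.dense()[gene_index.get_indexer(present), :]
    return pd.Series((P > 0).all(axis=0), index=matrix.sample_ids,
                     name="proliferating")


@dataclass
class EmbeddingResult:
    normalized: ExpressionMatrix      # log1p CP10K, all QC'd genes
    embedding: np.ndarray             # cells x PCs
    clusters: pd.Series               # cell -> cluster label (int)
    n_pcs: int


def normalize_and_embed(counts: ExpressionMatrix,
                        thresholds: Thresholds = Thresholds(),
                        seed: int = 0, resolution: float = 0.3,
                        target_sum: float = 1e4) -> EmbeddingResult:
    """Normalize, select variable genes, embed and cluster (deterministic).

    Library-size normalization to *target_sum* then log1p; the
    ``n_features`` most variable genes are z-scaled and reduced by PCA. The
    retained component count follows a Kaiser-style rule (components whose
    explained-variance ratio exceeds the uniform expectation; at least 2),
    standing in for a permutation-significance rule, and is logged. Leiden
    clustering on the kNN graph with a fixed seed.
    """
    import scanpy as sc

    if counts.scale != "raw_counts":
        raise ValidationError("normalize_and_embed expects QC-filtered raw counts")
    adata = counts.to_anndata()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    norm = ExpressionMatrix(
        sp.csr_matrix(adata.X).T if sp.issparse(adata.X) else np.asarray(adata.X).T,
        counts.gene_ids, counts.sample_ids, scale="log2")

    n_feat = thresholds.n_features
    if counts.n_genes < n_feat:
        logger.warning("only %d genes available (< n_features=%d); using all",
                       counts.n_genes, n_feat)
        n_feat = counts.n_genes
    sc.pp.highly_variable_genes(adata, n_top_genes=n_feat, flavor="seurat")
    adata = adata[:, adata.var["highly_variable"]].copy()
    sc.pp.scale(adata, max_value=10)
    n_comps = min(50, adata.n_obs - 1, adata.n_vars - 1)
    sc.tl.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    ratio = adata.uns["pca"]["variance_ratio"]
    n_pcs = min(n_comps, max(10, int((ratio > 1.0 / len(ratio)).sum())))
    logger.info("retaining %d principal components", n_pcs)
    sc.pp.neighbors(adata, n_pcs=n_pcs, random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="igraph", n_iterations=2, directed=False)
    clusters = pd.Series(adata.obs["leiden"].astype(int).to_numpy(),
                         index=counts.sample_ids, name="cluster")
    return EmbeddingResult(norm, adata.obsm["X_pca"][:, :n_pcs], clusters, n_pcs)


def _panel_score_matrix(normalized: ExpressionMatrix, clusters: pd.Series,
                        panels: SignatureCollection,
                        panel_names: list[str]) -> pd.DataFrame:
    """Clusters x panels: mean over cells of mean normalized panel expression."""
    gene_index = pd.Index(normalized.gene_ids)
    X = normalized.dense()
    rows = {}
    for name in panel_names:
        present = gene_index.get_indexer([g for g in panels[name]
                                          if g in gene_index])
        if len(present) == 0:
            raise ValidationError(f"panel {name!r} has no gene in the matrix")
        rows[name] = X[present, :].mean(axis=0)
    per_cell = pd.DataFrame(rows, index=normalized.sample_ids)
    return per_cell.groupby(clusters).mean()


def _null_score_floor(normalized: ExpressionMatrix, clusters: pd.Series,
                      panel_sizes: dict[str, int], seed: int = 0,
                      n_perm: int = 100, q: float = 90.0) -> dict[str, float]:
    """90th percentile of max cluster scores over random same-size panels."""
    rng = np.random.default_rng(seed)
    X = normalized.dense()
    cl = clusters.to_numpy()
    uniq = np.unique(cl)
    floors = {}
    for name, size in panel_sizes.items():
        maxima = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(X.shape[0], size=size, replace=False)
            per_cell = X[idx, :].mean(axis=0)
            maxima[b] = max(per_cell[cl == lab].mean() for lab in uniq)
        floors[name] = float(np.percentile(maxima, q))
    return floors


def annotate_clusters(normalized: ExpressionMatrix, clusters: pd.Series,
                      panels: SignatureCollection,
                      proliferation_panel: str = "PROLIFERATION",
                      seed: int = 0) -> list[CellAnnotation]:
    """Assign a cell type per cluster by arg-max marker-panel score.

    The proliferation panel is excluded from typing; clusters whose best
    score falls below a permutation-null floor are ``unassigned``. The
    per-cell ``proliferating`` flag requires concomitant detection (> 0) of
    every proliferation-panel gene.
    """
    typing_panels = [n for n in panels.names() if n != proliferation_panel
                     and n in _PANEL_TO_TYPE]
    scored_panels = typing_panels + ([proliferation_panel]
                                     if proliferation_panel in panels else [])
    all_scores = _panel_score_matrix(normalized, clusters, panels, scored_panels)
    scores = all_scores[typing_panels]
    floors = _null_score_floor(
        normalized, clusters,
        {n: len([g for g in panels[n] if g in set(normalized.gene_ids)])
         for n in typing_panels},
        seed=seed)

    cluster_type: dict[int, str] = {}
    for lab, row in scores.iterrows():
        best = row.idxmax()
        cluster_type[lab] = (_PANEL_TO_TYPE[best]
                             if row[best] > floors[best] else "unassigned")

    concomitant = proliferating_cells(normalized, panels[proliferation_panel])

    per_cell_scores = all_scores.loc[clusters].set_axis(normalized.sample_ids)
    return [CellAnnotation(cell_id=c, cluster=int(clusters[c]),
                           cell_type=cluster_type[clusters[c]],
                           proliferating=bool(concomitant.iloc[i]),
                           panel_scores=per_cell_scores.iloc[i].to_dict())
            for i, c in enumerate(normalized.sample_ids)]


def call_malignant(annotations: list[CellAnnotation],
                   normalized: ExpressionMatrix,
                   arm_calls: pd.DataFrame,
                   sox2_gene: str = "SOX2",
                   min_event_fraction: float = 0.5) -> list[CellAnnotation]:
    """Flag malignant clusters by SOX2 positivity plus arm-level CNV.

    A cluster is malignant when its SOX2-positive cell fraction exceeds the
    highest fraction seen in any immune/oligodendrocyte (reference) cluster
    and at least *min_event_fraction* of its cells carry >= 1 arm event.
    Immune/oligodendrocyte-typed clusters are never malignant.
    """
    by_cluster: dict[int, list[CellAnnotation]] = {}
    for a in annotations:
        by_cluster.setdefault(a.cluster, []).append(a)
    ref_clusters = {cl for cl, anns in by_cluster.items()
                    if anns[0].cell_type.lower() in IMMUNE_OR_DIFFERENTIATED}
    if not ref_clusters:
        raise ValidationError(
            "no immune/oligodendrocyte reference cluster found; supply "
            "reference cell ids explicitly")
    gene_index = pd.Index(normalized.gene_ids)
    if sox2_gene.upper() not in gene_index:
        raise ValidationError(f"{sox2_gene} absent from the matrix")
    sox2 = normalized.dense()[gene_index.get_loc(sox2_gene.upper()), :]
    pos = pd.Series(sox2 > 0, index=normalized.sample_ids)
    has_event = (arm_calls != "neutral").any(axis=1)

    sox2_frac = {cl: pos[[a.cell_id for a in anns]].mean()
                 for cl, anns in by_cluster.items()}
    event_frac = {cl: has_event[[a.cell_id for a in anns]].mean()
                  for cl, anns in by_cluster.items()}
    ref_level = max(sox2_frac[cl] for cl in ref_clusters)

    for cl, anns in by_cluster.items():
        is_mal = (cl not in ref_clusters
                  and sox2_frac[cl] > ref_level
                  and event_frac[cl] >= min_event_fraction)
        for a in anns:
            a.malignant = is_mal
    return annotations


@dataclass
class ProliferationSummary:
    per_sample_pct: pd.Series
    cohort_mean: float
    cohort_sd: float
    excluded_samples: list[str]


def proliferation_fraction(annotations: list[CellAnnotation],
                           sample_of_cell: pd.Series) -> ProliferationSummary:
    """Percent of malignant cells proliferating, per sample and cohort-wide.

    Samples without malignant cells are excluded from the cohort statistics
    and listed; samples whose malignant cells include no proliferating cell
    report 0%.
    """
    df = pd.DataFrame({
        "sample": [sample_of_cell[a.cell_id] for a in annotations],
        "malignant": [a.malignant for a in annotations],
        "prolif": [a.proliferating and a.malignant for a in annotations]})
    grouped = df.groupby("sample").agg(n_mal=("malignant", "sum"),
                                       n_prolif=("prolif", "sum"))
    excluded = grouped.index[grouped["n_mal"] == 0].tolist()
    valid = grouped[grouped["n_mal"] > 0]
    pct = 100.0 * valid["n_prolif"] / valid["n_mal"]
    if len(pct) == 0:
        raise ValidationError("no sample has malignant cells")
    if len(pct) == 1:
        logger.warning("single-sample cohort: SD reported as 0")
        sd = 0.0
    else:
        sd = float(pct.std(ddof=1))
    return ProliferationSummary(pct.rename("prolif_pct"), float(pct.mean()),
                                sd, excluded)


def stage_correlation(cluster_profile: pd.Series,
                      reference_profiles: pd.DataFrame,
                      min_shared: int = 30) -> tuple[str, pd.Series]:
    """Pearson correlation of a cluster profile to per-stage references.

    Both inputs are log-normalized expression; the correlation is computed
    over the shared-gene intersection. Returns (arg-max stage, full r
    vector). A constant vector raises — never a silent r = 0.
    """
    shared = cluster_profile.index.intersection(reference_profiles.index)
    if len(shared) < min_shared:
        raise ValidationError(f"only {len(shared)} shared genes (<{min_shared})")
    x = cluster_profile.loc[shared].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValidationError("cluster profile is constant; correlation undefined")
    rs = {}
    for stage in reference_profiles.columns:
        y = reference_profiles.loc[shared, stage].to_numpy(float)
        if np.ptp(y) == 0:
            raise ValidationError(f"reference profile {stage!r} is constant; "
                                  "correlation undefined")
        rs[stage] = stats.pearsonr(x, y).statistic
    r = pd.Series(rs, name="pearson_r")
    return str(r.idxmax()), r


def cluster_mean_profiles(normalized: ExpressionMatrix,
                          clusters: pd.Series) -> pd.DataFrame:
    """Genes x clusters mean log-normalized expression."""
    X = normalized.dense()
    out = {lab: X[:, (clusters == lab).to_numpy()].mean(axis=1)
           for lab in sorted(clusters.unique())}
    return pd.DataFrame(out, index=normalized.gene_ids)


def annotations_to_frame(annotations: list[CellAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": a.cell_id, "cluster": a.cluster, "cell_type": a.cell_type,
        "malignant": a.malignant, "proliferating": a.proliferating}
        for a in annotations]).set_index("cell_id")
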