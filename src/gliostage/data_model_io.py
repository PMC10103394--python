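"""Domain types, file IO, and packaged signature resources.

The pipeline's shared currency is a small set of plain containers:

* :class:`ExpressionMatrix` — genes x samples (bulk, log2) or genes x cells
  (UMI counts), dense or sparse.
* :class:`GeneAnnotation` — per-gene chromosome/arm/coordinates, 0-based
  half-open, BED on disk.
* :class:`SignatureCollection` — named gene sets (GMT on disk).
* :class:`BetaMatrix` — CpG x samples methylation fractions in [0, 1].
* :class:`Thresholds` — the analysis constants used throughout.

Gene symbols are matched by upper-case exact identity everywhere; no alias
expansion is attempted (aliasing would silently change set sizes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("gliostage")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class GliostageError(Exception):
    """Base class for all package errors."""


class ParseError(GliostageError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(GliostageError):
    """Inputs violate a documented precondition."""


@dataclass
class ExpressionMatrix:
    """Expression values with row (gene) and column (sample/cell) identifiers.

    ``scale`` is ``"log2"`` for bulk log-scale data and ``"raw_counts"`` for
    UMI count matrices (non-negative integers, possibly sparse).
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "raw_counts"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        self.gene_ids = [str(g).upper() for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_ids after loading")
        if self.scale == "raw_counts" and np.prod(self.values.shape) > 0:
            if self.values.min() < 0:
                raise ValidationError("raw_counts matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        keep = [g.upper() for g in genes]
        idx = pd.Index(self.gene_ids).get_indexer(keep)
        if (idx < 0).any():
            missing = [g for g, i in zip(keep, idx) if i < 0]
            raise ValidationError(f"genes absent from matrix: {missing[:5]}...")
        vals = self.values[idx, :]
        return replace(self, values=vals, gene_ids=list(keep))

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(list(samples))
        if (idx < 0).any():
            raise ValidationError("sample ids absent from matrix")
        return replace(self, values=self.values[:, idx], sample_ids=list(samples))

    def to_anndata(self):
        """Cells x genes AnnData view (single-cell convention)."""
        import anndata as ad

        X = self.values.T.tocsr() if sp.issparse(self.values) else self.dense().T
        return ad.AnnData(
            X=X,
            obs=pd.DataFrame(index=pd.Index(self.sample_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


@dataclass
class GeneAnnotation:
    """Per-gene genomic annotation: chrom, arm, 0-based half-open start/end, TSS.

    Backed by a DataFrame indexed by upper-cased gene symbol with columns
    ``chrom, start, end, arm, tss``.
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "start", "end", "arm", "tss")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str).str.upper()
        if (self.table["start"] >= self.table["end"]).any():
            bad = self.table.index[self.table["start"] >= self.table["end"]][:3].tolist()
            raise ValidationError(f"start >= end for genes {bad}")
        if not self.table["arm"].isin(["p", "q"]).all():
            raise ValidationError("arm must be 'p' or 'q'")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def arm_of(self) -> pd.Series:
        """Series gene -> 'chrom_arm' label, e.g. '1p', '19q'."""
        chrom = self.table["chrom"].astype(str).str.replace("chr", "", regex=False)
        return chrom + self.table["arm"]

    def genes_on_arms(self, arms: Sequence[str]) -> list[str]:
        lab = self.arm_of()
        return lab.index[lab.isin(list(arms))].tolist()

    def validate_arms(self, centromeres: Mapping[str, int]) -> None:
        """Check arm labels against a chrom -> centromere-position table."""
        for g, row in self.table.iterrows():
            cen = centromeres.get(str(row["chrom"]))
            if cen is None:
                continue
            expected = "p" if row["tss"] < cen else "q"
            if row["arm"] != expected:
                raise ValidationError(
                    f"gene {g}: arm {row['arm']!r} inconsistent with centromere at {cen}"
                )


@dataclass
class SignatureCollection:
    """Named gene sets with free-text provenance."""

    sets: dict[str, list[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(str(g).upper(), None)
            if not seen:
                raise ValidationError(f"signature set {name!r} is empty")
            cleaned[name] = list(seen)
        self.sets = cleaned

    def __getitem__(self, name: str) -> list[str]:
        return list(self.sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class BetaMatrix:
    """CpG x samples methylation beta values in [0, 1] with CpG coordinates."""

    values: np.ndarray
    cpg_ids: list[str]
    cpg_coords: pd.DataFrame  # columns chrom, pos; index cpg_ids
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValidationError("beta matrix shape does not match id lists")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValidationError("duplicate cpg_ids")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
            raise ValidationError("beta values outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class Thresholds:
    """Analysis constants.

    Defaults follow the published workflow: top-N differential genes (2000 for
    array cohorts, 1000 for RNA-seq), fold-change floor 1.5, classifier
    derivation at p = 1e-16, single-cell QC at 200 transcripts / 3 cells,
    500 variable features, per-platform CNV clip 1.0 (STRT-seq) / 1.0
    (Smart-seq2) / 0.1 (10X), DMP rule q < 0.05 and |dbeta| > 0.20, MDS on
    the top 1000 variable CpGs.
    """

    de_top_n: int = 2000
    fc_min: float = 1.5
    de_p: float = 0.05
    de_q: float = 0.05
    classifier_p: float = 1e-16
    min_transcripts_per_cell: int = 200
    min_cells_per_gene: int = 3
    n_features: int = 500
    pc_p_cut: float = 1e-10
    cnv_clip: Mapping[str, float] = field(
        default_factory=lambda: {"strt": 1.0, "smartseq2": 1.0, "10x": 0.1}
    )
    cnv_window: int = 101
    cnv_gain_cut: float = 0.2
    cnv_loss_cut: float = -0.2
    dmp_q: float = 0.05
    dmp_delta_beta: float = 0.20
    mds_top_cpgs: int = 1000
    tss_window: int = 1500

    def __post_init__(self) -> None:
        for name in ("de_top_n", "fc_min", "de_p", "de_q", "classifier_p",
                     "min_transcripts_per_cell", "min_cells_per_gene",
                     "n_features", "pc_p_cut", "cnv_window", "dmp_q",
                     "dmp_delta_beta", "mds_top_cpgs", "tss_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        for name in ("de_p", "de_q", "dmp_q", "dmp_delta_beta"):
            if not 0 < getattr(self, name) <= 1:
                raise ValidationError(f"threshold {name} must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    # multiple probe sets per symbol collapse to the per-gene maximum
    if df.index.has_duplicates:
        ndup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by per-gene maximum", ndup)
        df = df.groupby(level=0, sort=False).max()
    return df


def read_expression_matrix(path: str | Path, layout: str = "tsv_dense",
                           scale: str = "log2") -> ExpressionMatrix:
    """Read a dense TSV (first column ``gene``) or an MTX triplet directory.

    Duplicate gene symbols are collapsed by elementwise maximum with a logged
    warning. For ``mtx_triplet``, *path* is a directory containing
    ``matrix.mtx``, ``features.tsv`` and ``barcodes.tsv``; the result is
    sparse-backed and flagged ``raw_counts``.
    """
    path = Path(path)
    if layout == "tsv_dense":
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"{path}: {exc}") from exc
        if df.index.name is None or df.index.name.lower() != "gene":
            raise ParseError(f"{path}:1: header must start with a 'gene' column, "
                             f"got {df.index.name!r}")
        df.index = df.index.astype(str).str.upper()
        df = _collapse_duplicate_genes(df)
        return ExpressionMatrix(df.to_numpy(dtype=float), list(df.index),
                                list(df.columns), scale=scale)
    if layout == "mtx_triplet":
        mtx, feat, bar = path / "matrix.mtx", path / "features.tsv", path / "barcodes.tsv"
        for p in (mtx, feat, bar):
            if not p.exists():
                raise FileNotFoundError(p)
        values = sp.csr_matrix(scipy.io.mmread(mtx))
        genes = pd.read_csv(feat, sep="\t", header=None)[0].astype(str).str.upper()
        cells = pd.read_csv(bar, sep="\t", header=None)[0].astype(str)
        if values.shape != (len(genes), len(cells)):
            raise ParseError(
                f"{path}: matrix is {values.shape} but features/barcodes give "
                f"({len(genes)}, {len(cells)})"
            )
        if genes.duplicated().any():
            df = pd.DataFrame.sparse.from_spmatrix(values, index=genes)
            df = _collapse_duplicate_genes(pd.DataFrame(df.sparse.to_dense()))
            values = sp.csr_matrix(df.to_numpy())
            genes = df.index
        return ExpressionMatrix(values, list(genes), list(cells), scale="raw_counts")
    raise ValidationError(f"unknown layout {layout!r}")


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path,
                            layout: str = "tsv_dense") -> None:
    path = Path(path)
    if layout == "tsv_dense":
        df = expr.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")
    elif layout == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        vals = expr.values if sp.issparse(expr.values) else sp.csr_matrix(expr.values)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(vals))
        pd.Series(expr.gene_ids).to_csv(path / "features.tsv", sep="\t",
                                        header=False, index=False)
        pd.Series(expr.sample_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                          header=False, index=False)
    else:
        raise ValidationError(f"unknown layout {layout!r}")


def read_signature_collection(path: str | Path) -> SignatureCollection:
    """Read gene sets in GMT dialect: name TAB description TAB gene...."""
    sets: dict[str, list[str]] = {}
    prov: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated "
                                 f"fields, got {len(fields)}")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ValidationError(f"signature set {name!r} has no genes "
                                      f"({path}:{lineno})")
            sets[name] = genes
            prov[name] = desc
    return SignatureCollection(sets, prov)


def write_signature_collection(sig: SignatureCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sig.names():
            desc = sig.provenance.get(name, "")
            fh.write("\t".join([name, desc] + sig[name]) + "\n")


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """BED with extra columns: chrom, start, end, gene_id, arm, tss."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id", "arm", "tss"])
    df["gene_id"] = df["gene_id"].astype(str).str.upper()
    return GeneAnnotation(df.set_index("gene_id"))


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    out = ann.table.reset_index()[["chrom", "start", "end", "gene_id", "arm", "tss"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_beta_matrix(path: str | Path, manifest: str | Path) -> BetaMatrix:
    """Beta TSV (first column ``cpg``) plus a BED manifest of CpG positions."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    man = pd.read_csv(manifest, sep="\t", header=None,
                      names=["chrom", "start", "end", "cpg_id"])
    coords = man.set_index("cpg_id").rename(columns={"start": "pos"})[["chrom", "pos"]]
    coords = coords.reindex(df.index)
    if coords["pos"].isna().any():
        missing = coords.index[coords["pos"].isna()][:3].tolist()
        raise ParseError(f"manifest lacks coordinates for CpGs {missing}")
    return BetaMatrix(df.to_numpy(float), list(df.index), coords, list(df.columns))


def write_beta_matrix(beta: BetaMatrix, path: str | Path, manifest: str | Path) -> None:
    df = beta.to_frame()
    df.index.name = "cpg"
    df.to_csv(path, sep="\t")
    man = beta.cpg_coords.copy()
    man["start"] = man["pos"].astype(int)
    man["end"] = man["start"] + 1
    man["cpg_id"] = man.index
    man[["chrom", "start", "end", "cpg_id"]].to_csv(manifest, sep="\t",
                                                    header=False, index=False)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    if "sample_id" not in meta.columns:
        raise ParseError(f"{path}: metadata requires a 'sample_id' column")
    return meta.set_index("sample_id")


# ---------------------------------------------------------------------------
# Packaged resources
# ---------------------------------------------------------------------------


def _resource_path(name: str) -> Path:
    path = _ilres.files("gliostage.resources").joinpath(name)
    if not path.is_file():
        raise GliostageError(f"packaged resource {name!r} is missing — broken install")
    return Path(str(path))


def load_packaged_1p19q_classifier() -> SignatureCollection:
    """The printed 152-gene 1p19q co-deletion classifier, order-preserving."""
    genes = _resource_path("classifier_1p19q.txt").read_text().split()
    return SignatureCollection(
        {"classifier_1p19q": [g.upper() for g in genes]},
        {"classifier_1p19q": "transcriptome classifier of 1p19q co-deletion "
                             "(152 genes, REMBRANDT-derived)"},
    )


def load_packaged_marker_panels() -> SignatureCollection:
    return read_signature_collection(_resource_path("marker_panels.gmt"))


def load_packaged_stage_signatures() -> SignatureCollection:
    """Synthetic default OPC/COP/NFOL/MFOL/MO stage signatures (testing aid)."""
    return read_signature_collection(_resource_path("stage_signatures_synthetic.gmt"))


def load_packaged_empm_signatures() -> SignatureCollection:
    """Synthetic default EM/PM module signatures (testing aid)."""
    return read_signature_collection(_resource_path("empm_signatures_synthetic.gmt"))


def load_packaged_methylation_gene_sets() -> SignatureCollection:
    return read_signature_collection(_resource_path("methylation_gene_sets.gmt"))
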