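"""Synthetic cohorts carrying the statistical structure the pipeline assumes.

Three generators produce, without any external download:

* a bulk log2 expression cohort with NT / PM-codel / PM-noncodel / EM groups,
  a stage-graded oligodendrocyte-lineage program (up in OPC/COP, down in
  MFOL/MO and myelination genes) and hemizygous 1p/19q dosage loss in the
  codeleted group;
* a single-cell UMI count mixture of malignant OPC/COP-like cells (mostly
  quiescent, a small proliferating subset) with microglia / oligodendrocyte /
  T-cell contaminants and arm-level CNV truth;
* tumor and normal methylation beta matrices with hypermethylation
  concentrated at myelination-gene promoters and hypomethylation at
  OPC-regulator promoters, on a genome-wide hypermethylator background.

Every generator is fully deterministic given ``SimConfig.seed`` and returns
its ground truth alongside the data, so downstream modules can be tested by
parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model_io import (
    BetaMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    SignatureCollection,
    ValidationError,
    load_packaged_1p19q_classifier,
    load_packaged_empm_signatures,
    load_packaged_marker_panels,
    load_packaged_methylation_gene_sets,
    load_packaged_stage_signatures,
)

STAGE_ORDER = ["OPC", "COP", "NFOL", "MFOL", "MO"]

# synthetic genome: chromosome -> (length, centromere); coordinates are bp
CHROM_LENGTH = 200_000_000
CENTROMERE = 100_000_000


@dataclass
class SimConfig:
    """Parameters of the synthetic study conditions.

    Bulk defaults: 4 groups x 30 samples, log2 Gaussian noise sd 0.5, tumor
    purity 0.8 (attenuates the stage-program shifts; the hemizygous-loss
    factor 0.67 is applied directly — its default already reflects stromal
    dilution). Single-cell defaults: ~5000 UMIs/cell, negative-binomial
    counts, 6% of malignant cells proliferating, hemizygous 1p/19q loss at
    factor 0.5. Methylation defaults: +0.30 beta at hypermethylated CpGs,
    96:4 hyper:hypo truth ratio, beta noise sd 0.05.
    """

    seed: int = 0
    n_genes: int = 2000
    groups: Mapping[str, int] = field(default_factory=lambda: {
        "NT": 30, "PM_codel": 30, "PM_noncodel": 30, "EM": 30})
    stage_program: Mapping[str, float] = field(default_factory=lambda: {
        "PRE_OPC": 2.0, "OPC": 2.0, "COP": 1.5, "NFOL": 0.75,
        "MFOL": -1.0, "MO": -1.5})
    myelination_shift: float = -1.5
    module_shift: float = 2.0           # EM/PM co-expression module amplitude
    dosage_loss_factor: float = 0.67
    noise_sd: float = 0.5
    purity: float = 0.8
    # single cell
    sc_groups: Mapping[str, int] = field(default_factory=lambda: {
        "malignant": 500, "microglia": 60, "oligodendrocyte": 40, "t_cell": 30})
    sc_library_size: float = 5000.0
    sc_dispersion: float = 0.2
    prolif_fraction: float = 0.06
    sc_cnv_events: Mapping[str, float] = field(default_factory=lambda: {
        "1p": 0.5, "19q": 0.5})
    marker_mean: float = 8.0            # expected UMIs of an "on" marker gene
    marker_off: float = 0.05
    prolif_marker_mean: float = 24.0    # cycling cells express cycle genes highly
    # methylation
    n_cpgs: int = 4000
    n_samples_tumor: int = 20
    n_samples_normal: int = 20
    beta_hyper_delta: float = 0.30
    beta_noise_sd: float = 0.05
    n_extra_hyper: int = 405            # genome-wide hypermethylator background
    n_extra_hypo: int = 0

    def __post_init__(self) -> None:
        for name, counts in (("groups", self.groups), ("sc_groups", self.sc_groups)):
            for k, v in counts.items():
                if v < 0:
                    raise ValidationError(f"{name}[{k}] must be >= 0")
        if not 0 < self.dosage_loss_factor < 1:
            raise ValidationError("dosage_loss_factor must lie in (0, 1)")
        if not 0 <= self.prolif_fraction <= 1:
            raise ValidationError("prolif_fraction must lie in [0, 1]")
        if not 0 < self.purity <= 1:
            raise ValidationError("purity must lie in (0, 1]")
        if self.beta_hyper_delta >= 1:
            raise ValidationError("beta_hyper_delta must be < 1")
        if self.noise_sd < 0 or self.beta_noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")


@dataclass
class BulkSim:
    expr: ExpressionMatrix
    labels: pd.Series                 # sample_id -> group
    signatures: SignatureCollection   # stage + EM/PM + myelination truth sets
    annotation: GeneAnnotation
    config: SimConfig


@dataclass
class SingleCellSim:
    counts: ExpressionMatrix          # raw_counts, sparse
    cell_truth: pd.DataFrame          # cell_id, cell_type, proliferating, cnv arms
    annotation: GeneAnnotation
    panels: SignatureCollection
    config: SimConfig


@dataclass
class MethylSim:
    tumor: BetaMatrix
    normal: BetaMatrix
    truth_hyper: set[str]
    truth_hypo: set[str]
    annotation: GeneAnnotation
    gene_sets: SignatureCollection
    config: SimConfig


# ---------------------------------------------------------------------------
# Gene universe and synthetic annotation
# ---------------------------------------------------------------------------


def _known_gene_pool() -> tuple[list[str], SignatureCollection]:
    """All packaged signature/panel/classifier genes plus their collections."""
    stage = load_packaged_stage_signatures()
    empm = load_packaged_empm_signatures()
    panels = load_packaged_marker_panels()
    methyl = load_packaged_methylation_gene_sets()
    classifier = load_packaged_1p19q_classifier()
    sets: dict[str, list[str]] = {}
    prov: dict[str, str] = {}
    # stage signatures listed first: on a name clash (the OPC/COP marker
    # panels share names with the stage sets) the stage set wins
    for coll in (stage, empm, panels, methyl, classifier):
        for name in coll.names():
            if name not in sets:
                sets[name] = coll[name]
                prov[name] = coll.provenance.get(name, "")
    ordered: dict[str, None] = {}
    for genes in sets.values():
        for g in genes:
            ordered.setdefault(g, None)
    ordered.setdefault("SOX2", None)
    return list(ordered), SignatureCollection(sets, prov)


def build_gene_universe(config: SimConfig) -> tuple[list[str], SignatureCollection]:
    """Packaged panel genes plus GENE#### filler up to ``n_genes``."""
    known, sigs = _known_gene_pool()
    if config.n_genes < len(known):
        raise ValidationError(
            f"n_genes={config.n_genes} smaller than the {len(known)} packaged "
            "signature genes; raise n_genes")
    filler = [f"GENE{i:04d}" for i in range(config.n_genes - len(known))]
    return known + filler, sigs


def synthetic_gene_annotation(genes: list[str], classifier: list[str],
                              chroms: tuple[str, ...] = tuple(
                                  f"chr{c}" for c in (2, 3, 4, 5, 6, 7, 10, 11, 12, 14)),
                              forced_arms: Mapping[str, str] | None = None,
                              ) -> GeneAnnotation:
    """Place most classifier genes on 1p / 19q and everything else elsewhere.

    Two of every three classifier genes go to the chr1 p arm / chr19 q arm
    (alternating); the remaining third joins the ordinary genes, mirroring
    the real classifier's minority of off-arm members. Ordinary genes are
    distributed round-robin over *chroms* with arms implied by a centromere
    at 100 Mb. Coordinates are synthetic but honor start < end and the
    0-based half-open convention.
    """
    cls = {g: i for i, g in enumerate(classifier)}
    rows = []
    i1 = i19 = 0
    per_chrom = {c: 0 for c in chroms}
    j = 0
    for g in genes:
        if g in cls and cls[g] % 3 != 2:
            if (i1 + i19) % 2 == 0:
                start = 1_000_000 + i1 * 100_000
                rows.append((g, "chr1", "p", start))
                i1 += 1
            else:
                start = CENTROMERE + 20_000_000 + i19 * 100_000
                rows.append((g, "chr19", "q", start))
                i19 += 1
        else:
            c = chroms[j % len(chroms)]
            k = per_chrom[c]
            start = 1_000_000 + k * 100_000
            forced = (forced_arms or {}).get(c)
            if forced == "q" or (forced is None and k % 2 == 1):
                start += CENTROMERE  # alternate arms unless one is forced
            rows.append((g, c, "p" if start < CENTROMERE else "q", start))
            per_chrom[c] += 1
            j += 1
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "arm", "start"])
    df["end"] = df["start"] + 10_000
    df["tss"] = df["start"]
    return GeneAnnotation(df.set_index("gene_id")[["chrom", "start", "end", "arm", "tss"]])


def centromere_table() -> dict[str, int]:
    return {f"chr{c}": CENTROMERE for c in list(range(1, 23)) + ["X", "Y"]}


# ---------------------------------------------------------------------------
# Bulk cohort
# ---------------------------------------------------------------------------


def simulate_bulk_cohort(config: SimConfig) -> BulkSim:
    """Bulk log2 cohort with stage-graded programs and 1p/19q dosage loss.

    PM samples carry the (purity-attenuated) ``stage_program`` shifts on the
    stage-signature genes, the PM module up and myelination genes down;
    PM_codel samples additionally have every gene annotated to 1p or 19q
    multiplied by ``dosage_loss_factor`` (a log2 shift of
    ``log2(dosage_loss_factor)``) before noise. EM samples carry the EM
    module. NT is baseline.
    """
    if "NT" not in config.groups:
        raise ValidationError("groups must include NT")
    tumor_groups = [g for g in config.groups if g != "NT"]
    if not tumor_groups:
        raise ValidationError("groups must include at least one tumor group")

    genes, sigs = build_gene_universe(config)
    for name in list(config.stage_program) + ["EM", "PM", "MYELINATION"]:
        if name not in sigs.names():
            raise ValidationError(f"stage/module set {name!r} absent from the "
                                  "signature universe")
    ann = synthetic_gene_annotation(genes, sigs["classifier_1p19q"])

    rng = np.random.default_rng(config.seed)
    gi = pd.Index(genes)
    baseline = rng.normal(7.0, 1.0, size=len(genes))

    def idx(names: list[str]) -> np.ndarray:
        return gi.get_indexer([g for g in names if g in gi])

    shift = {}  # group -> per-gene additive log2 effect
    for grp in config.groups:
        eff = np.zeros(len(genes))
        if grp.startswith("PM"):
            for stage, s in config.stage_program.items():
                eff[idx(sigs[stage])] += config.purity * s
            eff[idx(sigs["MYELINATION"])] += config.purity * config.myelination_shift
            eff[idx(sigs["PM"])] += config.purity * config.module_shift
        elif grp == "EM":
            eff[idx(sigs["EM"])] += config.purity * config.module_shift
        if grp == "PM_codel":
            lost = ann.genes_on_arms(["1p", "19q"])
            eff[idx(lost)] += np.log2(config.dosage_loss_factor)
        shift[grp] = eff

    cols, labels, blocks = [], [], []
    for grp, n in config.groups.items():
        mu = baseline[:, None] + shift[grp][:, None]
        blocks.append(mu + rng.normal(0.0, config.noise_sd, size=(len(genes), n)))
        cols += [f"{grp}_{i + 1:02d}" for i in range(n)]
        labels += [grp] * n
    values = np.concatenate(blocks, axis=1)
    expr = ExpressionMatrix(values, genes, cols, scale="log2")
    return BulkSim(expr, pd.Series(labels, index=cols, name="group"), sigs, ann, config)


# ---------------------------------------------------------------------------
# Single-cell mixture
# ---------------------------------------------------------------------------

_SC_CHROMS = ("chr1", "chr19", "chr2", "chr7", "chr10", "chr11")


def _sc_annotation(genes: list[str], classifier: list[str]) -> GeneAnnotation:
    # compact 6-chromosome layout so the CNV moving-average window always
    # fits; chr1 carries only its p arm and chr19 only its q arm so the
    # simulated arm events cover whole chromosomes of genes
    return synthetic_gene_annotation(
        genes, classifier,
        chroms=("chr1", "chr19", "chr2", "chr7", "chr10", "chr11"),
        forced_arms={"chr1": "p", "chr19": "q"})


def _sc_expected_counts(config: SimConfig, genes: list[str],
                        sigs: SignatureCollection) -> pd.DataFrame:
    """Expected UMI counts per gene for a pure cell of each population."""
    gi = pd.Index(genes)
    rng = np.random.default_rng(config.seed + 1_000_003)
    base = rng.lognormal(mean=0.0, sigma=0.5, size=len(genes))

    marker_sets = {
        "malignant": (["PRE_OPC", "OPC", "COP"], ["SOX2"]),
        "microglia": (["MICROGLIA"], []),
        "oligodendrocyte": (["OLIGODENDROCYTE", "MO", "MYELINATION"], []),
        "t_cell": (["T_CELL"], []),
        # pure lineage-stage profiles, used for reference staging
        "ref_OPC": (["OPC"], []),
        "ref_COP": (["COP"], []),
        "ref_NFOL": (["NFOL"], []),
        "ref_MFOL": (["MFOL"], []),
        "ref_MO": (["MO", "MYELINATION", "OLIGODENDROCYTE"], []),
    }
    all_panel_genes: set[str] = set()
    for pn in (list(load_packaged_marker_panels().names())
               + ["OPC", "COP", "NFOL", "MFOL", "MO", "MYELINATION"]):
        all_panel_genes.update(sigs[pn])
    all_panel_genes.add("SOX2")

    profiles = {}
    for pop, (panel_names, extra) in marker_sets.items():
        on = set(extra)
        for pn in panel_names:
            on.update(sigs[pn])
        if pop == "malignant":
            # graded lineage program: strong OPC/COP, weak NFOL, silent MFOL/MO
            graded = {"OPC": 1.0, "COP": 0.8, "NFOL": 0.15, "MFOL": 0.0, "MO": 0.0}
        else:
            graded = {}
        rate = base.copy()
        for g_idx, g in enumerate(genes):
            if g in all_panel_genes:
                rate[g_idx] = config.marker_off
        for g in on:
            if g in gi:
                rate[gi.get_loc(g)] = config.marker_mean
        for stage, frac in graded.items():
            for g in sigs[stage]:
                if g in gi:
                    rate[gi.get_loc(g)] = max(rate[gi.get_loc(g)],
                                              frac * config.marker_mean)
        # scale filler background so the cell totals ~ sc_library_size
        is_bg = ~gi.isin(list(all_panel_genes))
        bg_target = max(config.sc_library_size - rate[~is_bg].sum(), 1.0)
        rate[is_bg] *= bg_target / rate[is_bg].sum()
        profiles[pop] = rate
    return pd.DataFrame(profiles, index=gi)


def simulate_single_cell(config: SimConfig) -> SingleCellSim:
    """Negative-binomial UMI mixture with arm-level CNV and proliferation truth.

    Malignant cells over-express SOX2 and the pre-OPC/OPC/COP panels with a
    graded lineage program; a ``prolif_fraction`` subset additionally switches
    on MKI67/TOP2A/CCNB2/CDK1. ``sc_cnv_events`` (arm -> dosage factor) is
    applied to malignant cells' expected counts. Contaminant populations
    express their canonical panels. Counts are NB with cell-specific library
    factors; fully deterministic given the seed.
    """
    genes, sigs = build_gene_universe(config)
    ann = _sc_annotation(genes, sigs["classifier_1p19q"])
    profiles = _sc_expected_counts(config, genes, sigs)
    panels = load_packaged_marker_panels()
    prolif_genes = [g for g in panels["PROLIFERATION"] if g in profiles.index]

    rng = np.random.default_rng(config.seed)
    arm_label = ann.arm_of()
    cnv_mult = np.ones(len(genes))
    for arm, factor in config.sc_cnv_events.items():
        cnv_mult[arm_label.isin([arm]).to_numpy()] = factor

    cells, types, prolif_flags, blocks = [], [], [], []
    r = 1.0 / config.sc_dispersion
    for pop, n in config.sc_groups.items():
        if n == 0:
            continue
        if pop not in profiles.columns:
            raise ValidationError(f"unknown single-cell population {pop!r}")
        mu_base = profiles[pop].to_numpy().copy()
        for i in range(n):
            cid = f"{pop}_{i + 1:04d}"
            mu = mu_base.copy()
            is_prolif = False
            if pop == "malignant":
                mu = mu * cnv_mult
                is_prolif = bool(rng.random() < config.prolif_fraction)
                pidx = profiles.index.get_indexer(prolif_genes)
                mu[pidx] = config.prolif_marker_mean if is_prolif else 0.01
            lib = rng.lognormal(mean=0.0, sigma=0.3)
            mu = np.maximum(mu * lib, 1e-9)
            # NB as Gamma-Poisson
            lam = rng.gamma(shape=r, scale=mu / r)
            blocks.append(rng.poisson(lam).astype(np.int32))
            cells.append(cid)
            types.append(pop)
            prolif_flags.append(is_prolif)
    if not cells:
        raise ValidationError("no cells requested")
    values = sp.csr_matrix(np.column_stack(blocks))
    counts = ExpressionMatrix(values, genes, cells, scale="raw_counts")
    truth = pd.DataFrame({
        "cell_id": cells,
        "cell_type": types,
        "malignant": [t == "malignant" for t in types],
        "proliferating": prolif_flags,
        "cnv_events": [";".join(f"{a}:{'loss' if f < 1 else 'gain'}"
                                for a, f in config.sc_cnv_events.items() if f != 1.0)
                       if t == "malignant" else ""
                       for t in types],
    }).set_index("cell_id")
    return SingleCellSim(counts, truth, ann, panels, config)


def stage_reference_profiles(config: SimConfig) -> pd.DataFrame:
    """Expected log-normalized profile of a pure cell at each lineage stage.

    Genes x stages (OPC, COP, NFOL, MFOL, MO); values are log1p of expected
    counts-per-10k under the generative model, for use as the reference in
    stage correlation.
    """
    genes, sigs = build_gene_universe(config)
    profiles = _sc_expected_counts(config, genes, sigs)
    ref = profiles[[f"ref_{s}" for s in STAGE_ORDER]]
    ref.columns = STAGE_ORDER
    cp10k = ref / ref.sum(axis=0) * 1e4
    return np.log1p(cp10k)


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------


def simulate_methylomes(config: SimConfig) -> MethylSim:
    """Tumor/normal beta matrices with promoter-targeted differential CpGs.

    Three CpGs are placed within +-1 kb of each myelination-gene TSS (tumor
    beta shifted up by ``beta_hyper_delta``) and of each OPC-regulator TSS
    (shifted down); ``n_extra_hyper``/``n_extra_hypo`` background CpGs model
    the genome-wide hypermethylator phenotype. All values are clipped to
    [0, 1]; deterministic given the seed.
    """
    genes, sigs = build_gene_universe(config)
    ann = synthetic_gene_annotation(genes, sigs["classifier_1p19q"])
    gene_sets = load_packaged_methylation_gene_sets()
    rng = np.random.default_rng(config.seed + 7)

    rows: list[tuple[str, str, int, str]] = []  # cpg_id, chrom, pos, role

    def add_promoter_cpgs(gene_list: list[str], role: str) -> None:
        for g in gene_list:
            if g not in ann.genes:
                continue
            row = ann.table.loc[g]
            for k, off in enumerate((0, 500, 1000)):
                rows.append((f"cg_{g}_{k}", str(row["chrom"]),
                             int(row["tss"]) + off, role))

    add_promoter_cpgs(gene_sets["MYELINATION"], "hyper")
    add_promoter_cpgs(gene_sets["OPC_REGULATORS"], "hypo")
    for i in range(config.n_extra_hyper):
        rows.append((f"cg_bgh_{i:05d}", "chr4", 150_000_000 + i * 1000, "hyper"))
    for i in range(config.n_extra_hypo):
        rows.append((f"cg_bgl_{i:05d}", "chr5", 150_000_000 + i * 1000, "hypo"))
    n_neutral = config.n_cpgs - len(rows)
    if n_neutral < 0:
        raise ValidationError("n_cpgs too small for the requested DMP truth sets")
    for i in range(n_neutral):
        rows.append((f"cg_bg_{i:05d}", "chr6", 10_000_000 + i * 1000, "neutral"))

    ids = [r[0] for r in rows]
    roles = np.array([r[3] for r in rows])
    coords = pd.DataFrame({"chrom": [r[1] for r in rows],
                           "pos": [r[2] for r in rows]}, index=ids)

    normal_mean = np.where(
        roles == "hyper", rng.uniform(0.10, 0.55, len(ids)),
        np.where(roles == "hypo", rng.uniform(0.45, 0.90, len(ids)),
                 rng.uniform(0.05, 0.95, len(ids))))
    delta = np.where(roles == "hyper", config.beta_hyper_delta,
                     np.where(roles == "hypo", -config.beta_hyper_delta, 0.0))
    tumor_mean = np.clip(normal_mean + delta, 0.0, 1.0)

    def draw(mean: np.ndarray, n: int, tag: str) -> BetaMatrix:
        vals = mean[:, None] + rng.normal(0.0, config.beta_noise_sd, (len(ids), n))
        vals = np.clip(vals, 0.0, 1.0)
        samples = [f"{tag}_{i + 1:02d}" for i in range(n)]
        return BetaMatrix(vals, ids, coords, samples)

    tumor = draw(tumor_mean, config.n_samples_tumor, "tumor")
    normal = draw(normal_mean, config.n_samples_normal, "normal")
    return MethylSim(tumor, normal,
                     set(np.array(ids)[roles == "hyper"]),
                     set(np.array(ids)[roles == "hypo"]),
                     ann, gene_sets, config)


# ---------------------------------------------------------------------------
# Sidecar truth output
# ---------------------------------------------------------------------------


def write_truth_json(obj: BulkSim | SingleCellSim | MethylSim, path: str | Path) -> None:
    if isinstance(obj, BulkSim):
        truth = {"kind": "bulk", "labels": obj.labels.to_dict()}
    elif isinstance(obj, SingleCellSim):
        truth = {"kind": "single_cell",
                 "cells": obj.cell_truth.reset_index().to_dict(orient="list")}
    else:
        truth = {"kind": "methyl", "hyper": sorted(obj.truth_hyper),
                 "hypo": sorted(obj.truth_hypo)}
    Path(path).write_text(json.dumps(truth, indent=1))
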