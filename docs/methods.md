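# Methods

`gliostage` re-implements, as a tested library, the computational chain used
to show that IDH-mutant ("PM", PDGFRA-module) gliomas are composed of cells
resembling early oligodendrocyte-lineage stages (OPC/COP) and are blocked
before myelination. This note documents the models, the defaults and the
reasoning behind the open design choices. No empirical claim is made here
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## Bulk signatures (module `bulk_signatures`)

Differential expression between a tumor group and non-tumor (NT) brain is a
per-gene two-sample t-test on log2-scale values with Benjamini–Hochberg
adjustment over all tested genes. The *Welch* (unequal-variance) form is
used; the upstream workflow specifies only "t-test", and Welch is the safer
default when tumor and control cohorts differ in dispersion. Genes with zero
variance in both groups are reported as t = 0, p = 1 rather than NaN.

Gene ranking for top-N selection is by ascending p, with ties broken by
descending |t| and then lexicographic gene id, making selection fully
deterministic. "Concordantly enriched" genes between the two PM subtypes are
the intersection of the two top-N up-regulated lists after a fold-change
floor (FC ≥ 1.5, i.e. log2FC ≥ 0.585).

The **stage-enrichment percentage** of a signature is

    100 · |{g ∈ S ∩ U : q_g < 0.05, log2FC_g ≥ log2 1.5, up}| / |S ∩ U|

with U the tested gene universe. "Enriched" is deliberately the joint
q/FC/direction condition; the per-dataset p/q cutoffs in the original
heatmaps are dataset-specific, so q < 0.05 is the package default and a
`Thresholds` field, not a constant. Across the ordered stages
OPC → COP → NFOL → MFOL → MO this percentage is expected to decline in PM
tumors; the acceptance suite asserts monotone non-increase on synthetic
cohorts.

Probe-set multiplicity is resolved before any statistics: duplicate gene
rows collapse to the per-gene elementwise maximum at load time (logged),
which is order-independent and keeps the best-detected probe per gene.

## Two-tier subtype classification (module `ontogeny_classifier`)

Tier 1 separates EM (EGFR-module) from PM (PDGFRA-module) samples; tier 2
separates PM samples into 1p19q-codeleted vs non-codeleted. Both tiers use
one deterministic recipe: restrict to the signature genes, median-center
each gene across samples, compute 1 − Pearson correlation between samples,
and cut a Ward agglomerative tree at k = 2. The clustering algorithm is not
specified upstream; Ward on correlation distance is the standard
expression-subtyping recipe and has no stochastic step, so repeated runs and
sample reorderings give identical calls.

Tier-1 orientation uses a *module score* per sample: mean expression of the
PM signature minus the sample's transcriptome-wide mean, less the same
quantity for the EM signature. If the two clusters' mean scores differ by at
least `min_split_margin` (default 0.5 log2 units) the higher-scoring cluster
is PM; otherwise the cohort is treated as homogeneous and every sample
receives the class of the cohort-wide mean score. This prevents an EM-only
or PM-only cohort from being force-split by a k = 2 cut of pure noise.

Tier-2 orientation is biological rather than trained: hemizygous loss of
1p/19q lowers the expression of classifier genes residing on those arms, so
the cluster with the lower mean expression of 1p/19q-annotated classifier
genes is labeled codeleted. A zero margin raises an error instead of
guessing, with the advice to supply reference centroids. The packaged
classifier is the printed 152-gene list; legacy identifiers that fail to
match a given matrix are dropped with a logged count, never remapped, since
alias expansion would silently change set sizes.

`derive_1p19q_classifier` exposes the derivation recipe (both-direction
t-test at a stringent p cutoff, default 1e-16) for users with labeled
cohorts; note that desk-scale synthetic cohorts rarely reach p = 1e-16, so
the utility returns an empty list rather than erroring at cutoffs beyond the
cohort's power.

## Single-cell staging (module `sc_staging`)

QC follows the strict-inequality reading of the upstream rule: cells with
total UMIs < 200 are removed first, then genes detected in < 3 cells.
Normalization is counts-per-10k + log1p; the 500 most variable genes are
z-scaled and reduced by PCA. The upstream "principal components with
p < 1e-10" rule is Seurat-specific; it is replaced by a deterministic
Kaiser-style rule (components whose explained-variance ratio exceeds the
uniform expectation, floored at 10) with the retained count logged.
Clustering is Leiden on the kNN graph with a fixed seed; the default
resolution (0.3) keeps homogeneous populations intact on data of this
separation while still isolating contaminant populations and the
proliferating subpopulation.

Cluster typing is arg-max over marker-panel scores (mean over cells of the
mean normalized expression of panel genes), with the proliferation panel
excluded from typing. The positivity floor below which a cluster is
`unassigned` is the 90th percentile of the best cluster score across 100
random same-size gene panels — a permutation null, since no floor is given
upstream.

Malignancy requires *both* lines of evidence: cluster-level SOX2 positivity
above the highest level seen in any immune/oligodendrocyte cluster, and an
arm-level CNV event in at least half the cluster's cells.
Immune/oligodendrocyte-typed clusters are never called malignant, so
sporadic single-cell SOX2 noise cannot flip them. Proliferation is per cell
and conjunctive: every marker of the panel detected (> 0). The 4-gene panel
{MKI67, TOP2A, CCNB2, CDK1} is the default (the Methods-style 3-gene variant
is a configuration away).

Stage assignment correlates a cluster's mean log-normalized profile with
per-stage reference profiles (Pearson, over the shared-gene intersection,
≥ 30 genes). Constant vectors raise an undefined-correlation error — never a
silent r = 0.

## Expression-based CNV (module `cnv_expression`)

Per gene: log-normalized expression centered by the reference-cell mean and
converted to log2 units; values clipped to ±clip; genes ordered by (chrom,
start, gene id); a centered moving average of `window` genes (default 101)
applied within each chromosome, truncated at the ends; each cell re-centered
by its median smoothed value. The per-platform "cutoff parameters" 1.0 /
1.0 / 0.1 (STRT-seq / Smart-seq2 / 10X) are implemented as the per-gene clip
bound — the closest well-defined reading of the wrapped tool's parameters —
and 1.0 is the default. Whether the original analysis re-centered per cell
by the median is not stated; the median re-centering here is this package's
choice and is flagged as such.

Arm calls threshold the per-arm mean of the smoothed profile at ±0.2 log2
units (no call thresholds are given upstream, which shows heatmaps; ±0.2
satisfies a < 5% false arm-event rate on matched null simulations, verified
in the acceptance suite). Note the interaction with the clip bound: with the
10X clip of 0.1 the smoothed profile cannot exceed ±0.1 and the ±0.2
thresholds can never fire; arm calling is meant to run at clip 1.0.

## Methylation (module `methylation`)

Inputs are pre-normalized beta matrices (the package does not parse IDATs).
A DMP must jointly satisfy BH-adjusted Welch-t p < 0.05 and |Δβ| > 0.20,
with Δβ = tumor mean − normal mean; "methylation difference > 20%" is read
as 0.20 in absolute beta units (the standard reading; a relative reading
would be a different filter). Tests are on beta values, not M-values, for
symmetry with the expression module; the statistic is swappable. The BH
routine is a single shared function (`bulk_signatures.bh_qvalues`) used by
both expression and methylation paths and is tested against a brute-force
implementation.

Promoter status maps DMPs to genes within ±1500 bp of the TSS (the
promoter-window convention; upstream says only "TSS/CpG island regions") and
takes a strict majority: hyper if > 50% of mapped DMPs are hyper, hypo
symmetrically, mixed at exactly 50%, none without a mapped DMP.

Cohort geometry uses classical (Torgerson) MDS — principal-coordinates
analysis of Euclidean sample distances over the top-1000 most variable
CpGs — with axis signs canonicalized so the first sample's coordinates are
non-negative, making the output deterministic up to reflection.

## Synthetic data (module `synthetic_data`)

The generator produces the statistical structure the pipeline assumes, with
ground truth, so every downstream stage is testable by parameter recovery.
It does **not** emulate doublets, ambient RNA, batch effects, probe
cross-hybridization, or realistic gene-gene correlation beyond the planted
programs — passing tests demonstrate correct recovery of the planted
structure, not performance on real tissue.

Bulk cohorts are Gaussian on the log2 scale (matching log-space t-tests on
array-style data): per-gene baselines ~ N(7, 1), four groups (NT, PM-codel,
PM-noncodel, EM) of 30 samples, noise sd 0.5. PM samples carry the stage
program (+2.0 pre-OPC/OPC, +1.5 COP, +0.75 NFOL, −1.0 MFOL, −1.5 MO and
myelination genes, in log2 units) and the PM module (+2.0); EM samples carry
the EM module. Tumor purity (default 0.8) attenuates these program shifts —
a bulk tumor is a tumor/stroma mixture — but the hemizygous-loss factor
(default 0.67 ≈ 2/3 dosage) is applied directly to every gene annotated to
1p/19q, because that default already reflects stromal dilution of a true
0.5 dosage; a noiseless run with factor 0.5 therefore shows an exact −1
log2 shift. Two of every three classifier genes are placed on 1p/19q and
the rest elsewhere, mirroring the real list's minority of off-arm members;
this matters because a dosage shift applied to *all* signature genes would
be invisible to correlation-based clustering.

Single-cell counts are negative binomial (Gamma–Poisson, dispersion 0.2)
with lognormal cell-specific library factors around ~5000 UMIs. "On" marker
genes have expected count 8; proliferation markers in cycling cells have
expected count 24 (cycling cells express cycle genes abundantly — this keeps
the conjunctive detection rule's sensitivity near 1 so that a planted 6%
cycling fraction is recovered as ~6%, not as 6% times a detection loss);
"off" panel genes 0.05; background genes share the remaining library.
Malignant cells express SOX2, the pre-OPC/OPC/COP panels and a graded
lineage program (OPC 1.0, COP 0.8, NFOL 0.15, MFOL/MO 0), and carry
arm-level dosage factors (default 1p and 19q at 0.5). The compact synthetic
genome uses 6 chromosomes so the 101-gene smoothing window always fits, with
chr1 all-p-arm and chr19 all-q-arm so the planted events are clean arm
events.

Methylomes place 3 CpGs within +1 kb of each myelination-gene TSS (tumor
β + 0.30) and each OPC-regulator TSS (−0.30), plus 405 background
hypermethylated CpGs — giving a 96:4 hyper:hypo truth ratio, the
hypermethylator phenotype — among ~4000 total CpGs; β noise is Gaussian
(sd 0.05) clipped to [0, 1]. Cohorts are 20 tumor vs 20 normal samples.

All generators are deterministic given `SimConfig.seed` (single
`numpy.random.default_rng` stream per generator).

## Problem sizes in the acceptance script

`scripts/acceptance.py` regenerates everything from scratch: 20 bulk
cohorts (120 samples × 2000 genes) for classification accuracy, one
single-cell mixture (630 cells) for the CNV/malignancy/staging chain plus
20 matched null mixtures for the false-call rate, 10 samples × 500 malignant
cells for proliferation, and one 4000-CpG methylome cohort plus 50 null
cohorts for DMP error control. These sizes give stable estimates (binomial
SEs of a few percent or less) while the whole script completes in about a
minute on one CPU.

## Known limitations

* Gene matching is upper-case exact; symbols that drifted across annotation
  eras (e.g. the classifier's legacy identifiers) are dropped, not remapped.
* The CNV module calls whole arms only; breakpoint-level segmentation,
  subclone trees and allele-specific CNV are out of scope.
* The methylation module consumes beta matrices; IDAT parsing, dasen
  normalization and DMR (region-level) detection are out of scope.
* The EM/PM signatures shipped in `resources/` are synthetic stand-ins for
  testing (anchor markers plus `SYN*` filler symbols, marked as such);
  real analyses should supply the published module signatures.
* The O/C1 vs O/C2 subpopulation distinction (sporadic astrocytic-gene
  expression within malignant cells) is reported descriptively via
  per-cluster astrocyte-panel scores; no hard call is made because no
  decision rule exists upstream.
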