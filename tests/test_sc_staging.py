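import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import gliostage as gs
from gliostage.data_model_io import ValidationError


def _counts(arr, genes=None, cells=None):
    arr = np.asarray(arr)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return gs.ExpressionMatrix(sp.csr_matrix(arr), genes, cells,
                               scale="raw_counts")


def brute_force_qc(arr, min_umi=200, min_cells=3):
    keep_cells = arr.sum(axis=0) >= min_umi
    sub = arr[:, keep_cells]
    keep_genes = (sub > 0).sum(axis=1) >= min_cells
    return keep_genes, keep_cells


class TestQCFilter:
    def test_cell_umi_boundary(self):
        arr = np.zeros((5, 3), dtype=int)
        arr[0, 0] = 199     # below
        arr[0, 1] = 200     # at threshold -> retained
        arr[0, 2] = 500
        arr[1:, 2] = 1      # keep gene 0 detected in >=3 cells? no, cells first
        out, report = gs.qc_filter(_counts(arr))
        assert "c0" in report.removed_cells
        assert "c1" in out.sample_ids and "c2" in out.sample_ids

    def test_gene_detection_boundary(self):
        arr = np.zeros((3, 4), dtype=int)
        arr[0] = [300, 300, 300, 300]   # detected in 4 cells
        arr[1] = [300, 300, 300, 0]     # 3 cells -> retained
        arr[2] = [300, 300, 0, 0]       # 2 cells -> removed
        out, report = gs.qc_filter(_counts(arr))
        assert out.gene_ids == ["G0", "G1"]
        assert report.removed_genes == ["G2"]

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            arr = rng.poisson(30, size=(rng.integers(4, 12),
                                        rng.integers(4, 12)))
            try:
                out, _ = gs.qc_filter(_counts(arr))
            except ValidationError:
                assert not (arr.sum(axis=0) >= 200).any()
                continue
            keep_genes, keep_cells = brute_force_qc(arr)
            np.testing.assert_array_equal(out.dense(),
                                          arr[keep_genes][:, keep_cells])

    def test_all_cells_removed_mentions_threshold(self):
        with pytest.raises(ValidationError, match="200"):
            gs.qc_filter(_counts(np.ones((3, 3), dtype=int)))


class TestNormalizeAndEmbed:
    def test_normalization_sums_to_target(self, sc_pipeline):
        filtered, _, emb = sc_pipeline
        pre_log = np.expm1(emb.normalized.dense())
        np.testing.assert_allclose(pre_log.sum(axis=0), 1e4, rtol=1e-6)

    def test_same_seed_identical_labels(self, sc_pipeline):
        filtered, _, emb = sc_pipeline
        again = gs.normalize_and_embed(filtered, seed=7)
        pd.testing.assert_series_equal(emb.clusters, again.clusters)

    def test_two_separated_populations_recovered_exactly(self):
        cfg = gs.SimConfig(seed=5, prolif_fraction=0.0,
                           sc_groups={"malignant": 300, "microglia": 100})
        sim = gs.simulate_single_cell(cfg)
        filtered, _ = gs.qc_filter(sim.counts)
        emb = gs.normalize_and_embed(filtered, seed=7)
        truth = sim.cell_truth.loc[filtered.sample_ids, "cell_type"]
        from sklearn.metrics import adjusted_rand_score
        assert emb.clusters.nunique() == 2
        assert adjusted_rand_score(truth, emb.clusters) == 1.0

    def test_log_normalize_requires_counts(self, sc_pipeline):
        _, _, emb = sc_pipeline
        with pytest.raises(ValidationError):
            gs.log_normalize(emb.normalized)


class TestAnnotateClusters:
    def test_contaminant_types_recovered(self, sc_sim, sc_pipeline):
        filtered, _, emb = sc_pipeline
        anns = gs.annotate_clusters(emb.normalized, emb.clusters,
                                    sc_sim.panels, seed=7)
        df = gs.annotations_to_frame(anns)
        truth = sc_sim.cell_truth.loc[filtered.sample_ids]
        for sim_type, called in (("microglia", "microglia"),
                                 ("oligodendrocyte", "oligodendrocyte"),
                                 ("t_cell", "T_cell")):
            cells = truth.index[truth["cell_type"] == sim_type]
            assert (df.loc[cells, "cell_type"] == called).mean() > 0.9
        mal = truth.index[truth["cell_type"] == "malignant"]
        assert df.loc[mal, "cell_type"].isin(["pre-OPC", "OPC", "COP"]).mean() > 0.9

    def test_single_positive_marker_is_not_proliferating(self):
        genes = ["MKI67", "TOP2A", "CCNB2", "CDK1", "OTHER"]
        arr = np.zeros((5, 2))
        arr[0, 0] = 5.0            # MKI67 only
        arr[:4, 1] = 3.0           # all four
        mat = gs.ExpressionMatrix(arr, genes, ["c0", "c1"], scale="log2")
        flags = gs.proliferating_cells(mat, ["MKI67", "TOP2A", "CCNB2", "CDK1"])
        assert not flags["c0"] and flags["c1"]

    def test_all_zero_cluster_unassigned(self, sc_sim):
        rng = np.random.default_rng(0)
        genes = sc_sim.counts.gene_ids[:400]
        vals = np.abs(rng.normal(1.0, 0.3, size=(400, 40)))
        vals[:, 20:] = 0.0         # second cluster silent
        mat = gs.ExpressionMatrix(vals, genes, [f"c{i}" for i in range(40)],
                                  scale="log2")
        clusters = pd.Series([0] * 20 + [1] * 20, index=mat.sample_ids)
        anns = gs.annotate_clusters(mat, clusters, sc_sim.panels, seed=0)
        assert all(a.cell_type == "unassigned" for a in anns
                   if a.cluster == 1)


@pytest.fixture(scope="module")
def annotated(sc_sim, sc_pipeline):
    filtered, _, emb = sc_pipeline
    anns = gs.annotate_clusters(emb.normalized, emb.clusters,
                                sc_sim.panels, seed=7)
    truth = sc_sim.cell_truth.loc[filtered.sample_ids]
    refs = truth.index[~truth["malignant"]].tolist()
    profile = gs.infer_cnv(emb.normalized, refs, sc_sim.annotation,
                           window=101, clip=1.0)
    calls = gs.call_arm_events(profile)
    return gs.call_malignant(anns, emb.normalized, calls), truth


class TestCallMalignant:
    def test_truth_malignant_recovered(self, annotated):
        anns, truth = annotated
        df = gs.annotations_to_frame(anns)
        mal = truth.index[truth["malignant"]]
        non = truth.index[~truth["malignant"]]
        assert df.loc[mal, "malignant"].mean() > 0.95
        assert not df.loc[non, "malignant"].any()

    def test_no_cnv_and_uniform_sox2_yields_no_calls(self, sc_sim, sc_pipeline):
        filtered, _, emb = sc_pipeline
        anns = gs.annotate_clusters(emb.normalized, emb.clusters,
                                    sc_sim.panels, seed=7)
        neutral = pd.DataFrame("neutral", index=emb.normalized.sample_ids,
                               columns=["1p", "19q"])
        flat_vals = np.ones((emb.normalized.n_genes, emb.normalized.n_samples))
        flat = gs.ExpressionMatrix(flat_vals, emb.normalized.gene_ids,
                                   emb.normalized.sample_ids, scale="log2")
        out = gs.call_malignant(anns, flat, neutral)
        assert not any(a.malignant for a in out)

    def test_missing_reference_cluster_raises(self, sc_sim, sc_pipeline):
        filtered, _, emb = sc_pipeline
        anns = gs.annotate_clusters(emb.normalized, emb.clusters,
                                    sc_sim.panels, seed=7)
        for a in anns:
            a.cell_type = "OPC"
        neutral = pd.DataFrame("neutral", index=emb.normalized.sample_ids,
                               columns=["1p"])
        with pytest.raises(ValidationError, match="reference"):
            gs.call_malignant(anns, emb.normalized, neutral)


class TestProliferationFraction:
    def _annotations(self, n_mal, n_prolif, sample, start=0):
        anns = []
        for i in range(n_mal):
            anns.append(gs.CellAnnotation(
                cell_id=f"{sample}_{start + i}", cluster=0, cell_type="OPC",
                malignant=True, proliferating=i < n_prolif))
        return anns

    def test_zero_prolif_gives_zero_everywhere(self):
        anns = self._annotations(50, 0, "sA") + self._annotations(40, 0, "sB")
        samples = pd.Series({a.cell_id: a.cell_id.split("_")[0] for a in anns})
        res = gs.proliferation_fraction(anns, samples)
        assert (res.per_sample_pct == 0).all()
        assert res.cohort_mean == 0.0

    def test_counts_are_exact(self):
        anns = (self._annotations(100, 6, "sA")
                + self._annotations(200, 10, "sB"))
        samples = pd.Series({a.cell_id: a.cell_id.split("_")[0] for a in anns})
        res = gs.proliferation_fraction(anns, samples)
        assert res.per_sample_pct["sA"] == pytest.approx(6.0)
        assert res.per_sample_pct["sB"] == pytest.approx(5.0)

    def test_sample_without_malignant_cells_excluded(self):
        anns = self._annotations(100, 5, "sA")
        lone = gs.CellAnnotation("sB_0", 0, "microglia", malignant=False)
        samples = pd.Series({a.cell_id: a.cell_id.split("_")[0]
                             for a in anns + [lone]})
        res = gs.proliferation_fraction(anns + [lone], samples)
        assert res.excluded_samples == ["sB"]

    def test_single_sample_sd_zero(self):
        anns = self._annotations(100, 5, "sA")
        samples = pd.Series({a.cell_id: "sA" for a in anns})
        res = gs.proliferation_fraction(anns, samples)
        assert res.cohort_sd == 0.0


class TestStageCorrelation:
    def test_self_correlation_is_one(self, sc_sim):
        ref = gs.stage_reference_profiles(sc_sim.config)
        stage, r = gs.stage_correlation(ref["OPC"], ref)
        assert stage == "OPC"
        assert r["OPC"] == pytest.approx(1.0)

    def test_anticorrelated_profile(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(100)]
        base = pd.Series(rng.normal(size=100), index=genes)
        ref = pd.DataFrame({"OPC": base})
        stage, r = gs.stage_correlation(-base, ref)
        assert r["OPC"] == pytest.approx(-1.0)

    def test_constant_profile_raises(self):
        genes = [f"G{i}" for i in range(50)]
        ref = pd.DataFrame({"OPC": np.arange(50.0)}, index=genes)
        with pytest.raises(ValidationError, match="constant"):
            gs.stage_correlation(pd.Series(1.0, index=genes), ref)

    def test_r_decreases_with_noise(self, sc_sim):
        ref = gs.stage_reference_profiles(sc_sim.config)
        rng = np.random.default_rng(1)
        rs = []
        for sd in (0.1, 1.0, 5.0):
            reps = []
            for _ in range(5):
                noisy = ref["OPC"] + rng.normal(0, sd, size=len(ref))
                reps.append(gs.stage_correlation(noisy, ref)[1]["OPC"])
            rs.append(np.mean(reps))
        assert rs[0] > rs[1] > rs[2]


class TestStagingIntegration:
    def test_malignant_clusters_stage_as_opc_or_cop(self, sc_sim, sc_pipeline):
        filtered, _, emb = sc_pipeline
        truth = sc_sim.cell_truth.loc[filtered.sample_ids]
        ref = gs.stage_reference_profiles(sc_sim.config)
        profiles = gs.cluster_mean_profiles(emb.normalized, emb.clusters)
        mal_clusters = emb.clusters[truth["malignant"].to_numpy()].unique()
        for cl in mal_clusters:
            stage, r = gs.stage_correlation(profiles[cl], ref)
            assert stage in ("OPC", "COP")
            assert stage != "MO"

    def test_proliferating_and_quiescent_share_stage(self, sc_sim, sc_pipeline):
        """Cycling and non-cycling malignant cells map to the same stage."""
        filtered, _, emb = sc_pipeline
        truth = sc_sim.cell_truth.loc[filtered.sample_ids]
        ref = gs.stage_reference_profiles(sc_sim.config)
        X = emb.normalized.dense()
        mal = truth["malignant"].to_numpy()
        prolif = truth["proliferating"].to_numpy() & mal
        quiet = mal & ~prolif
        assert prolif.sum() >= 5
        genes = emb.normalized.gene_ids
        prof_p = pd.Series(X[:, prolif].mean(axis=1), index=genes)
        prof_q = pd.Series(X[:, quiet].mean(axis=1), index=genes)
        # exclude the cycle markers themselves from the comparison
        keep = [g for g in genes
                if g not in set(sc_sim.panels["PROLIFERATION"])]
        stage_p, _ = gs.stage_correlation(prof_p[keep], ref.loc[keep])
        stage_q, _ = gs.stage_correlation(prof_q[keep], ref.loc[keep])
        assert stage_p == stage_q
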