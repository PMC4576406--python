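"""PCA embedding, clustering, stage assignment, projection, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import hscycle as h
from hscycle.cellcycle import STAGE_PANELS, ClusterResult, StageAssignment
from hscycle.data import DataError


def _norm_from(array, genes, cells=None):
    array = np.asarray(array, dtype=float)
    cells = cells or [f"c{j}" for j in range(array.shape[1])]
    return pd.DataFrame(array, index=genes, columns=cells)


class TestPCAEmbed:
    def test_rank1_data_single_component(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(1, 10, size=8)
        weights = rng.uniform(0.5, 2.0, size=6)
        norm = _norm_from(np.exp2(np.outer(profile, weights)) - 1,
                          [f"g{i}" for i in range(8)])
        emb = h.pca_embed(norm, list(norm.index), n_components=2, anchor_genes=None)
        assert emb.var_explained[0] >= 0.999

    def test_two_gene_loadings_match_analytic_eigenvectors(self):
        # closed-form eigenvector of the 2x2 covariance of the log data
        norm = _norm_from([[1, 3, 8], [2, 3, 5]], ["gA", "gB"])
        X = np.log2(norm.to_numpy().T + 1)
        C = np.cov(X.T, bias=True)
        evals, evecs = np.linalg.eigh(C)
        v1 = evecs[:, np.argmax(evals)]
        emb = h.pca_embed(norm, ["gA", "gB"], n_components=1, anchor_genes=None)
        assert abs(float(emb.loadings[:, 0] @ v1)) == pytest.approx(1.0, abs=1e-10)

    def test_reprojection_of_training_cells_equals_scores(self, normalized_default):
        m, _, _, sets, _, norm = normalized_default
        emb = h.pca_embed(norm, sets["cell_cycle"])
        back = emb.transform(norm.loc[emb.gene_ids])
        np.testing.assert_allclose(
            back.to_numpy(), emb.scores.to_numpy(), atol=1e-10
        )

    def test_loadings_orthonormal(self, normalized_default):
        *_, sets, _, norm = normalized_default
        emb = h.pca_embed(norm, sets["cell_cycle"], n_components=3)
        gram = emb.loadings.T @ emb.loadings
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_sign_convention_anchors_positive(self, normalized_default):
        *_, sets, _, norm = normalized_default
        emb = h.pca_embed(norm, sets["cell_cycle"])
        idx = [list(emb.gene_ids).index(g) for g in emb.anchor_genes
               if g in set(emb.gene_ids)]
        assert emb.loadings[idx, 0].sum() >= 0

    def test_too_few_genes_errors(self):
        norm = _norm_from([[1, 2], [2, 3]], ["gA", "gB"])
        with pytest.raises(DataError, match="2 usable genes"):
            h.pca_embed(norm, ["gA", "absent"], anchor_genes=None)


class TestClusterEmbedding:
    def test_separated_blobs_perfect_partition(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(20, 5))
        b = rng.normal(8, 0.1, size=(20, 5))
        norm = _norm_from(np.exp2(np.vstack([a, b]).T) - 1,
                          [f"g{i}" for i in range(5)]).clip(lower=0)
        emb = h.pca_embed(norm, list(norm.index), anchor_genes=None)
        res = h.cluster_embedding(emb, k=2, seed=0)
        first20 = res.labels.iloc[:20].nunique()
        last20 = res.labels.iloc[20:].nunique()
        assert first20 == 1 and last20 == 1
        assert res.labels.iloc[0] != res.labels.iloc[-1]

    def test_same_seed_identical_labels(self, normalized_default):
        *_, sets, _, norm = normalized_default
        emb = h.pca_embed(norm, sets["cell_cycle"])
        r1 = h.cluster_embedding(emb, k=5, seed=3)
        r2 = h.cluster_embedding(emb, k=5, seed=3)
        assert r1.labels.equals(r2.labels)

    def test_k_exceeding_cells_errors(self, normalized_default):
        *_, sets, _, norm = normalized_default
        emb = h.pca_embed(norm.iloc[:, :4], sets["cell_cycle"])
        with pytest.raises(DataError, match="exceeds"):
            h.cluster_embedding(emb, k=10)

    def test_hierarchical_agreement_reported(self, normalized_default):
        *_, sets, _, norm = normalized_default
        emb = h.pca_embed(norm, sets["cell_cycle"])
        res = h.cluster_embedding(emb, k=5, seed=0)
        assert res.ari_hierarchical is not None
        assert -1.0 <= res.ari_hierarchical <= 1.0


class TestAssignStages:
    def _panel_matrix(self, cluster_profiles, n_per_cluster=8, seed=0):
        """Build a normalized matrix whose clusters express chosen panels."""
        rng = np.random.default_rng(seed)
        genes = sorted({g for p in STAGE_PANELS.values() for g in p["high"] + p["low"]})
        cols, labels = [], []
        for ci, stages in enumerate(cluster_profiles):
            high = set()
            for st in stages:
                high |= set(STAGE_PANELS[st]["high"])
            for j in range(n_per_cluster):
                cols.append([100.0 if g in high else 1.0 for g in genes]
                            + rng.normal(0, 0.01, size=len(genes)))
                labels.append(f"C{ci + 1}")
        arr = np.abs(np.array(cols)).T
        cells = [f"c{i}" for i in range(arr.shape[1])]
        norm = pd.DataFrame(arr, index=genes, columns=cells)
        lab = pd.Series(labels, index=cells, name="cluster")
        centroids = pd.DataFrame(
            np.zeros((len(cluster_profiles), 2)),
            index=[f"C{i + 1}" for i in range(len(cluster_profiles))],
            columns=["PC1", "PC2"],
        )
        return norm, ClusterResult(labels=lab, centroids=centroids, inertia=0.0)

    def test_quiescence_markers_give_g0(self):
        norm, clusters = self._panel_matrix([["G0/early-G1"], ["S"], ["G2/M"]])
        model, assign = h.assign_cluster_stages(clusters, norm)
        assert model.cluster_stage["C1"] == "G0/early-G1"
        assert model.cluster_stage["C2"] == "S"
        assert model.cluster_stage["C3"] == "G2/M"

    def test_small_cluster_undetermined(self):
        norm, clusters = self._panel_matrix([["G0/early-G1"], ["S"]], n_per_cluster=3)
        model, assign = h.assign_cluster_stages(
            clusters, norm, min_cells_for_label=5
        )
        assert set(model.cluster_stage.values()) == {"undetermined"}
        assert (assign.table["stage"] == "undetermined").all()

    def test_occupancy_sums_to_one(self, normalized_default):
        *_, sets, _, norm = normalized_default
        emb = h.pca_embed(norm, sets["cell_cycle"])
        clusters = h.cluster_embedding(emb, k=5, seed=0)
        _, assign = h.assign_cluster_stages(clusters, norm)
        occ = assign.occupancy()
        np.testing.assert_allclose(occ.sum(axis=1), 1.0)


class TestProjection:
    def test_reference_cells_project_to_own_cluster(self, normalized_default):
        *_, sets, _, norm = normalized_default
        emb = h.pca_embed(norm, sets["cell_cycle"])
        clusters = h.cluster_embedding(emb, k=4, seed=0)
        model, ref = h.assign_cluster_stages(clusters, norm)
        proj = h.project_and_classify(emb, model, norm)
        # nearest-centroid agrees with k-means labels for nearly every cell
        agree = (proj.table["cluster"] == ref.table["cluster"]).mean()
        assert agree >= 0.95

    def test_insufficient_gene_overlap_errors(self, normalized_default):
        *_, sets, _, norm = normalized_default
        emb = h.pca_embed(norm, sets["cell_cycle"])
        clusters = h.cluster_embedding(emb, k=3, seed=0)
        model, _ = h.assign_cluster_stages(clusters, norm)
        half = list(emb.gene_ids)[: len(emb.gene_ids) // 2]
        with pytest.raises(DataError, match="gene list"):
            h.project_and_classify(emb, model, norm.loc[half])


class TestCompareOccupancy:
    @staticmethod
    def _assignment(n_in, n_total, group):
        stages = ["S"] * n_in + ["G0/early-G1"] * (n_total - n_in)
        t = pd.DataFrame({
            "cluster": "C1", "stage": stages, "group": group,
        }, index=[f"{group}{i}" for i in range(n_total)])
        return StageAssignment(table=t)

    def test_printed_contrast_36_61_vs_31_119(self):
        # 59.0% vs 26.1%: difference 0.329 and a strongly significant Fisher p
        a = self._assignment(36, 61, "KO")
        b = self._assignment(31, 119, "WT")
        comp = h.compare_occupancy(a, b, stages=("S",))
        assert comp.difference == pytest.approx(36 / 61 - 31 / 119, abs=1e-12)
        assert comp.difference == pytest.approx(0.329, abs=1e-3)
        assert comp.p_value < 0.001
        # independent oracle: two-sided Fisher p by hypergeometric enumeration
        M, K, n = 180, 67, 61
        probs = hypergeom.pmf(np.arange(max(0, n - (M - K)), min(K, n) + 1), M, K, n)
        p_obs = hypergeom.pmf(36, M, K, n)
        oracle = probs[probs <= p_obs * (1 + 1e-12)].sum()
        assert comp.p_value == pytest.approx(float(oracle), rel=1e-8)

    def test_identical_groups_null(self):
        a = self._assignment(10, 40, "A")
        b = self._assignment(10, 40, "B")
        comp = h.compare_occupancy(a, b, stages=("S",))
        assert comp.difference == 0.0
        assert comp.p_value == 1.0

    def test_extreme_table_matches_closed_form(self):
        # all-in vs all-out: two-sided p = hypergeometric point mass at the
        # observed corner, 2 * 1 / C(20, 10)
        a = self._assignment(10, 10, "A")
        b = self._assignment(0, 10, "B")
        comp = h.compare_occupancy(a, b, stages=("S",))
        expected = 2 * hypergeom.pmf(10, 20, 10, 10)
        assert comp.p_value == pytest.approx(float(expected), rel=1e-10)


class TestTranscriptionalActivity:
    def test_planted_activity_boost_detected(self, normalized_default):
        m, meta, truth, sets, sf, norm = normalized_default
        groups = meta.groups
        truth_assign = StageAssignment(table=pd.DataFrame({
            "cluster": "C1",
            "stage": truth.cells["stage"],
            "group": truth.cells["group"],
        }, index=truth.cells.index))
        activity, tests = h.transcriptional_activity(m, sf, truth_assign)
        row = tests[tests["comparison"] == "KO: S/G2/M vs G0/G1"].iloc[0]
        assert row["median_1"] > row["median_2"]
        assert row["p_value"] < 0.01
        between = tests[tests["comparison"] == "S/G2/M: WT vs KO"].iloc[0]
        assert between["median_2"] > between["median_1"]
        assert between["p_value"] < 0.01
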