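"""GSEA (ranking, ES, permutation NES) and hypergeometric ORA."""

import math

import numpy as np
import pandas as pd
import pytest

import hscycle as h
from hscycle.data import DataError, GeneSetCollection
from hscycle.enrichment import RankedList


def brute_force_es_extrema(genes, metric, members, weight_p):
    """Independent running-sum implementation (plain loop).

    Returns (max positive peak, min negative trough) of the running sum; the
    enrichment score is whichever has the larger magnitude.  Both are
    returned because the peak magnitudes can tie exactly (they are small
    rationals), in which case the reported sign is a tie-break convention.
    """
    hits = [g in members for g in genes]
    n, n_hits = len(genes), sum(hits)
    denom_hit = sum(abs(m) ** weight_p for m, h_ in zip(metric, hits) if h_)
    peak, trough, cur = 0.0, 0.0, 0.0
    for m, hit in zip(metric, hits):
        if hit:
            cur += (abs(m) ** weight_p) / denom_hit if denom_hit else 1.0 / n_hits
        else:
            cur -= 1.0 / (n - n_hits)
        peak = max(peak, cur)
        trough = min(trough, cur)
    return peak, trough


def brute_force_es(genes, metric, members, weight_p):
    peak, trough = brute_force_es_extrema(genes, metric, members, weight_p)
    return peak if peak >= -trough else trough


def assert_es_matches_oracle(es, genes, metric, members, weight_p, tol=1e-12):
    peak, trough = brute_force_es_extrema(genes, metric, members, weight_p)
    assert abs(abs(es) - max(peak, -trough)) <= tol
    assert min(abs(es - peak), abs(es - trough)) <= tol


def brute_force_hypergeom_upper(M, K, n, k):
    """P[X >= k] by full enumeration with exact integer combinatorics."""
    total = math.comb(M, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(M - K, n - i)
    return acc / total


class TestRanking:
    def _norm(self, rows, genes):
        return pd.DataFrame(rows, index=genes,
                            columns=[f"c{i}" for i in range(len(rows[0]))])

    def test_equal_means_zero_metric(self):
        norm = self._norm([[5, 5, 5, 5, 5, 5]], ["g"])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=norm.columns)
        r = h.rank_genes_s2n(norm, labels)
        assert r.metric[0] == 0.0

    def test_signal_to_noise_arithmetic(self):
        rng = np.random.default_rng(0)
        a = 4 + rng.normal(0, 1e-9, 3)
        norm = self._norm([[4, 5, 3, 2, 3, 1]], ["g"])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=norm.columns)
        r = h.rank_genes_s2n(norm, labels)
        # means (4, 2), sds (1, 1) -> (4-2)/(1+1) = 1.0
        assert r.metric[0] == pytest.approx(1.0)

    def test_zero_variance_floor(self):
        norm = self._norm([[1, 1, 1, 0, 0, 0]], ["g"])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=norm.columns)
        r = h.rank_genes_s2n(norm, labels)
        # sds floored at 0.2*|mean| (0.2 when the mean is 0): 1/(0.2+0.2)
        assert r.metric[0] == pytest.approx(2.5)

    def test_tie_break_lexicographic(self):
        norm = self._norm([[1, 1, 0, 0]] * 3, ["b", "a", "c"])
        labels = pd.Series(["A", "A", "B", "B"], index=norm.columns)
        with pytest.raises(DataError, match=">= 3"):
            h.rank_genes_s2n(norm, labels)
        norm = self._norm([[1, 1, 1, 0, 0, 0]] * 3, ["b", "a", "c"])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=norm.columns)
        r = h.rank_genes_s2n(norm, labels)
        assert list(r.genes) == ["a", "b", "c"]


class TestEnrichmentScore:
    def test_top_gene_singleton_unweighted(self):
        ranked = RankedList(
            genes=[f"g{i}" for i in range(10)], metric=np.arange(10, 0, -1.0)
        )
        es, running, leading = h.enrichment_score(ranked, {"g0"}, weight_p=0.0)
        assert es == pytest.approx(1.0)
        assert leading == ["g0"]

    def test_bottom_set_negative(self):
        ranked = RankedList(
            genes=[f"g{i}" for i in range(10)], metric=np.arange(10, 0, -1.0)
        )
        es, _, _ = h.enrichment_score(ranked, {"g8", "g9"})
        assert es < 0

    def test_matches_brute_force_on_random_instances(self):
        from test_enrichment import assert_es_matches_oracle

        rng = np.random.default_rng(12)
        for _ in range(100):
            metric = np.sort(rng.normal(size=20))[::-1]
            genes = [f"g{i}" for i in range(20)]
            members = set(rng.choice(genes, size=5, replace=False))
            ranked = RankedList(genes=genes, metric=metric)
            es, _, _ = h.enrichment_score(ranked, members, weight_p=1.0)
            assert_es_matches_oracle(es, genes, metric, members, 1.0)

    def test_weight_zero_invariant_to_monotone_metric_transform(self):
        rng = np.random.default_rng(5)
        metric = np.sort(rng.normal(size=30))[::-1]
        genes = [f"g{i}" for i in range(30)]
        members = set(rng.choice(genes, size=6, replace=False))
        es1, _, _ = h.enrichment_score(RankedList(genes=genes, metric=metric),
                                       members, weight_p=0.0)
        es2, _, _ = h.enrichment_score(
            RankedList(genes=genes, metric=np.exp(metric)), members, weight_p=0.0
        )
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_empty_intersection_and_full_set_error(self):
        ranked = RankedList(genes=["a", "b"], metric=np.array([2.0, 1.0]))
        with pytest.raises(DataError, match="intersect"):
            h.enrichment_score(ranked, {"zz"})
        with pytest.raises(DataError, match="entire"):
            h.enrichment_score(ranked, {"a", "b"})


class TestGSEA:
    @pytest.fixture(scope="class")
    def depletion_run(self, normalized_default):
        m, meta, truth, sets, sf, norm = normalized_default
        bio = norm.loc[m.gene_ids[~m.is_spikein]]
        sig = GeneSetCollection(sets={
            "CLP_signature": sets["CLP_signature"],
            "MegE_signature": sets["MegE_signature"],
        })
        res = h.gsea(bio, meta.groups, sig, n_perm=200, seed=3,
                     classes=("WT", "KO"))
        return res

    def test_lymphoid_depletion_positive_nes(self, depletion_run):
        row = depletion_run.loc["CLP_signature"]
        assert row["es"] > 0 and row["nes"] > 0
        assert row["p_value"] < 0.05

    def test_es_bounds_and_sign_consistency(self, depletion_run):
        assert (depletion_run["es"].abs() <= 1.0).all()
        assert (np.sign(depletion_run["nes"]) == np.sign(depletion_run["es"])).all()
        assert depletion_run["p_value"].between(0, 1).all()
        assert depletion_run["fdr_q"].between(0, 1).all()

    def test_seed_determinism(self, normalized_default):
        m, meta, _, sets, _, norm = normalized_default
        bio = norm.loc[m.gene_ids[~m.is_spikein]].iloc[:300]
        sig = GeneSetCollection(sets={"s": list(bio.index[:25])})
        r1 = h.gsea(bio, meta.groups, sig, n_perm=100, seed=9)
        r2 = h.gsea(bio, meta.groups, sig, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_too_few_permutations_rejected(self, normalized_default):
        m, meta, _, sets, _, norm = normalized_default
        bio = norm.loc[m.gene_ids[~m.is_spikein]].iloc[:100]
        sig = GeneSetCollection(sets={"s": list(bio.index[:10])})
        with pytest.raises(DataError, match="n_perm"):
            h.gsea(bio, meta.groups, sig, n_perm=50)


class TestORA:
    def test_small_universe_example_exact(self):
        # universe 20, set 5, selected 5, overlap 4:
        # (C(5,4)C(15,1) + C(5,5)C(15,0)) / C(20,5) = 76/15504
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection(sets={"s": universe[:5]})
        selected = universe[1:5] + [universe[10]]
        res = h.ora_hypergeometric(selected, universe, sets)
        assert res.loc["s", "overlap"] == 4
        assert res.loc["s", "p_value"] == pytest.approx(76 / 15504, rel=1e-12)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection(sets={"s": universe[:5]})
        res = h.ora_hypergeometric(universe[10:15], universe, sets)
        assert res.loc["s", "p_value"] == pytest.approx(1.0)

    def test_selected_equals_universe_p_one(self):
        universe = [f"g{i}" for i in range(12)]
        sets = GeneSetCollection(sets={"s": universe[:4]})
        res = h.ora_hypergeometric(universe, universe, sets)
        assert res.loc["s", "overlap"] == 4
        assert res.loc["s", "p_value"] == pytest.approx(1.0)

    def test_selection_outside_universe_rejected(self):
        sets = GeneSetCollection(sets={"s": ["a"]})
        with pytest.raises(DataError, match="subset"):
            h.ora_hypergeometric(["zz"], ["a", "b"], sets)

    def test_exact_against_enumeration_small_universes(self):
        rng = np.random.default_rng(4)
        for M in (5, 10, 18, 25):
            universe = [f"g{i}" for i in range(M)]
            for _ in range(20):
                K = int(rng.integers(1, M + 1))
                n = int(rng.integers(1, M + 1))
                members = list(rng.choice(universe, size=K, replace=False))
                selected = list(rng.choice(universe, size=n, replace=False))
                res = h.ora_hypergeometric(
                    selected, universe, GeneSetCollection(sets={"s": members})
                )
                k = len(set(members) & set(selected))
                assert res.loc["s", "p_value"] == pytest.approx(
                    brute_force_hypergeom_upper(M, K, n, k), rel=1e-10
                )
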