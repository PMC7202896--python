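"""Tanimoto similarity, clustering and Fisher enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ryrmod.chem import (
    cluster_dendrogram,
    clusters_from_records,
    enrichment_report,
    extract_structural_clusters,
    fisher_enrichment,
    pairwise_tanimoto,
    similarity_matrix,
    tanimoto,
)
from ryrmod.synthetic import LibrarySpec, gen_chemical_library

from conftest import record


class TestTanimoto:
    def test_hand_cases(self):
        assert tanimoto([1, 1, 0], [1, 1, 0]) == 1.0
        assert tanimoto([1, 0, 0], [0, 1, 1]) == 0.0
        # supports {1,2} vs {2,3}: |intersection|=1, |union|=3
        assert tanimoto([0, 1, 1, 0], [0, 0, 1, 1]) == pytest.approx(1 / 3)
        assert tanimoto([0, 0], [0, 0]) == 0.0  # both-empty convention

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto([1, 0], [1, 0, 1])

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=32),
        st.data(),
    )
    def test_symmetry_bounds_identity(self, a, data):
        b = data.draw(st.lists(st.integers(0, 1), min_size=len(a), max_size=len(a)))
        s = tanimoto(a, b)
        assert s == tanimoto(b, a)
        assert 0.0 <= s <= 1.0
        if any(a):
            # score 1 iff supports are equal (nonzero case)
            assert (s == 1.0) == (a == b)


class TestSimilarityMatrix:
    def test_hand_computed_block(self):
        hits = [record("h1", [0, 1]), record("h2", [2])]
        lib = [record("h1", [0, 1]), record("h2", [2]), record("x", [1, 2])]
        m = similarity_matrix(hits, lib)
        expect = np.array([[1.0, 0.0, 1 / 3], [0.0, 1.0, 0.5]])
        np.testing.assert_allclose(m.values, expect)

    def test_identical_fingerprints_all_ones(self):
        recs = [record(f"c{i}", [0, 3]) for i in range(3)]
        m = similarity_matrix(recs[:2], recs)
        assert (m.values == 1.0).all()

    def test_empty_hits_rejected(self):
        with pytest.raises(ValueError):
            similarity_matrix([], [record("a", [0])])

    def test_entries_bounded_random(self):
        rng = np.random.default_rng(0)
        recs = [
            record(f"c{i}", list(np.flatnonzero(rng.random(16) < 0.3)), n_bits=16)
            for i in range(10)
        ]
        m = similarity_matrix(recs[:4], recs)
        assert ((m.values >= 0) & (m.values <= 1)).all()


class TestDendrogram:
    def test_identical_rows_merge_at_zero(self):
        recs = [record("a", [0, 1]), record("b", [0, 1]), record("c", [5])]
        m = pairwise_tanimoto(recs)
        d = cluster_dendrogram(m, axis="rows")
        assert d.linkage[0, 2] == pytest.approx(0.0)

    def test_complete_linkage_hand_trace(self):
        """Points on a line at 0, 1, 3: first merge at distance 1, then the
        complete-linkage merge at max(2, 3) = 3."""
        from ryrmod.chem import SimilarityMatrix

        m = SimilarityMatrix(
            row_ids=["a", "b", "c"],
            col_ids=["x"],
            values=np.array([[0.0], [1.0], [3.0]]),
        )
        d = cluster_dendrogram(m, axis="rows")
        assert d.linkage[0, 2] == pytest.approx(1.0)
        assert d.linkage[1, 2] == pytest.approx(3.0)

    def test_leaf_order_is_permutation(self):
        rng = np.random.default_rng(1)
        recs = [
            record(f"c{i}", list(np.flatnonzero(rng.random(16) < 0.4)), n_bits=16)
            for i in range(12)
        ]
        m = pairwise_tanimoto(recs)
        d = cluster_dendrogram(m, axis="rows")
        assert sorted(d.leaf_order) == sorted(m.row_ids)

    def test_merge_heights_monotone_random(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            recs = [
                record(f"c{i}", list(np.flatnonzero(rng.random(24) < 0.3)), n_bits=24)
                for i in range(15)
            ]
            d = cluster_dendrogram(pairwise_tanimoto(recs), axis="rows")
            heights = d.linkage[:, 2]
            assert (np.diff(heights) >= -1e-12).all()

    def test_single_item_trivial(self):
        m = pairwise_tanimoto([record("only", [0])])
        d = cluster_dendrogram(m)
        assert d.leaf_order == ["only"]


class TestStructuralClusters:
    def test_identical_pair_plus_unrelated(self):
        recs = [record("a", [0, 1, 2]), record("b", [0, 1, 2]),
                record("u1", [5]), record("u2", [6]), record("u3", [7])]
        m = pairwise_tanimoto(recs)
        d = cluster_dendrogram(m)
        clusters = extract_structural_clusters(d, m)
        pair = [c for c in clusters if set(c.member_ids) == {"a", "b"}]
        assert len(pair) == 1
        assert pair[0].cohesion == 1.0 and pair[0].is_structural

    def test_all_distinct_yield_structural_singletons(self):
        recs = [record(f"c{i}", [i]) for i in range(5)]
        m = pairwise_tanimoto(recs)
        clusters = extract_structural_clusters(cluster_dendrogram(m), m, cut=5)
        assert all(len(c.member_ids) == 1 and c.is_structural for c in clusters)

    def test_threshold_validation(self):
        recs = [record("a", [0]), record("b", [1])]
        m = pairwise_tanimoto(recs)
        with pytest.raises(ValueError):
            extract_structural_clusters(cluster_dendrogram(m), m, tanimoto_threshold=1.5)

    def test_planted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            lib = gen_chemical_library(
                LibrarySpec(n_compounds=50, n_clusters=2, cluster_sizes=(8, 8), seed=seed)
            )
            _, clusters = clusters_from_records(lib)
            assign = {m: c.cluster_id for c in clusters for m in c.member_ids}
            truth, pred = [], []
            for r in lib:
                lab = next(iter(r.class_labels))
                if lab.startswith("cluster"):
                    truth.append(lab)
                    pred.append(assign[r.compound_id])
            aris.append(adjusted_rand_score(truth, pred))
        assert np.mean(aris) > 0.9


def fisher_two_sided_oracle(k: int, K: int, n: int, N: int) -> Fraction:
    """Exhaustive two-sided Fisher p in exact rational arithmetic: sum of
    hypergeometric point probabilities <= the observed table's."""
    denom = comb(N, n)
    p_obs = Fraction(comb(K, k) * comb(N - K, n - k), denom)
    total = Fraction(0)
    for j in range(max(0, n - (N - K)), min(K, n) + 1):
        pj = Fraction(comb(K, j) * comb(N - K, n - j), denom)
        if pj <= p_obs:
            total += pj
    return total


class TestFisherEnrichment:
    @pytest.mark.parametrize(
        "k,K,n,N,expect",
        [
            (2, 9, 18, 1280, 0.0063),   # DHPR inhibitors among MicroSource hits
            (1, 1, 18, 1280, 0.0141),   # thiostrepton, structurally unique
            (2, 2, 18, 1280, 0.0002),   # riboflavin + riboflavin 5-phosphate
            (1, 2, 2, 4, 1.0),          # full enumeration: all 3 tables <= observed
        ],
    )
    def test_reported_p_values(self, k, K, n, N, expect):
        res = fisher_enrichment(k, K, n, N)
        assert round(res.p_two_sided, 4) == expect

    def test_exhaustive_oracle_small_N(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n - (N - K)), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            res = fisher_enrichment(k, K, n, N)
            assert res.p_two_sided == pytest.approx(
                float(fisher_two_sided_oracle(k, K, n, N)), abs=1e-12
            )

    def test_screen_scale_matches_exact_rational(self):
        """At N=1280 the p must agree with exact rational arithmetic to 12
        significant digits."""
        for k, K, n in [(2, 9, 18), (1, 1, 18), (2, 2, 18), (5, 40, 18)]:
            exact = float(fisher_two_sided_oracle(k, K, n, 1280))
            got = fisher_enrichment(k, K, n, 1280).p_two_sided
            assert got == pytest.approx(exact, rel=1e-12)

    def test_table_symmetry(self):
        # swapping the roles of "in group" and "hit" transposes the table
        p1 = fisher_enrichment(3, 10, 7, 50).p_two_sided
        p2 = fisher_enrichment(3, 7, 10, 50).p_two_sided
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_odds_ratio_conventions(self):
        res = fisher_enrichment(2, 2, 18, 1280)
        assert res.odds_ratio == np.inf  # zero (K-k) cell
        res2 = fisher_enrichment(2, 9, 18, 1280)
        assert res2.odds_ratio == pytest.approx(2 * (1280 - 9 - 18 + 2) / (7 * 16))

    def test_margin_validation(self):
        with pytest.raises(ValueError):
            fisher_enrichment(5, 4, 18, 1280)
        with pytest.raises(ValueError):
            fisher_enrichment(0, 3, 4, 5)  # 4 non-hits cannot fit in N-K=2


class TestEnrichmentReport:
    def _library(self):
        lib = []
        for i in range(20):
            lib.append(record(f"c{i}", [i % 8], is_hit=i < 4))
        return lib

    def test_no_hits_all_p_one(self):
        lib = [record(f"c{i}", [i % 4]) for i in range(10)]
        rep = enrichment_report({"g1": ["c0", "c1"], "g2": ["c2"]}, lib)
        assert (rep["p_two_sided"] == 1.0).all()

    def test_whole_library_group_degenerate(self):
        lib = self._library()
        rep = enrichment_report({"all": [r.compound_id for r in lib]}, lib)
        assert rep.loc[0, "p_two_sided"] == 1.0

    def test_enriched_cluster_ranks_first(self):
        lib = self._library()
        groups = {"hits": ["c0", "c1", "c2", "c3"], "mixed": ["c4", "c5", "c6", "c7"]}
        rep = enrichment_report(groups, lib)
        assert rep.loc[0, "group_id"] == "hits"
        assert rep.loc[0, "k"] == 4

    def test_empty_group_skipped_with_warning(self):
        lib = self._library()
        with pytest.warns(UserWarning, match="no members"):
            rep = enrichment_report({"ghost": ["zzz"], "ok": ["c0"]}, lib)
        assert list(rep["group_id"]) == ["ok"]
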