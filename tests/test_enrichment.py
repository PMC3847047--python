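"""Clustering, subtree enumeration and permutation enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cytoprofile import (
    cluster_profiles,
    cosine_distance_matrix,
    enumerate_clusters,
    rank_clusters,
    score_enrichment,
)
from cytoprofile.enrichment import (
    ClusterCandidate,
    EnrichmentError,
    sample_uniform_clusters,
)


def _profiles(rows, ids=None):
    X = np.asarray(rows, dtype=float)
    ids = ids or [f"C{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=ids)


class TestCosineDistance:
    def test_collinear_vectors_are_at_zero(self):
        D = cosine_distance_matrix(_profiles([[1, 1], [2, 2]]))
        assert D.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors_are_at_one(self):
        D = cosine_distance_matrix(_profiles([[1, 0], [0, 1]]))
        assert D.iloc[0, 1] == pytest.approx(1.0)

    def test_forty_five_degrees(self):
        D = cosine_distance_matrix(_profiles([[1, 0], [1, 1]]))
        assert D.iloc[0, 1] == pytest.approx(1 - 1 / np.sqrt(2))

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        D = cosine_distance_matrix(_profiles(rng.random((6, 4)) + 0.1))
        np.testing.assert_allclose(D.to_numpy(), D.to_numpy().T)
        np.testing.assert_array_equal(np.diag(D.to_numpy()), np.zeros(6))

    def test_zero_norm_profile_named_in_error(self):
        with pytest.raises(EnrichmentError, match="C1"):
            cosine_distance_matrix(_profiles([[1, 1], [0, 0]], ids=["C0", "C1"]))


def _brute_single_linkage(D):
    """Reference agglomeration: merge the closest pair of clusters where
    inter-cluster distance is the minimum over cross pairs."""
    clusters = [{i} for i in range(len(D))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = min(D[i][j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), d))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


class TestClustering:
    def test_three_point_merge_order_matches_brute_force(self):
        # d(A,B)=1, d(A,C)=5, d(B,C)=4: merge (A,B) at 1, then with C at 4
        D = pd.DataFrame(
            [[0, 1, 5], [1, 0, 4], [5, 4, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        tree = cluster_profiles(D)
        np.testing.assert_allclose(tree.heights(), [1.0, 4.0])
        ref = _brute_single_linkage(D.to_numpy())
        assert [m[2] for m in ref] == [1.0, 4.0]
        first = tree.subtrees()[0]
        assert first.members == {"A", "B"}

    def test_random_matrix_heights_match_brute_force(self):
        rng = np.random.default_rng(3)
        X = rng.random((7, 5)) + 0.1
        D = cosine_distance_matrix(_profiles(X))
        tree = cluster_profiles(D)
        ref_heights = sorted(m[2] for m in _brute_single_linkage(D.to_numpy()))
        np.testing.assert_allclose(sorted(tree.heights()), ref_heights, rtol=1e-10)

    def test_identical_profiles_merge_at_zero(self):
        D = cosine_distance_matrix(_profiles([[1, 2]] * 4))
        tree = cluster_profiles(D)
        np.testing.assert_allclose(tree.heights(), 0.0, atol=1e-12)

    def test_heights_are_non_decreasing(self, tiny_screen):
        compounds = tiny_screen["compounds"]
        prof = compounds.compound_data.set_index("compound_id")[compounds.feature_names]
        tree = cluster_profiles(cosine_distance_matrix(prof))
        h = tree.heights()
        assert (np.diff(h) >= -1e-15).all()

    def test_single_profile_is_an_error(self):
        with pytest.raises(EnrichmentError, match=">=2"):
            cluster_profiles(pd.DataFrame([[0.0]], index=["C0"], columns=["C0"]))


class TestSubtrees:
    @pytest.mark.parametrize("n_leaves, n_candidates", [(2, 1), (5, 4), (75, 74)])
    def test_candidate_count_is_leaves_minus_one(self, n_leaves, n_candidates):
        rng = np.random.default_rng(n_leaves)
        D = cosine_distance_matrix(_profiles(rng.random((n_leaves, 8)) + 0.1))
        cands = enumerate_clusters(cluster_profiles(D))
        assert len(cands) == n_candidates
        assert cands[-1].size == n_leaves  # the root holds every leaf

    def test_children_are_subsets_of_parents(self, tiny_screen):
        compounds = tiny_screen["compounds"]
        prof = compounds.compound_data.set_index("compound_id")[compounds.feature_names]
        tree = cluster_profiles(cosine_distance_matrix(prof))
        members = {i: frozenset([c]) for i, c in enumerate(tree.leaves)}
        n = tree.n_leaves
        for i, (a, b, _h, _c) in enumerate(tree.linkage):
            node = members[n + i] = members[int(a)] | members[int(b)]
            assert members[int(a)] <= node and members[int(b)] <= node

    def test_newick_serialization_parses_back(self, tiny_screen):
        import dendropy

        compounds = tiny_screen["compounds"]
        prof = compounds.compound_data.set_index("compound_id")[compounds.feature_names]
        tree = cluster_profiles(cosine_distance_matrix(prof))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(tree.leaves)
        # root-to-leaf path length equals the root merge height
        depths = parsed.calc_node_root_distances(return_leaf_distances_only=True)
        np.testing.assert_allclose(depths, tree.heights()[-1], atol=1e-9)


def _exact_fraction(N, M, k, m):
    """Enumerate all C(N, k) subsets; fraction with >= m of the first M."""
    hits = total = 0
    for subset in itertools.combinations(range(N), k):
        total += 1
        if sum(1 for i in subset if i < M) >= m:
            hits += 1
    return hits / total


class TestEnrichmentScores:
    def _score(self, N, M, k, n_perm=100_000, seed=5):
        universe = [f"C{i}" for i in range(N)]
        ann = pd.DataFrame({"compound_id": universe[:M], "term": "t"})
        cluster = ClusterCandidate(node_id=N, members=frozenset(universe[:k]))
        return score_enrichment([cluster], ann, universe, n_permutations=n_perm, seed=seed)

    def test_exact_tail_all_carriers_in_cluster(self):
        # N=10, M=3, k=3, m=3 -> 1 / C(10,3) = 1/120
        rec = self._score(10, 3, 3).iloc[0]
        assert rec["m"] == 3
        assert rec["exact_tail"] == pytest.approx(1 / 120)
        assert rec["exact_tail"] == pytest.approx(_exact_fraction(10, 3, 3, 3))
        se = math.sqrt((1 / 120) * (119 / 120) / 100_000)
        assert abs(rec["perm_fraction"] - 1 / 120) <= 3 * se

    def test_exact_tail_by_complement_counting(self):
        # N=10, M=5, k=2, m=1 -> 1 - C(5,2)/C(10,2) = 7/9
        universe = [f"C{i}" for i in range(10)]
        ann = pd.DataFrame({"compound_id": universe[:5], "term": "t"})
        cluster = ClusterCandidate(node_id=10, members=frozenset(["C0", "C9"]))
        rec = score_enrichment([cluster], ann, universe, n_permutations=100, seed=5).iloc[0]
        assert rec["m"] == 1
        assert rec["exact_tail"] == pytest.approx(7 / 9)
        assert _exact_fraction(10, 5, 2, 1) == pytest.approx(7 / 9)

    def test_terms_absent_from_cluster_are_not_scored(self):
        universe = [f"C{i}" for i in range(6)]
        ann = pd.DataFrame({"compound_id": ["C4", "C5"], "term": ["t", "t"]})
        cluster = ClusterCandidate(node_id=6, members=frozenset(universe[:3]))
        out = score_enrichment([cluster], ann, universe, n_permutations=100, seed=0)
        assert out.empty  # m = 0 for the only term

    def test_term_without_universe_carrier_skipped(self, caplog):
        universe = ["C0", "C1", "C2"]
        ann = pd.DataFrame({"compound_id": ["C0", "X9"], "term": ["t", "orphan"]})
        cluster = ClusterCandidate(node_id=3, members=frozenset(["C0", "C1"]))
        with caplog.at_level("WARNING"):
            out = score_enrichment([cluster], ann, universe, n_permutations=100, seed=0)
        assert set(out["term"]) == {"t"}
        assert "orphan" in caplog.text

    def test_perm_fraction_matches_enumeration_small_universe(self):
        """10^5 uniform draws agree with full enumeration over all C(N,k)
        subsets within 3 binomial SEs, for a spread of (N, M, k, m)."""
        rng_cases = [(6, 2, 3), (8, 4, 3), (9, 3, 4), (12, 5, 6)]
        for N, M, k in rng_cases:
            recs = self._score(N, M, k)
            for _, rec in recs.iterrows():
                p = _exact_fraction(N, M, k, int(rec["m"]))
                se = math.sqrt(p * (1 - p) / rec["n_permutations"])
                assert abs(rec["perm_fraction"] - p) <= max(3 * se, 1e-12), (N, M, k)

    def test_relabeling_compounds_preserves_fraction_multiset(self, tiny_screen):
        compounds = tiny_screen["compounds"]
        model = tiny_screen["model"]
        universe = sorted(model.truth.compound_groups)
        ann = model.annotations(coverage=1.0, n_decoy_terms=0)
        prof = compounds.compound_data.set_index("compound_id").loc[
            universe, compounds.feature_names
        ]
        tree = cluster_profiles(cosine_distance_matrix(prof))
        recs = score_enrichment(enumerate_clusters(tree), ann, universe, 2000, seed=9)

        relabel = {c: f"X{i}" for i, c in enumerate(universe)}
        prof2 = prof.rename(index=relabel)
        ann2 = ann.assign(compound_id=ann["compound_id"].map(relabel))
        universe2 = sorted(relabel.values())
        tree2 = cluster_profiles(cosine_distance_matrix(prof2.loc[sorted(prof2.index)]))
        recs2 = score_enrichment(enumerate_clusters(tree2), ann2, universe2, 2000, seed=9)
        assert sorted(recs["perm_fraction"]) == pytest.approx(sorted(recs2["perm_fraction"]))

    def test_subset_sampler_draws_without_replacement(self):
        rng = np.random.default_rng(0)
        S = sample_uniform_clusters(10, 4, 500, rng)
        assert S.shape == (500, 4)
        for row in S:
            assert len(set(row.tolist())) == 4


class TestRanking:
    def _rec(self, **kw):
        base = dict(node_id=1, term="t", k=3, m=1, M=3, N=10,
                    perm_fraction=0.5, exact_tail=0.5, n_permutations=100, seed=0)
        base.update(kw)
        return base

    def test_lower_fraction_ranks_first(self):
        out = rank_clusters(pd.DataFrame([
            self._rec(node_id=1, perm_fraction=0.2),
            self._rec(node_id=2, perm_fraction=0.001),
        ]))
        assert out.loc[0, "node_id"] == 2
        assert out["rank"].tolist() == [1, 2]

    def test_tie_broken_by_larger_m(self):
        out = rank_clusters(pd.DataFrame([
            self._rec(node_id=1, m=2), self._rec(node_id=2, m=3),
        ]))
        assert out.loc[0, "m"] == 3

    def test_output_carries_k_m_M_counts(self):
        out = rank_clusters(pd.DataFrame([self._rec()]))
        assert {"k", "m", "M", "N"} <= set(out.columns)

    def test_empty_records_is_an_error(self):
        with pytest.raises(EnrichmentError):
            rank_clusters(pd.DataFrame())
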