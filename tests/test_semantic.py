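"""Semantic lexicon induction: LSA, MCL, cluster scoring, category lexicon."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from entrelex.errors import DimensionError, EmptyMatrixError, ParameterError
from entrelex.semantic import (
    Clustering,
    build_category_lexicon,
    build_term_context_matrix,
    cluster_terms,
    compute_cluster_score,
    cosine_sim,
    lsa_reduce,
    markov_cluster,
    normalize_term,
    score_clustering,
)


class TestNormalize:
    @pytest.mark.parametrize("surface,expected", [
        ("Complex", "complex"),
        ("Promoters", "promot"),
        ("a", "a"),
        ("", ""),
        ("DNA binding domains", "dna bind domain"),
    ])
    def test_examples(self, surface, expected):
        assert normalize_term(surface) == expected


class TestContextMatrix:
    def test_window_counts_by_enumeration(self):
        # brute-force oracle over "a b a b", window 1
        vocab, mat = build_term_context_matrix([["a", "b", "a", "b"]],
                                               window=1, min_count=1)
        m = mat.toarray()
        ia, ib = vocab.index("a"), vocab.index("b")
        assert m[ia, ib] == 3 and m[ib, ia] == 3
        assert m[ia, ia] == 0 and m[ib, ib] == 0

    def test_min_count_above_all_raises(self):
        with pytest.raises(EmptyMatrixError):
            build_term_context_matrix([["a", "b"]], window=1, min_count=10)

    def test_single_token_sentence_zero_row(self):
        vocab, mat = build_term_context_matrix([["solo"]], window=1,
                                               min_count=1)
        assert mat.toarray().sum() == 0

    def test_matches_brute_force_on_random_corpus(self):
        rng = np.random.default_rng(5)
        sents = [[f"w{rng.integers(5)}" for _ in range(rng.integers(2, 9))]
                 for _ in range(30)]
        window = 2
        vocab, mat = build_term_context_matrix(sents, window=window,
                                               min_count=1)
        idx = {t: i for i, t in enumerate(vocab)}
        expect = np.zeros((len(vocab), len(vocab)))
        for s in sents:
            for i, a in enumerate(s):
                for j, b in enumerate(s):
                    if i != j and abs(i - j) <= window:
                        expect[idx[a], idx[b]] += 1
        assert np.array_equal(mat.toarray(), expect)


class TestLSA:
    def test_rank_one_exact(self):
        # counts whose log-scaled form is exactly rank 1: k=1 reproduces
        # all pairwise row cosines of the weighted matrix
        w = np.outer([1.0, 2.0, 0.5], [0.5, 1.0, 2.0])
        counts = sp.csr_matrix(np.expm1(w))
        space = lsa_reduce(["x", "y", "z"], counts, 1)
        for i in range(3):
            for j in range(3):
                assert cosine_sim(space.vectors[i], space.vectors[j]) == \
                    pytest.approx(cosine_sim(w[i], w[j]), abs=1e-10)

    def test_identical_rows_identical_vectors(self):
        counts = sp.csr_matrix(np.array([[3, 1, 0], [3, 1, 0], [0, 0, 5]]))
        space = lsa_reduce(["x", "y", "z"], counts, 2)
        np.testing.assert_allclose(space.vectors[0], space.vectors[1],
                                   atol=1e-10)

    def test_full_rank_preserves_cosines(self):
        rng = np.random.default_rng(0)
        counts = sp.csr_matrix(rng.integers(0, 6, size=(8, 12)))
        space = lsa_reduce([f"t{i}" for i in range(8)], counts, 8)
        w = np.log1p(counts.toarray())
        for i in range(8):
            for j in range(8):
                assert cosine_sim(space.vectors[i], space.vectors[j]) == \
                    pytest.approx(cosine_sim(w[i], w[j]), abs=1e-8)

    def test_reconstruction_error_equals_discarded_singular_mass(self):
        # full-SVD oracle on a random 20x30 matrix, k=5
        rng = np.random.default_rng(1)
        counts = sp.csr_matrix(rng.integers(0, 9, size=(20, 30)))
        w = np.log1p(counts.toarray())
        u, s, vt = np.linalg.svd(w, full_matrices=False)
        k = 5
        space = lsa_reduce([f"t{i}" for i in range(20)], counts, k)
        # squared error of the best rank-k approximation equals the
        # discarded singular mass (Eckart-Young)
        err = np.linalg.norm(w - u[:, :k] * s[:k] @ vt[:k]) ** 2
        assert err == pytest.approx(float(np.sum(s[k:] ** 2)), rel=1e-9)
        # the row projections have the same Gram matrix as U_k S_k
        gram = space.vectors @ space.vectors.T
        want = (u[:, :k] * s[:k]) @ (u[:, :k] * s[:k]).T
        np.testing.assert_allclose(gram, want, atol=1e-8)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(2)
        counts = sp.csr_matrix(rng.integers(0, 4, size=(6, 7)))
        a = lsa_reduce([f"t{i}" for i in range(6)], counts, 3)
        b = lsa_reduce([f"t{i}" for i in range(6)], counts, 3)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_k_out_of_range(self):
        counts = sp.csr_matrix(np.ones((3, 4)))
        with pytest.raises(ParameterError):
            lsa_reduce(["a", "b", "c"], counts, 5)


class TestCosine:
    def test_self_similarity_one(self):
        v = np.array([0.3, -2.0, 1.0])
        assert cosine_sim(v, v) == pytest.approx(1.0)

    def test_orthogonal_zero(self):
        assert cosine_sim([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine_sim([1, 1], [1, 0]) == pytest.approx(0.70710678, abs=1e-8)

    def test_zero_vector_convention(self):
        assert cosine_sim([0, 0], [1, 2]) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            cosine_sim([1, 2], [1, 2, 3])


class TestMCL:
    def test_two_disjoint_triangles(self):
        sim = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            sim[a, b] = sim[b, a] = 1.0
        cl = markov_cluster([f"n{i}" for i in range(6)], sim, 2.0)
        assert sorted(map(sorted, cl.clusters)) == [
            ["n0", "n1", "n2"], ["n3", "n4", "n5"]
        ]

    def test_single_node(self):
        cl = markov_cluster(["x"], np.zeros((1, 1)), 2.0)
        assert cl.clusters == [["x"]]

    def test_empty_graph(self):
        cl = markov_cluster([], np.zeros((0, 0)), 2.0)
        assert cl.clusters == []

    def test_complete_graph_single_cluster(self):
        sim = np.ones((5, 5))
        np.fill_diagonal(sim, 0.0)
        cl = markov_cluster([f"n{i}" for i in range(5)], sim, 2.0)
        assert len(cl.clusters) == 1

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(2, 12))
            sim = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
            sim = np.triu(sim, 1)
            sim = sim + sim.T
            nodes = [f"n{i}" for i in range(n)]
            cl = markov_cluster(nodes, sim, 2.0)
            flat = [t for grp in cl.clusters for t in grp]
            assert sorted(flat) == sorted(nodes)
            assert len(flat) == len(set(flat))

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ParameterError):
            markov_cluster(["a"], np.zeros((1, 1)), 1.0)


class TestClusterScore:
    def test_direct_substitution(self):
        score = compute_cluster_score(
            ["complex", "heterodimer", "dimer", "unknownterm"],
            {"complex": "SC", "heterodimer": "SC", "dimer": "SC"},
        )
        assert (score.known, score.unknown) == (3, 1)
        assert score.hg == 1.0
        assert score.reliability == pytest.approx(0.75)
        assert score.s == pytest.approx(0.75)

    def test_no_unknown_scores_zero(self):
        score = compute_cluster_score(["a", "b"], {"a": "X", "b": "X"})
        assert score.s == 0.0

    def test_split_labels(self):
        terms = ["a1", "a2", "b1", "b2", "u1", "u2", "u3", "u4"]
        lookup = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        score = compute_cluster_score(terms, lookup)
        assert score.hg == pytest.approx(0.5)
        assert score.reliability == pytest.approx(0.5)
        assert score.s == pytest.approx(1.0)

    def test_empty_cluster(self):
        score = compute_cluster_score([], {})
        assert score.s == 0.0 and score.reliability == 0.0

    @given(st.lists(st.sampled_from(["A", "B", "C", None]), max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_relabel_invariance(self, labels):
        terms = [f"t{i}" for i in range(len(labels))]
        lookup = {t: l for t, l in zip(terms, labels) if l is not None}
        score = compute_cluster_score(terms, lookup)
        assert 0.0 <= score.hg <= 1.0
        assert 0.0 <= score.reliability <= 1.0
        assert score.s >= 0.0
        # S depends only on the label multiset: permute label names
        swap = {"A": "B", "B": "C", "C": "A"}
        swapped = {t: swap[l] for t, l in lookup.items()}
        assert compute_cluster_score(terms, swapped).s == pytest.approx(score.s)

    def test_score_clustering_additive_and_permutation_invariant(self):
        lookup = {"complex": "SC", "heterodimer": "SC", "dimer": "SC"}
        c1 = ["complex", "heterodimer", "dimer", "x"]
        c2 = ["a1", "a2", "b1", "b2", "u1", "u2", "u3", "u4"]
        lookup2 = {**lookup, "a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        a = score_clustering(Clustering(clusters=[c1, c2]), lookup2)
        b = score_clustering(Clustering(clusters=[c2, c1]), lookup2)
        assert a == pytest.approx(0.75 + 1.0)
        assert a == pytest.approx(b)
        assert score_clustering(Clustering(clusters=[]), {}) == 0.0


class TestCategoryLexicon:
    def test_normalized_lookup(self):
        lex = build_category_lexicon([("promoters", "DNA-domain-or-region")])
        assert lex.lookup("Promoter") == "DNA-domain-or-region"

    def test_majority_vote(self):
        lex = build_category_lexicon([
            ("complex", "protein-complex"),
            ("complex", "protein-complex"),
            ("complex", "other-name"),
        ])
        assert lex.lookup("complexes") == "protein-complex"

    def test_tie_breaks_lexicographic(self):
        lex = build_category_lexicon([("site", "b-cat"), ("site", "a-cat")])
        assert lex.lookup("site") == "a-cat"

    def test_unseen_term(self):
        lex = build_category_lexicon([])
        assert lex.lookup("anything") is None


def test_cluster_terms_groups_identical_context_rows():
    # two terms with identical context vectors always share a cluster
    from entrelex.semantic import SemanticSpace

    vectors = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    space = SemanticSpace(vocabulary=["a", "b", "c"], vectors=vectors, dims=2)
    cl = cluster_terms(space, threshold=0.5, inflation=2.0)
    mapping = cl.as_mapping()
    assert mapping["a"] == mapping["b"]
    assert mapping["a"] != mapping["c"]
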