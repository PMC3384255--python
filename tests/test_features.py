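"""Feature extraction: blinding, n-grams, dependency paths and walks."""

import pytest
from hypothesis import given, settings, strategies as st

from entrelex.errors import InstanceError
from entrelex.features import (
    FeatureConfig,
    blind_sentence,
    build_instance_vector,
    dep_walk_features,
    ngram_features,
    pos_ngram_features,
    semantic_class_features,
    shortest_dep_path,
)
from entrelex.semantic import SemanticLexicon

from conftest import make_sentence, mention_for


def _binds_sentence():
    # "p65 binds IkB ."
    return make_sentence(
        [("p65", "NNP"), ("binds", "VBZ"), ("IkB", "NNP"), (".", ".")],
        [(1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")],
    )


class TestBlinding:
    def test_candidate_and_cooccurring_ggp_substituted(self):
        sent = _binds_sentence()
        cand = mention_for(sent, 0, "T1", "ggp")
        other = mention_for(sent, 2, "T2", "ggp")
        blinded, content = blind_sentence(sent, cand, [other])
        assert blinded == ["protx", "bind", "exprotx", "."]
        assert "ggpcontent:p65" in content
        assert "exggpcontent:ikb" in content

    def test_single_ggp_no_exprotx(self):
        sent = _binds_sentence()
        cand = mention_for(sent, 0, "T1", "ggp")
        blinded, _ = blind_sentence(sent, cand, [])
        assert "exprotx" not in blinded

    def test_no_raw_candidate_surface_in_positional_features(self):
        sent = _binds_sentence()
        cand = mention_for(sent, 0, "T1", "ggp")
        other = mention_for(sent, 2, "T2", "ggp")
        vec = build_instance_vector(
            "sentence", {"sentence": sent, "ggp": cand,
                         "other_ggps": [other]},
        )
        positional = [k for k in vec.features
                      if k.startswith(("ng", "pos", "sem"))]
        assert positional
        for name in positional:
            assert "p65" not in name.lower()

    def test_candidate_outside_sentence_raises(self):
        sent = _binds_sentence()
        from entrelex.model import EntityMention

        ghost = EntityMention(id="T9", kind="ggp", type_label="Protein",
                              begin=900, end=903, surface="Myc")
        with pytest.raises(InstanceError):
            blind_sentence(sent, ghost, [])


class TestNgrams:
    def test_top_pattern_trigram_name(self):
        # the classic positive cue for embedded component relations
        frag = ngram_features(["human", "protx", "promot"], 3)
        assert frag == {"ng3:human_protx_promot": 1.0}

    def test_unigrams_are_bag_of_words(self):
        frag = ngram_features(["a", "b", "a"], 1)
        assert set(frag) == {"ng1:a", "ng1:b"}

    def test_bigram_count(self):
        frag = ngram_features(["x", "y", "z"], 2)
        assert len(frag) == 2

    def test_n_longer_than_sentence_empty(self):
        assert ngram_features(["only"], 3) == {}

    @given(st.lists(st.sampled_from("abcd"), max_size=12),
           st.integers(min_value=1, max_value=5))
    @settings(deadline=None, max_examples=60)
    def test_count_bound(self, tokens, n):
        frag = ngram_features(tokens, n)
        assert len(frag) <= max(0, len(tokens) - n + 1)


class TestPosNgrams:
    def test_bigram_set(self):
        sent = make_sentence([("a", "NN"), ("b", "NN"), ("c", "VBZ")], [])
        assert set(pos_ngram_features(sent, 2)) == {"pos2:NN_NN",
                                                    "pos2:NN_VBZ"}

    def test_surface_independent(self):
        s1 = make_sentence([("x", "NN"), ("runs", "VBZ")], [])
        s2 = make_sentence([("y", "NN"), ("sits", "VBZ")], [])
        assert pos_ngram_features(s1, 2) == pos_ngram_features(s2, 2)


class TestSemanticClasses:
    def test_shared_cluster_shared_feature(self):
        lex = SemanticLexicon(clusters={"heterodim": 17, "complex": 17})
        f1 = semantic_class_features(["heterodim"], lex)
        f2 = semantic_class_features(["complex"], lex)
        assert "sem:cluster17" in f1 and "sem:cluster17" in f2

    def test_category_feature_present(self):
        lex = SemanticLexicon(categories={"complex": "protein-complex"})
        frag = semantic_class_features(["protx", "complex"], lex,
                                       ngram_n=(2,))
        assert "sem:protein-complex" in frag
        assert "semng2:protx_protein-complex" in frag

    def test_no_hit_no_features(self):
        assert semantic_class_features(["plain", "words"],
                                       SemanticLexicon()) == {}


class TestShortestPath:
    def test_chain_length(self):
        # a <- b <- c chain: governor b over a, c over b
        sent = make_sentence([("a", "NN"), ("b", "NN"), ("c", "NN")],
                             [(1, 0, "dep"), (2, 1, "dep")])
        path = shortest_dep_path(sent, 0, 2)
        assert len(path) == 2

    def test_identity_path_empty(self):
        sent = _binds_sentence()
        assert shortest_dep_path(sent, 1, 1) == []

    def test_disconnected_returns_none(self):
        sent = make_sentence([("a", "NN"), ("b", "NN"), ("c", "NN")],
                             [(1, 0, "dep")])
        assert shortest_dep_path(sent, 0, 2) is None

    @given(st.integers(min_value=2, max_value=9), st.randoms())
    @settings(deadline=None, max_examples=40)
    def test_length_matches_bfs_oracle_on_random_trees(self, n, rnd):
        tokens = [(f"w{i}", "NN") for i in range(n)]
        edges = [(rnd.randrange(i), i, rnd.choice(["amod", "dobj", "nsubj"]))
                 for i in range(1, n)]
        sent = make_sentence(tokens, edges)
        # independent BFS oracle over the undirected tree
        adj = {i: set() for i in range(n)}
        for g, d, _ in edges:
            adj[g].add(d)
            adj[d].add(g)
        from collections import deque

        for a in range(n):
            dist = {a: 0}
            q = deque([a])
            while q:
                u = q.popleft()
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            for b in range(n):
                path = shortest_dep_path(sent, a, b)
                assert path is not None
                assert len(path) == dist[b]


class TestDepWalks:
    def test_isolated_token_only_center_attributes(self):
        sent = make_sentence([("lonely", "NN")], [])
        frag = dep_walk_features(sent, 0, depth=3)
        assert set(frag) == {"tok:stem=lone", "tok:pos=NN"}

    def test_star_depth_one_counts(self):
        sent = make_sentence(
            [("hub", "NN"), ("a", "NN"), ("b", "NN"), ("c", "NN")],
            [(0, 1, "nsubj"), (0, 2, "dobj"), (0, 3, "amod")],
        )
        frag = dep_walk_features(sent, 0, depth=1)
        walks = [k for k in frag if k.startswith("dw:")]
        # three distinctly-labelled dependents x (stem + pos) features
        assert len(walks) == 6

    def test_matches_exhaustive_walk_oracle(self):
        # brute-force enumeration of simple paths up to depth 2
        import itertools

        tokens = [(f"w{i}", "NN") for i in range(6)]
        edges = [(0, 1, "x"), (1, 2, "y"), (1, 3, "z"), (3, 4, "x"),
                 (0, 5, "y")]
        sent = make_sentence(tokens, edges)
        depth = 2
        frag = dep_walk_features(sent, 0, depth=depth)
        adj = {}
        for g, d, lbl in edges:
            adj.setdefault(g, []).append((d, lbl, ">"))
            adj.setdefault(d, []).append((g, lbl, "<"))
        expected = {"tok:stem=w0", "tok:pos=NN"}
        for length in (1, 2):
            for combo in itertools.permutations(range(6), length + 1):
                if combo[0] != 0:
                    continue
                steps = []
                ok = True
                for u, v in zip(combo, combo[1:]):
                    hit = [(lbl, d) for w, lbl, d in adj.get(u, ())
                           if w == v]
                    if not hit:
                        ok = False
                        break
                    steps.append(f"{hit[0][1]}{hit[0][0]}")
                if ok:
                    prefix = "dw:" + "_".join(steps)
                    expected.add(f"{prefix}:stem=w{combo[-1]}")
                    expected.add(f"{prefix}:pos=NN")
        assert set(frag) == expected


class TestInstanceAssembly:
    def test_determinism(self):
        sent = _binds_sentence()
        cand = mention_for(sent, 0, "T1", "ggp")
        ctx = {"sentence": sent, "ggp": cand, "term": 2}
        a = build_instance_vector("edge", ctx)
        b = build_instance_vector("edge", ctx)
        assert a.features == b.features

    def test_edge_vector_has_path_and_lexical_parts(self):
        sent = _binds_sentence()
        cand = mention_for(sent, 0, "T1", "ggp")
        vec = build_instance_vector("edge", {"sentence": sent, "ggp": cand,
                                             "term": 2})
        assert any(k.startswith("path:") for k in vec.features)
        assert any(k.startswith("ng1:") for k in vec.features)

    def test_disabling_all_fragments_gives_content_only(self):
        sent = _binds_sentence()
        cand = mention_for(sent, 0, "T1", "ggp")
        cfg = FeatureConfig(use_ngrams=False, use_pos_generalization=False,
                            use_semantic_blinding=False, use_path=False,
                            use_dep_walks=False)
        vec = build_instance_vector("sentence",
                                    {"sentence": sent, "ggp": cand}, cfg)
        assert all(k.startswith(("ggpcontent:", "exggpcontent:"))
                   for k in vec.features)

    def test_missing_context_raises(self):
        sent = _binds_sentence()
        with pytest.raises(InstanceError):
            build_instance_vector("edge", {"sentence": sent})
        with pytest.raises(InstanceError):
            build_instance_vector("token", {"sentence": sent})

    def test_window_restricts_ngrams(self):
        sent = make_sentence(
            [("far", "RB"), ("away", "RB"), ("words", "NNS"),
             ("p65", "NNP"), ("binds", "VBZ")],
            [(4, 3, "nsubj")],
        )
        cand = mention_for(sent, 3, "T1", "ggp")
        cfg = FeatureConfig(window=1, use_pos_generalization=False,
                            use_semantic_blinding=False)
        vec = build_instance_vector("sentence",
                                    {"sentence": sent, "ggp": cand}, cfg)
        assert "ng1:far" not in vec.features
        assert "ng1:protx" in vec.features and "ng1:bind" in vec.features
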