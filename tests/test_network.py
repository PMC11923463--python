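import itertools
from datetime import datetime, timezone

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from drugpulse import synthetic
from drugpulse.entities import EntityMention, LexiconEntry, build_matcher, extract_corpus
from drugpulse.network import (
    IncidenceMatrix,
    Partition,
    annotate_atc,
    build_incidence,
    build_network,
    cosine,
    cosine_matrix,
    drug_symptom_network,
    export_network,
    import_network,
    load_incidence,
    louvain,
    modularity,
    partition_agreement,
    save_incidence,
    top_neighbors,
)
from drugpulse.synthetic import EntitySpec, GeneratorConfig


def _mention(canonical, tweet_id, cls="drug"):
    return EntityMention(tweet_id, 0, len(canonical), canonical, canonical, cls)


def _inc_from_dense(rows, entities, cls="drug"):
    M = sp.csr_matrix(np.asarray(rows))
    return IncidenceMatrix(
        entities=list(entities),
        tweet_ids=[f"t{j}" for j in range(M.shape[1])],
        matrix=M,
        classes={e: cls for e in entities},
    )


def set_partitions(items):
    """All partitions of a collection (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1 :]
        yield [[first]] + sub


class TestBuildIncidence:
    def test_multiplicity_collapsed(self):
        mentions = [_mention("druga", "t0"), _mention("druga", "t0")]
        inc = build_incidence(mentions, {"druga"}, ["t0", "t1"])
        assert inc.matrix.toarray().tolist() == [[1, 0]]

    def test_entity_without_mentions_excluded(self):
        mentions = [_mention("druga", "t0")]
        inc = build_incidence(mentions, {"druga", "ghost"}, ["t0"])
        assert inc.entities == ["druga"]

    def test_row_sums_match_scan_oracle(self, basic_corpus, basic_config):
        records, _ = basic_corpus
        lexicon = [
            LexiconEntry(s, c, cls)
            for s, c, cls, _ in synthetic.lexicon_entries(basic_config)
        ]
        matcher = build_matcher(lexicon)
        mentions = extract_corpus(records, matcher)
        retained = {m.canonical for m in mentions}
        tweet_ids = [r.tweet_id for r in records]
        inc = build_incidence(mentions, retained, tweet_ids)
        row_sums = np.asarray(inc.matrix.sum(axis=1)).ravel()
        for e, rs in zip(inc.entities, row_sums):
            distinct = len({m.tweet_id for m in mentions if m.canonical == e})
            assert rs == distinct

    def test_count_mode(self):
        mentions = [_mention("druga", "t0"), _mention("druga", "t0")]
        inc = build_incidence(mentions, {"druga"}, ["t0"], count_mode=True)
        assert inc.matrix.toarray().tolist() == [[2]]

    def test_mtx_roundtrip(self, tmp_path):
        inc = _inc_from_dense([[1, 0, 1], [0, 1, 1]], ["a", "b"])
        save_incidence(inc, tmp_path / "inc")
        loaded = load_incidence(tmp_path / "inc")
        assert loaded.entities == inc.entities
        assert loaded.tweet_ids == inc.tweet_ids
        assert (loaded.matrix != inc.matrix).nnz == 0


class TestCosine:
    def test_identity(self):
        u = np.array([1, 0, 1, 1])
        assert cosine(u, u) == pytest.approx(1.0)

    def test_disjoint(self):
        assert cosine(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_hand_arithmetic(self):
        # |T_u|=4, |T_v|=3, overlap 2 -> 2/sqrt(12)
        u = np.array([1, 1, 1, 1, 0])
        v = np.array([1, 1, 0, 0, 1])
        assert cosine(u, v) == pytest.approx(2 / np.sqrt(12))
        assert cosine(u, v) == pytest.approx(0.57735, abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(3), np.ones(3))

    def test_set_overlap_closed_form_50_random(self):
        # |T_i ∩ T_j| / sqrt(|T_i| |T_j|) to 1e-12 on random binary matrices
        rng = np.random.default_rng(12)
        for _ in range(50):
            n_ent = int(rng.integers(2, 21))
            n_tw = int(rng.integers(20, 201))
            M = (rng.random((n_ent, n_tw)) < 0.2).astype(int)
            M[M.sum(axis=1) == 0, 0] = 1  # no all-zero rows
            W = cosine_matrix(sp.csr_matrix(M))
            supports = [set(np.flatnonzero(M[i])) for i in range(n_ent)]
            for i in range(n_ent):
                for j in range(n_ent):
                    expected = len(supports[i] & supports[j]) / np.sqrt(
                        len(supports[i]) * len(supports[j])
                    )
                    assert abs(W[i, j] - expected) < 1e-12


class TestBuildNetwork:
    def test_tau_zero_complete_when_all_overlap(self):
        inc = _inc_from_dense(
            [[1, 1, 0], [1, 0, 1], [1, 1, 1]], ["a", "b", "c"]
        )
        G = build_network(inc, tau=0.0)
        assert G.number_of_edges() == 3

    def test_tau_one_keeps_nothing_imperfect(self):
        inc = _inc_from_dense([[1, 1, 0], [1, 0, 1]], ["a", "b"])
        G = build_network(inc, tau=1.0, drop_isolated=False)
        assert G.number_of_edges() == 0

    def test_perfect_cooccurrence_survives_high_tau(self):
        inc = _inc_from_dense([[1, 1], [1, 1]], ["a", "b"])
        G = build_network(inc, tau=0.999)
        assert G.has_edge("a", "b")
        assert G.edges["a", "b"]["weight"] == pytest.approx(1.0)

    def test_toy_matrix_brute_force(self):
        rows = [
            [1, 1, 0, 0, 1, 0],
            [1, 0, 1, 0, 0, 0],
            [0, 1, 1, 1, 0, 0],
            [0, 0, 0, 1, 1, 1],
            [1, 0, 0, 0, 0, 1],
        ]
        names = ["a", "b", "c", "d", "e"]
        tau = 0.4
        inc = _inc_from_dense(rows, names)
        G = build_network(inc, tau=tau, drop_isolated=False)
        M = np.asarray(rows)
        expected = set()
        for i, j in itertools.combinations(range(5), 2):
            w = M[i] @ M[j] / np.sqrt(M[i].sum() * M[j].sum())
            if w > tau:
                expected.add((names[i], names[j]))
        assert {tuple(sorted(e)) for e in G.edges} == expected

    def test_strict_inequality_at_tau(self):
        # weight exactly tau must be excluded
        inc = _inc_from_dense([[1, 1], [1, 0]], ["a", "b"])
        w = 1 / np.sqrt(2)
        G = build_network(inc, tau=w, drop_isolated=False)
        assert G.number_of_edges() == 0
        G = build_network(inc, tau=w - 1e-9, drop_isolated=False)
        assert G.number_of_edges() == 1

    def test_isolated_pruning_flag(self):
        inc = _inc_from_dense([[1, 1, 0], [1, 1, 0], [0, 0, 1]], ["a", "b", "c"])
        G_pruned = build_network(inc, tau=0.5)
        G_full = build_network(inc, tau=0.5, drop_isolated=False)
        assert set(G_pruned.nodes) == {"a", "b"}
        assert set(G_full.nodes) == {"a", "b", "c"}

    def test_degree_attribute(self):
        inc = _inc_from_dense([[1, 1], [1, 1], [1, 0]], ["a", "b", "c"])
        G = build_network(inc, tau=0.1)
        for v in G.nodes:
            assert G.nodes[v]["degree"] == G.degree(v)

    def test_tau_monotonicity_nested(self):
        rng = np.random.default_rng(3)
        M = (rng.random((12, 80)) < 0.15).astype(int)
        M[M.sum(axis=1) == 0, 0] = 1
        inc = _inc_from_dense(M, [f"e{i}" for i in range(12)])
        taus = [0.0, 0.005, 0.05, 0.5]
        prev_edges, prev_nodes = None, None
        for tau in taus:
            G = build_network(inc, tau=tau)
            edges = {tuple(sorted(e)) for e in G.edges}
            nodes = set(G.nodes)
            if prev_edges is not None:
                assert edges <= prev_edges
                assert nodes <= prev_nodes
            prev_edges, prev_nodes = edges, nodes


class TestDrugSymptomNetwork:
    def test_nested_symptom_weight_one(self):
        d = _inc_from_dense([[1, 1, 1, 0]], ["druga"])
        s = _inc_from_dense([[1, 1, 1, 0]], ["symb"], cls="symptom")
        G = drug_symptom_network(d, s, tau=0.5)
        assert G.edges["druga", "symb"]["weight"] == pytest.approx(1.0)

    def test_no_within_class_edges_by_default(self):
        d = _inc_from_dense([[1, 1, 0], [1, 1, 0]], ["d1", "d2"])
        s = _inc_from_dense([[1, 1, 0]], ["s1"], cls="symptom")
        G = drug_symptom_network(d, s, tau=0.1)
        assert not G.has_edge("d1", "d2")
        assert G.has_edge("d1", "s1") and G.has_edge("d2", "s1")

    def test_within_class_edges_when_configured(self):
        d = _inc_from_dense([[1, 1, 0], [1, 1, 0]], ["d1", "d2"])
        s = _inc_from_dense([[1, 1, 0]], ["s1"], cls="symptom")
        G = drug_symptom_network(d, s, tau=0.1, cross_only=False)
        assert G.has_edge("d1", "d2")

    def test_column_mismatch_rejected(self):
        d = _inc_from_dense([[1, 0]], ["d1"])
        s = _inc_from_dense([[1, 0]], ["s1"], cls="symptom")
        s.tweet_ids = ["t9", "t8"]
        with pytest.raises(ValueError):
            drug_symptom_network(d, s)

    def test_planted_pairing_top_edge(self):
        ents = (
            EntitySpec("drugx", ("drugx",), "drug", 0.05),
            EntitySpec("drugo", ("drugo",), "drug", 0.05),
            EntitySpec("sympy", ("sympy",), "symptom", 0.05),
            EntitySpec("sympz", ("sympz",), "symptom", 0.05),
        )
        blocks = np.ones((4, 4))
        blocks[0, 2] = blocks[2, 0] = 20.0  # drugx <-> sympy
        config = GeneratorConfig(
            n_tweets=20_000, entities=ents, community_blocks=blocks, seed=21
        )
        records, _ = synthetic.generate(config)
        matcher = build_matcher(
            [LexiconEntry(e.canonical, e.canonical, e.concept_class) for e in ents]
        )
        mentions = extract_corpus(records, matcher)
        tweet_ids = [r.tweet_id for r in records]
        d_inc = build_incidence(mentions, {"drugx", "drugo"}, tweet_ids)
        s_inc = build_incidence(mentions, {"sympy", "sympz"}, tweet_ids)
        G = drug_symptom_network(d_inc, s_inc, tau=0.0)
        best = max(G.edges(data="weight"), key=lambda e: e[2])
        assert {best[0], best[1]} == {"drugx", "sympy"}


def two_triangles():
    G = nx.Graph()
    G.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], weight=1.0)
    return G


class TestModularity:
    def test_two_triangles_half(self):
        G = two_triangles()
        membership = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity(G, membership) == pytest.approx(0.5)

    def test_single_community_zero(self):
        for G in (two_triangles(), nx.path_graph(5), nx.complete_graph(4)):
            nx.set_edge_attributes(G, 1.0, "weight")
            membership = {v: 0 for v in G.nodes}
            assert modularity(G, membership) == pytest.approx(0.0, abs=1e-12)

    def test_matches_networkx(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            G = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1e6)))
            for u, v in G.edges:
                G.edges[u, v]["weight"] = float(rng.random() + 0.1)
            if G.number_of_edges() == 0:
                continue
            membership = {v: int(rng.integers(3)) for v in G.nodes}
            groups = {}
            for v, c in membership.items():
                groups.setdefault(c, set()).add(v)
            expected = nx.community.modularity(G, groups.values(), weight="weight")
            assert modularity(G, membership) == pytest.approx(expected, rel=1e-12)

    def test_empty_edge_set_zero(self):
        G = nx.Graph()
        G.add_nodes_from([0, 1])
        assert modularity(G, {0: 0, 1: 1}) == 0.0

    def test_uncovered_node_rejected(self):
        G = two_triangles()
        with pytest.raises(ValueError):
            modularity(G, {0: 0})

    def test_random_partitions_never_beat_exhaustive(self):
        rng = np.random.default_rng(5)
        G = nx.gnp_random_graph(7, 0.45, seed=9)
        nx.set_edge_attributes(G, 1.0, "weight")
        nodes = list(G.nodes)
        best = max(
            modularity(G, {v: i for i, group in enumerate(p) for v in group})
            for p in set_partitions(nodes)
        )
        for _ in range(200):
            membership = {v: int(rng.integers(4)) for v in nodes}
            assert modularity(G, membership) <= best + 1e-12


class TestLouvain:
    def test_two_triangles(self):
        G = two_triangles()
        part = louvain(G)
        assert len(set(part.membership.values())) == 2
        assert part.q == pytest.approx(0.5)
        assert part.membership[0] == part.membership[1] == part.membership[2]

    def test_single_node(self):
        G = nx.Graph()
        G.add_node("only")
        part = louvain(G)
        assert part.membership == {"only": 0}
        assert part.q == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain(nx.Graph())

    def test_q_equals_modularity_of_partition(self):
        rng = np.random.default_rng(11)
        for trial in range(10):
            G = nx.gnp_random_graph(10, 0.4, seed=trial)
            for u, v in G.edges:
                G.edges[u, v]["weight"] = float(rng.random() + 0.05)
            if G.number_of_edges() == 0:
                continue
            part = louvain(G, seed=trial)
            assert part.q == pytest.approx(modularity(G, part.membership), abs=1e-12)

    def test_never_exceeds_exhaustive_optimum(self):
        rng = np.random.default_rng(13)
        for trial in range(8):
            n = int(rng.integers(4, 9))
            G = nx.gnp_random_graph(n, 0.5, seed=100 + trial)
            for u, v in G.edges:
                G.edges[u, v]["weight"] = float(rng.random() + 0.05)
            if G.number_of_edges() == 0:
                continue
            best = max(
                modularity(G, {v: i for i, grp in enumerate(p) for v in grp})
                for p in set_partitions(list(G.nodes))
            )
            part = louvain(G)
            assert part.q <= best + 1e-9

    def test_at_least_singleton_quality(self):
        G = nx.karate_club_graph()
        nx.set_edge_attributes(G, 1.0, "weight")
        part = louvain(G)
        singletons = {v: i for i, v in enumerate(G.nodes)}
        assert part.q >= modularity(G, singletons)

    def test_deterministic_given_seed(self):
        G = nx.karate_club_graph()
        nx.set_edge_attributes(G, 1.0, "weight")
        p1 = louvain(G, seed=5)
        p2 = louvain(G, seed=5)
        assert p1.membership == p2.membership

    def test_planted_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        ents = tuple(
            EntitySpec(f"d{i:02d}", (f"d{i:02d}",), "drug", 0.02) for i in range(9)
        )
        blocks = np.ones((9, 9))
        for b in range(3):
            for i, j in itertools.combinations(range(3 * b, 3 * b + 3), 2):
                blocks[i, j] = blocks[j, i] = 25.0
        config = GeneratorConfig(
            n_tweets=20_000, entities=ents, community_blocks=blocks, seed=3
        )
        records, truth = synthetic.generate(config)
        matcher = build_matcher(
            [LexiconEntry(e.canonical, e.canonical, "drug") for e in ents]
        )
        mentions = extract_corpus(records, matcher)
        inc = build_incidence(
            mentions, {e.canonical for e in ents}, [r.tweet_id for r in records]
        )
        G = build_network(inc, tau=0.05)
        part = louvain(G, seed=0)
        nodes = sorted(part.membership)
        ari = adjusted_rand_score(
            [truth.communities[v] for v in nodes],
            [part.membership[v] for v in nodes],
        )
        assert ari >= 0.9


class TestAnnotationAgreement:
    def test_identical_grouping_ari_one(self):
        part = Partition(membership={"a": 0, "b": 0, "c": 1}, q=0.0)
        ari, nmi = partition_agreement(part, {"a": "N", "b": "N", "c": "J"})
        assert ari == pytest.approx(1.0)
        assert nmi == pytest.approx(1.0)

    def test_one_community_vs_two_classes_zero(self):
        part = Partition(membership={"a": 0, "b": 0, "c": 0, "d": 0}, q=0.0)
        ari, _ = partition_agreement(part, {"a": "N", "b": "N", "c": "J", "d": "J"})
        assert ari == pytest.approx(0.0)

    def test_ari_matches_pair_counting_oracle(self):
        membership = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 1, "f": 2}
        labels = {"a": "N", "b": "J", "c": "J", "d": "J", "e": "P", "f": "P"}
        part = Partition(membership=membership, q=0.0)
        ari, _ = partition_agreement(part, labels)
        # brute-force pair counting
        nodes = sorted(membership)
        same_p = lambda u, v: membership[u] == membership[v]
        same_l = lambda u, v: labels[u] == labels[v]
        a = b = c = d = 0
        for u, v in itertools.combinations(nodes, 2):
            if same_p(u, v) and same_l(u, v):
                a += 1
            elif same_p(u, v):
                c += 1
            elif same_l(u, v):
                d += 1
            else:
                b += 1
        n_pairs = a + b + c + d
        expected_index = ((a + c) * (a + d)) / n_pairs
        max_index = 0.5 * ((a + c) + (a + d))
        expected = (a - expected_index) / (max_index - expected_index)
        assert ari == pytest.approx(expected, rel=1e-12)

    def test_unknown_labels_excluded(self):
        part = Partition(membership={"a": 0, "b": 1}, q=0.0)
        G = nx.Graph()
        G.add_nodes_from(["a", "b"])
        annotate_atc(G, {"a": "N"})
        assert G.nodes["b"]["atc"] == "unknown"
        ari, _ = partition_agreement(part, {"a": "N", "b": "unknown"})


class TestTopNeighbors:
    def _graph(self):
        G = nx.Graph()
        G.add_edge("x", "a", weight=0.9)
        G.add_edge("x", "b", weight=0.3)
        G.add_edge("x", "c", weight=0.3)
        return G

    def test_fewer_than_k(self):
        G = self._graph()
        out = top_neighbors(G, "x", k=10)
        assert len(out) == 3
        assert out[0] == ("a", 0.9)

    def test_tie_lexicographic(self):
        out = top_neighbors(self._graph(), "x", k=3)
        assert [v for v, _ in out] == ["a", "b", "c"]

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            top_neighbors(self._graph(), "zzz")

    def test_planted_strongest_partner_first(self):
        ents = (
            EntitySpec("druga", ("druga",), "drug", 0.03),
            EntitySpec("drugb", ("drugb",), "drug", 0.03),
            EntitySpec("drugc", ("drugc",), "drug", 0.03),
        )
        blocks = np.ones((3, 3))
        blocks[0, 1] = blocks[1, 0] = 25.0
        blocks[0, 2] = blocks[2, 0] = 3.0
        config = GeneratorConfig(
            n_tweets=20_000, entities=ents, community_blocks=blocks, seed=8
        )
        records, _ = synthetic.generate(config)
        matcher = build_matcher(
            [LexiconEntry(e.canonical, e.canonical, "drug") for e in ents]
        )
        mentions = extract_corpus(records, matcher)
        inc = build_incidence(
            mentions, {e.canonical for e in ents}, [r.tweet_id for r in records]
        )
        G = build_network(inc, tau=0.0)
        assert top_neighbors(G, "druga", k=10)[0][0] == "drugb"


class TestExport:
    def _network(self):
        inc = _inc_from_dense(
            [[1, 1, 0, 1], [1, 1, 0, 0], [0, 1, 1, 1]], ["a", "b", "c"]
        )
        return build_network(inc, tau=0.1)

    @pytest.mark.parametrize("fmt,ext", [("gexf", ".gexf"), ("graphml", ".graphml")])
    def test_roundtrip_weights(self, tmp_path, fmt, ext):
        G = self._network()
        part = louvain(G, seed=0)
        path = tmp_path / f"net{ext}"
        export_network(G, path, fmt=fmt, partition=part)
        H = import_network(path, fmt=fmt)
        assert set(H.nodes) == set(G.nodes)
        assert {tuple(sorted(e)) for e in H.edges} == {
            tuple(sorted(e)) for e in G.edges
        }
        for u, v in G.edges:
            assert abs(H.edges[u, v]["weight"] - G.edges[u, v]["weight"]) < 1e-9
        for v in G.nodes:
            assert H.nodes[v]["community"] == part.membership[v]

    def test_edge_csv_roundtrip(self, tmp_path):
        G = self._network()
        path = tmp_path / "edges.csv"
        export_network(G, path, fmt="edge-csv")
        H = import_network(path, fmt="edge-csv")
        for u, v in G.edges:
            assert H.edges[u, v]["weight"] == pytest.approx(
                G.edges[u, v]["weight"], abs=1e-12
            )

    def test_empty_network_valid_file(self, tmp_path):
        G = nx.Graph()
        path = tmp_path / "empty.gexf"
        export_network(G, path, fmt="gexf")
        assert import_network(path).number_of_nodes() == 0

    def test_two_node_one_edge(self, tmp_path):
        G = nx.Graph()
        G.add_edge("a", "b", weight=0.25)
        path = tmp_path / "tiny.gexf"
        export_network(G, path, fmt="gexf")
        text = path.read_text()
        assert text.count("<edge ") == 1
        H = import_network(path)
        assert H.edges["a", "b"]["weight"] == pytest.approx(0.25)

    def test_edge_symmetry_single_record(self):
        G = self._network()
        for u, v in G.edges:
            assert G.edges[u, v]["weight"] == G.edges[v, u]["weight"]
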