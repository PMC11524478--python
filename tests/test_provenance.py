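"""Processing-queue loop, content-shared table, components and MSTs."""

import itertools
import json

import numpy as np
import pytest

from figprov.evidence import EvidenceDB, PanelDescriptor, RetrievalConfig
from figprov.matching import ContentShareScore
from figprov.provenance import (
    ContentSharedTable,
    ProvenanceComponent,
    build_full_table,
    connected_components,
    export_graph,
    import_graph_json,
    maximum_spanning_tree,
    process_probe,
    provenance_graphs,
)


def db_from_vectors(vectors: dict[str, np.ndarray], panel_type="microscopy"):
    db = EvidenceDB()
    for pid, v in vectors.items():
        v = np.asarray(v, float)
        db.add(PanelDescriptor(pid, v / np.linalg.norm(v), "hash"), pid.split("/")[0], panel_type)
    return db


def table_scorer(scores: dict[frozenset, tuple[float, float]]):
    """Stub pair scorer driven by a dict of planted directional scores."""

    def scorer(p, r):
        key = frozenset((p, r))
        if key not in scores:
            return None
        a, b = scores[key]
        if p > r:
            a, b = b, a
        return ContentShareScore(a, b)

    return scorer


def angle_vec(deg):
    return np.array([np.cos(np.radians(deg)), np.sin(np.radians(deg))])


class TestProcessProbe:
    def test_no_consistent_candidates_leaves_table_empty(self):
        db = db_from_vectors({f"d{i}/f/p0": angle_vec(i * 7) for i in range(5)})
        table = ContentSharedTable()
        process_probe("d0/f/p0", db, table, RetrievalConfig(), table_scorer({}))
        assert len(table) == 0

    def test_expansion_reaches_chain_beyond_top_k(self):
        """A panel outside the probe's top-K is still examined when a
        suspicious hit's top-L neighbourhood contains it."""
        # cosine decreases with angular distance; A's top-2 are B and X,
        # C only enters through B's neighbourhood
        vecs = {
            "dA/f/p0": angle_vec(0),
            "dB/f/p0": angle_vec(10),  # A's top-1
            "dX/f/p0": angle_vec(14),  # A's top-2
            "dC/f/p0": angle_vec(18),  # outside A's K=2, inside B's L=2
            "dY/f/p0": angle_vec(60),
        }
        db = db_from_vectors(vecs)
        cfg = RetrievalConfig(K=2, L=2, queue_cap=300)
        # A's top-2 by cosine: B (35 deg) then C (37 deg)? ensure C outside:
        ranked = [p for p, _ in db.retrieve_similar("dA/f/p0", 10)]
        assert ranked.index("dC/f/p0") >= 2  # C not in A's top-K
        scores = {frozenset(("dA/f/p0", "dB/f/p0")): (0.5, 0.5)}
        examined = []
        base = table_scorer(scores)

        def spy(p, r):
            examined.append((p, r))
            return base(p, r)

        table = ContentSharedTable()
        process_probe("dA/f/p0", db, table, cfg, spy)
        assert ("dA/f/p0", "dC/f/p0") in examined

    def test_threshold_boundary_controls_expansion(self):
        """Scores of (0.009, 0.009) are recorded but do not expand the queue;
        (0.010, 0.004) does expand."""
        # C is close to B but nearly orthogonal to A, so C is reachable
        # only through B's neighbourhood expansion
        vecs = {
            "dA/f/p0": [1.0, 0.0, 0.0],
            "dB/f/p0": [0.9, 0.436, 0.0],
            "dX/f/p0": [0.85, 0.0, 0.527],
            "dC/f/p0": [0.45, 0.893, 0.0],
            "dY/f/p0": [0.0, 0.0, 1.0],
        }
        db = db_from_vectors(vecs)
        cfg = RetrievalConfig(K=2, L=2, queue_cap=300)
        ranked = [p for p, _ in db.retrieve_similar("dA/f/p0", 10)]
        assert ranked[:2] == ["dB/f/p0", "dX/f/p0"]  # C outside A's top-K

        for pair_scores, expect_c_examined in [
            ({frozenset(("dA/f/p0", "dB/f/p0")): (0.009, 0.009)}, False),
            ({frozenset(("dA/f/p0", "dB/f/p0")): (0.010, 0.004)}, True),
        ]:
            examined = []
            base = table_scorer(pair_scores)

            def spy(p, r):
                examined.append(r)
                return base(p, r)

            table = ContentSharedTable()
            process_probe("dA/f/p0", db, table, cfg, spy)
            assert table.score("dA/f/p0", "dB/f/p0") is not None  # recorded
            assert ("dC/f/p0" in examined) == expect_c_examined

    def test_queue_cap_limits_examinations(self):
        vecs = {f"d{i:03d}/f/p0": angle_vec(i * 0.2) for i in range(40)}
        db = db_from_vectors(vecs)
        cfg = RetrievalConfig(K=39, L=1, queue_cap=10)
        examined = []

        def spy(p, r):
            examined.append(r)
            return None

        process_probe("d000/f/p0", db, ContentSharedTable(), cfg, spy)
        assert len(examined) == 10

    def test_both_cells_written_together(self):
        db = db_from_vectors({"dA/f/p0": angle_vec(0), "dB/f/p0": angle_vec(4)})
        table = ContentSharedTable()
        process_probe(
            "dA/f/p0", db, table, RetrievalConfig(),
            table_scorer({frozenset(("dA/f/p0", "dB/f/p0")): (0.7, 0.3)}),
        )
        assert table.score("dA/f/p0", "dB/f/p0") == 0.7
        assert table.score("dB/f/p0", "dA/f/p0") == 0.3


class TestBuildFullTable:
    def test_each_pair_examined_once_globally(self):
        db = db_from_vectors({f"d{i}/f/p0": angle_vec(i * 3) for i in range(6)})
        calls = []

        def spy(p, r):
            calls.append(frozenset((p, r)))
            return None

        build_full_table(db, RetrievalConfig(), spy)
        assert len(calls) == len(set(calls))

    def test_no_reuse_gives_empty_table(self):
        db = db_from_vectors({f"d{i}/f/p0": angle_vec(i * 3) for i in range(6)})
        table = build_full_table(db, RetrievalConfig(), lambda p, r: None)
        assert len(table) == 0

    def test_planted_pair_fills_exactly_two_cells(self):
        db = db_from_vectors({f"d{i}/f/p0": angle_vec(i * 3) for i in range(10)})
        scores = {frozenset(("d2/f/p0", "d7/f/p0")): (0.4, 0.2)}
        table = build_full_table(db, RetrievalConfig(), table_scorer(scores))
        assert len(table) == 2
        assert table.score("d2/f/p0", "d7/f/p0") == 0.4

    def test_deterministic_across_runs(self):
        db = db_from_vectors({f"d{i}/f/p0": angle_vec(i * 5) for i in range(8)})
        scores = {
            frozenset(("d0/f/p0", "d1/f/p0")): (0.3, 0.3),
            frozenset(("d4/f/p0", "d6/f/p0")): (0.2, 0.9),
        }
        t1 = build_full_table(db, RetrievalConfig(), table_scorer(scores))
        t2 = build_full_table(db, RetrievalConfig(), table_scorer(scores))
        assert t1.entries() == t2.entries()

    def test_symmetry_of_presence(self):
        db = db_from_vectors({f"d{i}/f/p0": angle_vec(i * 5) for i in range(8)})
        scores = {frozenset(("d0/f/p0", "d3/f/p0")): (0.5, 0.0)}
        table = build_full_table(db, RetrievalConfig(), table_scorer(scores))
        for r, c, _ in table.entries():
            assert table.score(c, r) is not None

    def test_csv_roundtrip(self, tmp_path):
        db = db_from_vectors({f"d{i}/f/p0": angle_vec(i * 5) for i in range(4)})
        scores = {frozenset(("d0/f/p0", "d2/f/p0")): (0.125, 0.0625)}
        table = build_full_table(db, RetrievalConfig(), table_scorer(scores))
        table.save_csv(tmp_path / "t.csv")
        assert ContentSharedTable.load_csv(tmp_path / "t.csv").entries() == table.entries()


def random_table(rng, n_nodes=30, p_edge=0.12):
    table = ContentSharedTable()
    ids = [f"d{i:02d}/f/p0" for i in range(n_nodes)]
    for a, b in itertools.combinations(ids, 2):
        if rng.random() < p_edge:
            s = rng.uniform(0.011, 1.0)
            table.set_pair(a, b, ContentShareScore(s, s * rng.uniform(0.5, 1.0)))
    return table, ids


def bfs_partition(edges, nodes):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, parts = set(), []
    for n in nodes:
        if n in seen or not adj[n]:
            continue
        comp, queue = set(), [n]
        while queue:
            cur = queue.pop()
            if cur in comp:
                continue
            comp.add(cur)
            queue.extend(adj[cur] - comp)
        if len(comp) > 1:
            parts.append(frozenset(comp))
        seen |= comp
    return set(parts)


class TestConnectedComponents:
    def test_empty_table_no_components(self):
        assert connected_components(ContentSharedTable(), 0.01) == []

    def test_two_chains(self):
        table = ContentSharedTable()
        for a, b in [("A", "B"), ("B", "C"), ("D", "E")]:
            table.set_pair(a, b, ContentShareScore(0.5, 0.5))
        comps = connected_components(table, 0.01)
        assert [c.nodes for c in comps] == [["A", "B", "C"], ["D", "E"]]

    def test_matches_bfs_oracle_on_random_tables(self, rng):
        for _ in range(10):
            table, ids = random_table(rng)
            comps = connected_components(table, 0.01)
            got = {frozenset(c.nodes) for c in comps}
            edges = [(r, c) for r, c, _ in table.pairs(0.01)]
            assert got == bfs_partition(edges, ids)

    def test_threshold_is_inclusive(self):
        table = ContentSharedTable()
        table.set_pair("A", "B", ContentShareScore(0.01, 0.001))
        table.set_pair("C", "D", ContentShareScore(0.009, 0.009))
        comps = connected_components(table, 0.01)
        assert [c.nodes for c in comps] == [["A", "B"]]


def exhaustive_mst_weight(nodes, edges):
    """Max spanning-tree weight by enumeration over all edge subsets."""
    best = None
    n = len(nodes)
    for subset in itertools.combinations(edges, n - 1):
        uf = {x: x for x in nodes}

        def find(x):
            while uf[x] != x:
                uf[x] = uf[uf[x]]
                x = uf[x]
            return x

        ok = True
        for u, v, _ in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            uf[ru] = rv
        if ok:
            w = sum(e[2] for e in subset)
            best = w if best is None else max(best, w)
    return best


class TestMaximumSpanningTree:
    def test_tree_input_returned_unchanged(self):
        comp = ProvenanceComponent(
            ["A", "B", "C"], [("A", "B", 0.5), ("B", "C", 0.4)]
        )
        tree = maximum_spanning_tree(comp)
        assert tree.edges == [("A", "B", 0.5), ("B", "C", 0.4)]

    def test_triangle_drops_minimum_edge(self):
        comp = ProvenanceComponent(
            ["A", "B", "C"],
            [("A", "B", 0.9), ("A", "C", 0.5), ("B", "C", 0.8)],
        )
        tree = maximum_spanning_tree(comp)
        assert ("A", "C", 0.5) not in tree.edges
        assert len(tree.edges) == 2

    def test_weight_equals_enumeration_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(3, 8))
            nodes = [f"n{i}" for i in range(n)]
            edges = []
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.6:
                    edges.append((a, b, float(rng.integers(1, 10)) / 10.0))
            part = bfs_partition([(u, v) for u, v, _ in edges], nodes)
            if len(part) != 1 or len(next(iter(part))) != n:
                continue  # need a connected graph
            tree = maximum_spanning_tree(ProvenanceComponent(nodes, edges))
            assert len(tree.edges) == n - 1
            got = sum(w for _, _, w in tree.edges)
            assert got == pytest.approx(exhaustive_mst_weight(nodes, edges))

    def test_deterministic_tie_break(self):
        comp = ProvenanceComponent(
            ["A", "B", "C"],
            [("A", "B", 0.5), ("A", "C", 0.5), ("B", "C", 0.5)],
        )
        tree = maximum_spanning_tree(comp)
        assert tree.edges == [("A", "B", 0.5), ("A", "C", 0.5)]

    def test_hub_is_highest_degree_node(self):
        comp = ProvenanceComponent(
            ["A", "B", "C", "D"],
            [("A", "B", 0.9), ("B", "C", 0.8), ("B", "D", 0.7)],
        )
        assert maximum_spanning_tree(comp).hub == "B"


class TestExport:
    def _tree(self):
        comp = ProvenanceComponent(
            ["docA/fig0/p0", "docB/fig1/p2"], [("docA/fig0/p0", "docB/fig1/p2", 0.75)]
        )
        return maximum_spanning_tree(comp)

    def test_graphml_node_and_edge_counts(self, tmp_path):
        import networkx as nx

        export_graph(self._tree(), tmp_path / "g.graphml", "graphml")
        g = nx.read_graphml(tmp_path / "g.graphml")
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_json_roundtrip_byte_identical(self, tmp_path):
        tree = self._tree()
        export_graph(tree, tmp_path / "a.json", "json")
        back = import_graph_json(tmp_path / "a.json")
        export_graph(back, tmp_path / "b.json", "json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_dot_has_tree_edge_count(self, tmp_path, rng):
        table, _ = random_table(rng, n_nodes=12, p_edge=0.5)
        graphs = provenance_graphs(table, 0.01)
        for g in graphs:
            export_graph(g, tmp_path / "g.dot", "dot")
            text = (tmp_path / "g.dot").read_text()
            assert text.count(" -- ") == len(g.nodes) - 1
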