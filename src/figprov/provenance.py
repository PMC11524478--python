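"""Image-level provenance: the probe loop, the content-shared table, and graphs.

Each indexed panel P is used once as a *probe*: its top-K most similar
same-type panels from other documents seed a FIFO processing queue; every
dequeued candidate is verified at pixel level and, when consistent, the pair's
two directional content-sharing scores are written into the content-shared
table. A suspicious hit (either directional score at or above the 1%
threshold) expands the queue with the candidate's own top-L neighbours, so a
chain of edited copies is reachable even when its far end is not similar to
the probe itself. A probe stops after the queue empties or ``queue_cap``
candidates have been examined.

The filled table is read as an adjacency structure: linking every pair whose
best directional score reaches the threshold yields connected components;
each component's maximum spanning tree is the provenance graph used for
inspection (the highest-degree node is a natural starting point for an
integrity investigation).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx

from .errors import ValidationError
from .evidence import EvidenceDB, RetrievalConfig
from .matching import (
    ContentShareScore,
    InterestPointSet,
    MatchConfig,
    content_sharing_score,
    extract_keypoints,
    match_and_verify,
    _flip_raster,
)

#: A pair scorer returns the directional scores of a consistent pair, or
#: None when the pair is inconsistent. Injectable for testing and for
#: alternative verification strategies.
PairScorer = Callable[[str, str], ContentShareScore | None]


class ContentSharedTable:
    """Sparse directional score table plus the global processed-pair registry.

    Cell (P, R) holds the content-sharing score of P with respect to R; the
    two directional cells of a pair are always written together. Panels of
    the same document are never paired, and there is no diagonal.
    """

    def __init__(self) -> None:
        self._scores: dict[tuple[str, str], float] = {}
        self._processed: set[frozenset[str]] = set()

    def __len__(self) -> int:
        return len(self._scores)

    def score(self, row: str, col: str) -> float | None:
        return self._scores.get((row, col))

    def set_pair(self, P: str, R: str, score: ContentShareScore) -> None:
        if P == R:
            raise ValidationError("no diagonal entries in the content-shared table")
        self._scores[(P, R)] = score.score_P_given_R
        self._scores[(R, P)] = score.score_R_given_P

    def mark_processed(self, P: str, R: str) -> None:
        self._processed.add(frozenset((P, R)))

    def was_processed(self, P: str, R: str) -> bool:
        return frozenset((P, R)) in self._processed

    def entries(self) -> list[tuple[str, str, float]]:
        return sorted((r, c, s) for (r, c), s in self._scores.items())

    def pairs(self, threshold: float | None = None) -> list[tuple[str, str, float]]:
        """Unordered pairs with their best directional score, sorted.

        With a threshold, only pairs whose best score reaches it.
        """
        out = []
        for (r, c), s in self._scores.items():
            if r < c:
                best = max(s, self._scores[(c, r)])
                if threshold is None or best >= threshold:
                    out.append((r, c, best))
        return sorted(out)

    # -- persistence (CSV: row_id,col_id,score) ------------------------------

    def save_csv(self, path: str | Path) -> None:
        lines = ["row_id,col_id,score"]
        lines += [f"{r},{c},{s:.17g}" for r, c, s in self.entries()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load_csv(cls, path: str | Path) -> "ContentSharedTable":
        table = cls()
        rows = Path(path).read_text().splitlines()[1:]
        for line in rows:
            if not line.strip():
                continue
            r, c, s = line.split(",")
            table._scores[(r, c)] = float(s)
        for r, c in list(table._scores):
            table._processed.add(frozenset((r, c)))
        return table


def default_pair_scorer(
    db: EvidenceDB,
    cfg: RetrievalConfig = RetrievalConfig(),
    mcfg: MatchConfig = MatchConfig(),
) -> PairScorer:
    """SIFT + robust homography scorer with a per-panel keypoint cache."""
    kp_cache: dict[str, InterestPointSet] = {}
    kp_flip_cache: dict[str, InterestPointSet] = {}

    def _kp(panel_id: str) -> InterestPointSet:
        if panel_id not in kp_cache:
            kp_cache[panel_id] = extract_keypoints(db.panel(panel_id))
        return kp_cache[panel_id]

    def _kp_flipped(panel_id: str) -> InterestPointSet:
        if panel_id not in kp_flip_cache:
            raster = _flip_raster(db.panel(panel_id).raster, mcfg.flip_axis)
            kp_flip_cache[panel_id] = extract_keypoints(raster)
        return kp_flip_cache[panel_id]

    def scorer(pid_P: str, pid_R: str) -> ContentShareScore | None:
        P, R = db.panel(pid_P), db.panel(pid_R)
        match = match_and_verify(
            P,
            R,
            cfg,
            mcfg,
            kp_P=_kp(pid_P),
            kp_R=_kp(pid_R),
            kp_P_flipped=lambda: _kp_flipped(pid_P),
        )
        if not match.consistent:
            return None
        return content_sharing_score(match, P, R, mcfg.flip_axis)

    return scorer


def process_probe(
    probe: str,
    db: EvidenceDB,
    table: ContentSharedTable,
    cfg: RetrievalConfig = RetrievalConfig(),
    scorer: PairScorer | None = None,
) -> ContentSharedTable:
    """Run the processing-queue loop for one probe panel, updating the table.

    The queue starts as the probe's top-K retrieval; candidates are examined
    FIFO. Pairs already in the global processed registry are skipped without
    consuming budget. A consistent pair writes both directional cells; if
    either score reaches ``cfg.score_threshold`` the candidate's own top-L
    neighbours are enqueued (same-type, excluding the probe's document,
    deduplicated). The loop stops when the queue empties or ``cfg.queue_cap``
    candidates have been examined.
    """
    if scorer is None:
        scorer = default_pair_scorer(db, cfg)
    probe_doc = db.doc_id(probe)

    queue: deque[str] = deque(pid for pid, _ in db.retrieve_similar(probe, cfg.K))
    seen: set[str] = set(queue)
    examined = 0
    while queue and examined < cfg.queue_cap:
        cand = queue.popleft()
        if table.was_processed(probe, cand):
            continue
        table.mark_processed(probe, cand)
        examined += 1
        score = scorer(probe, cand)
        if score is None:
            continue
        table.set_pair(probe, cand, score)
        if score.max >= cfg.score_threshold:
            for pid, _ in db.retrieve_similar(cand, cfg.L):
                if pid == probe or pid in seen:
                    continue
                if db.doc_id(pid) == probe_doc:
                    continue
                queue.append(pid)
                seen.add(pid)
    return table


def build_full_table(
    db: EvidenceDB,
    cfg: RetrievalConfig = RetrievalConfig(),
    scorer: PairScorer | None = None,
    panel_ids: Iterable[str] | None = None,
) -> ContentSharedTable:
    """Probe every panel (sorted id order) against the shared table/registry.

    The shared processed-pair registry guarantees each unordered pair is
    examined at most once across all probes, so the table's contents do not
    depend on probe order (only which probe's budget paid for a pair does).
    """
    if scorer is None:
        scorer = default_pair_scorer(db, cfg)
    table = ContentSharedTable()
    for probe in sorted(panel_ids) if panel_ids is not None else db.panel_ids:
        process_probe(probe, db, table, cfg, scorer)
    return table


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

@dataclass
class ProvenanceComponent:
    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (u, v, weight), u < v


@dataclass
class ProvenanceGraph:
    nodes: list[str]
    edges: list[tuple[str, str, float]]
    degrees: dict[str, int]

    @property
    def hub(self) -> str | None:
        """Highest-degree node: the natural entry point of an investigation."""
        if not self.nodes:
            return None
        return max(self.nodes, key=lambda n: (self.degrees[n], n))


def connected_components(
    table: ContentSharedTable, threshold: float = 0.01
) -> list[ProvenanceComponent]:
    """Link pairs whose best directional score reaches the threshold.

    Components are returned largest first, ties by smallest node id; edges
    are stored with the pair's best directional score as weight.
    """
    g = nx.Graph()
    for u, v, w in table.pairs(threshold):
        g.add_edge(u, v, weight=w)
    comps = []
    for nodes in nx.connected_components(g):
        nodes = sorted(nodes)
        edges = sorted(
            (min(u, v), max(u, v), d["weight"]) for u, v, d in g.edges(nodes, data=True)
        )
        comps.append(ProvenanceComponent(nodes, edges))
    comps.sort(key=lambda c: (-len(c.nodes), c.nodes[0]))
    return comps


def maximum_spanning_tree(component: ProvenanceComponent) -> ProvenanceGraph:
    """Kruskal maximum spanning tree with deterministic tie-breaking.

    Among equal-weight edges the lexicographically smaller (u, v) pair is
    preferred, so identical inputs give identical trees on any platform.
    """
    uf = nx.utils.UnionFind(component.nodes)
    tree_edges = []
    for u, v, w in sorted(component.edges, key=lambda e: (-e[2], e[0], e[1])):
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree_edges.append((u, v, w))
    degrees = {n: 0 for n in component.nodes}
    for u, v, _ in tree_edges:
        degrees[u] += 1
        degrees[v] += 1
    return ProvenanceGraph(list(component.nodes), sorted(tree_edges), degrees)


def provenance_graphs(
    table: ContentSharedTable, threshold: float = 0.01
) -> list[ProvenanceGraph]:
    return [maximum_spanning_tree(c) for c in connected_components(table, threshold)]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _node_attrs(node: str) -> dict[str, str]:
    parts = node.split("/")
    return {
        "panel_id": node,
        "doc_id": parts[0],
        "figure": "/".join(parts[:2]) if len(parts) > 1 else parts[0],
    }


def _to_nx(graph: ProvenanceGraph) -> nx.Graph:
    g = nx.Graph()
    for node in graph.nodes:
        g.add_node(node, **_node_attrs(node))
    for u, v, w in graph.edges:
        g.add_edge(u, v, weight=w)
    return g


def export_graph(graph: ProvenanceGraph, path: str | Path, fmt: str = "json") -> None:
    """Write a provenance graph as GraphML, DOT or JSON."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_to_nx(graph), path)
    elif fmt == "dot":
        lines = ["graph provenance {"]
        for node in graph.nodes:
            a = _node_attrs(node)
            lines.append(f'  "{node}" [doc_id="{a["doc_id"]}", figure="{a["figure"]}"];')
        for u, v, w in graph.edges:
            lines.append(f'  "{u}" -- "{v}" [weight={w:.17g}, label="{w:.3f}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = {
            "nodes": [_node_attrs(n) for n in graph.nodes],
            "edges": [{"source": u, "target": v, "weight": w} for u, v, w in graph.edges],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        raise ValidationError(f"unknown export format {fmt!r}")


def import_graph_json(path: str | Path) -> ProvenanceGraph:
    """Read back a JSON export losslessly."""
    payload = json.loads(Path(path).read_text())
    nodes = [n["panel_id"] for n in payload["nodes"]]
    edges = [(e["source"], e["target"], e["weight"]) for e in payload["edges"]]
    degrees = {n: 0 for n in nodes}
    for u, v, _ in edges:
        degrees[u] += 1
        degrees[v] += 1
    return ProvenanceGraph(nodes, edges, degrees)
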