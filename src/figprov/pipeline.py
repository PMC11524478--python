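"""End-to-end convenience driver: panels in, provenance at both levels out."""

from __future__ import annotations

from dataclasses import dataclass

from .docgraph import DocumentMatrix, build_document_matrix, document_components_and_mst
from .evidence import EvidenceDB, RetrievalConfig, build_evidence_db
from .ingest import Panel
from .matching import MatchConfig
from .provenance import (
    ContentSharedTable,
    ProvenanceGraph,
    build_full_table,
    connected_components,
    maximum_spanning_tree,
)


@dataclass
class PipelineResult:
    db: EvidenceDB
    table: ContentSharedTable
    graphs: list[ProvenanceGraph]          # image level, one MST per component
    doc_matrix: DocumentMatrix
    doc_graphs: list[ProvenanceGraph]      # document level

    # -- prediction views for the evaluation metrics -------------------------

    @property
    def image_links(self) -> list[tuple[str, str]]:
        return [(p, r) for p, r, _ in self.table.pairs(self._threshold)]

    @property
    def image_groups(self) -> list[set[str]]:
        return [set(g.nodes) for g in self.graphs]

    @property
    def image_suspicious(self) -> set[str]:
        return {n for g in self.graphs for n in g.nodes}

    @property
    def document_links(self) -> list[tuple[str, str]]:
        out = []
        ids, counts = self.doc_matrix.doc_ids, self.doc_matrix.counts
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if counts[i, j] >= 1:
                    out.append((ids[i], ids[j]))
        return out

    @property
    def document_groups(self) -> list[set[str]]:
        return [set(g.nodes) for g in self.doc_graphs]

    @property
    def document_suspicious(self) -> set[str]:
        return {n for g in self.doc_graphs for n in g.nodes}

    _threshold: float = 0.01


def analyze_panels(
    panels: list[Panel],
    cfg: RetrievalConfig = RetrievalConfig(),
    mcfg: MatchConfig = MatchConfig(),
    backend: str = "hash",
) -> PipelineResult:
    """Index, cross-verify and graph a corpus of panels at both levels."""
    from .provenance import default_pair_scorer

    db = build_evidence_db(panels, backend)
    table = build_full_table(db, cfg, default_pair_scorer(db, cfg, mcfg))
    components = connected_components(table, cfg.score_threshold)
    graphs = [maximum_spanning_tree(c) for c in components]
    doc_matrix = build_document_matrix(
        table, {p.panel_id: p.doc_id for p in panels}, cfg.score_threshold
    )
    doc_graphs = document_components_and_mst(doc_matrix)
    result = PipelineResult(db, table, graphs, doc_matrix, doc_graphs)
    result._threshold = cfg.score_threshold
    return result
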