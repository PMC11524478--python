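"""Document-level provenance: the n x n shared-element matrix and its graphs.

Panel-level evidence is aggregated per document pair: cell (i, j) of the
matrix counts the suspicious panel pairs (best directional content-sharing
score at or above the threshold) whose panels belong to documents i and j.
Documents linked by at least one suspicious pair form connected components;
each component's maximum spanning tree — on the integer shared-element
counts — is the document provenance graph. Articles fabricated by one paper
mill tend to land in a single component despite unrelated authors or topics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .provenance import (
    ContentSharedTable,
    ProvenanceComponent,
    ProvenanceGraph,
    maximum_spanning_tree,
)

import networkx as nx


@dataclass
class DocumentMatrix:
    """Symmetric shared-element counts with a zero diagonal."""

    doc_ids: list[str]
    counts: np.ndarray  # (n, n) int

    @property
    def n(self) -> int:
        return len(self.doc_ids)

    def count(self, doc_i: str, doc_j: str) -> int:
        i, j = self.doc_ids.index(doc_i), self.doc_ids.index(doc_j)
        return int(self.counts[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.doc_ids, columns=self.doc_ids)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def load_csv(cls, path: str | Path) -> "DocumentMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(list(frame.index), frame.to_numpy(dtype=int))


def panel_doc_map(panel_metadata: Mapping[str, Mapping[str, str] | str]) -> dict[str, str]:
    """Normalize ``{panel_id: doc_id}`` or ``{panel_id: {"doc_id": ...}}``."""
    out = {}
    for pid, meta in panel_metadata.items():
        out[pid] = meta if isinstance(meta, str) else meta["doc_id"]
    return out


def build_document_matrix(
    table: ContentSharedTable,
    panel_metadata: Mapping[str, Mapping[str, str] | str],
    threshold: float = 0.01,
    doc_ids: list[str] | None = None,
) -> DocumentMatrix:
    """Count suspicious panel pairs per document pair.

    ``doc_ids`` may list the whole corpus (so clean documents appear as
    zero rows); by default only documents owning scored panels appear.
    Every panel in the table must map to a document.
    """
    doc_of = panel_doc_map(panel_metadata)
    pairs = table.pairs(threshold)
    for p, r, _ in pairs:
        for pid in (p, r):
            if pid not in doc_of:
                raise ValidationError(f"panel {pid!r} has no document mapping")
    if doc_ids is None:
        doc_ids = sorted({doc_of[pid] for pair in pairs for pid in pair[:2]})
    else:
        doc_ids = sorted(doc_ids)
    index = {d: i for i, d in enumerate(doc_ids)}
    counts = np.zeros((len(doc_ids), len(doc_ids)), dtype=int)
    for p, r, _ in pairs:
        i, j = index[doc_of[p]], index[doc_of[r]]
        if i == j:
            continue  # same-document pairs never enter the table, but be safe
        counts[i, j] += 1
        counts[j, i] += 1
    return DocumentMatrix(doc_ids, counts)


def document_components_and_mst(matrix: DocumentMatrix) -> list[ProvenanceGraph]:
    """Document provenance graphs: one MST per connected component of M.

    Documents are linked when they share at least one suspicious panel pair;
    edge weight is the shared-element count. Components come back largest
    first; isolated (all-zero) documents appear in no graph.
    """
    g = nx.Graph()
    n = matrix.n
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.counts[i, j] >= 1:
                g.add_edge(matrix.doc_ids[i], matrix.doc_ids[j], weight=int(matrix.counts[i, j]))
    graphs = []
    for nodes in nx.connected_components(g):
        nodes = sorted(nodes)
        edges = sorted(
            (min(u, v), max(u, v), float(d["weight"]))
            for u, v, d in g.edges(nodes, data=True)
        )
        graphs.append(maximum_spanning_tree(ProvenanceComponent(nodes, edges)))
    graphs.sort(key=lambda t: (-len(t.nodes), t.nodes[0]))
    return graphs
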