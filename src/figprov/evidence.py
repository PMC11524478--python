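"""Panel descriptors, the evidence database, and top-K retrieval.

Every panel gets a fixed-length global descriptor meant to survive the
post-processing routinely applied to figure panels — rescaling, mirroring,
recompression, mild recoloring — so that a processed copy still retrieves its
original. The default ``hash`` backend is deterministic and weight-free: the
panel is downscaled to a fixed grid, converted to luma, described by the
magnitudes of its low-frequency 2-D DCT coefficients (magnitudes are
invariant to horizontal/vertical mirroring, which only flips coefficient
signs), and concatenated with per-channel color histograms. A pretrained
convolutional backend can be plugged in where weights are available.

Retrieval is an exact cosine-similarity scan over all stored vectors of the
query's panel type, excluding panels from the query's own document — reuse
within one document is not evidence of cross-document fabrication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import scipy.fft
from skimage.transform import resize

from .errors import ConfigurationError, ValidationError
from .ingest import Panel

HASH_GRID = 64          # downscale target before the DCT
HASH_DCT_BLOCK = 12     # keep the 12x12 lowest-frequency magnitudes
HASH_HIST_BINS = 8      # per RGB channel
HASH_HIST_WEIGHT = 0.5  # structure dominates color


@dataclass(frozen=True)
class RetrievalConfig:
    """Knobs of the retrieval/matching/queue pipeline.

    Defaults: K=400 retrieved candidates per probe, L=40 expansion
    neighbours per suspicious hit, 300 examined panels per probe, 1%
    content-sharing suspicion threshold, 20 verified inliers for a pair to
    count as consistent.
    """

    K: int = 400
    L: int = 40
    queue_cap: int = 300
    score_threshold: float = 0.01
    min_inliers: int = 20

    def __post_init__(self) -> None:
        if self.L > self.K:
            raise ValidationError("L must not exceed K")


@dataclass
class PanelDescriptor:
    panel_id: str
    vector: np.ndarray
    backend_name: str

    @property
    def dim(self) -> int:
        return int(self.vector.shape[0])


def _luma(raster: np.ndarray) -> np.ndarray:
    return raster.astype(np.float64) @ np.array([0.299, 0.587, 0.114])


def _l2(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def hash_descriptor(raster: np.ndarray) -> np.ndarray:
    """Deterministic mirror-invariant global descriptor of an RGB raster."""
    gray = _luma(raster) / 255.0
    small = resize(gray, (HASH_GRID, HASH_GRID), anti_aliasing=True)
    coeffs = scipy.fft.dctn(small, norm="ortho")
    structure = np.abs(coeffs[:HASH_DCT_BLOCK, :HASH_DCT_BLOCK]).ravel()
    hist = np.concatenate(
        [
            np.histogram(raster[..., c], bins=HASH_HIST_BINS, range=(0, 256))[0]
            for c in range(3)
        ]
    ).astype(np.float64)
    hist /= max(1.0, raster.shape[0] * raster.shape[1])
    return _l2(np.concatenate([_l2(structure), HASH_HIST_WEIGHT * _l2(hist)]))


def describe_panel(
    panel: Panel,
    backend: str = "hash",
    conv_model: Callable[[np.ndarray], np.ndarray] | None = None,
) -> PanelDescriptor:
    """Compute the L2-normalized global descriptor of a panel.

    ``backend='conv'`` expects a callable wrapping a pretrained network
    (raster -> feature vector); without one a ConfigurationError points at
    the built-in hash backend.
    """
    if backend == "hash":
        vector = hash_descriptor(panel.raster)
    elif backend == "conv":
        if conv_model is None:
            raise ConfigurationError(
                "conv descriptor backend needs a loaded model; "
                "pass conv_model= or use backend='hash'"
            )
        vector = _l2(np.asarray(conv_model(panel.raster), dtype=np.float64))
    else:
        raise ConfigurationError(f"unknown descriptor backend {backend!r}")
    return PanelDescriptor(panel.panel_id, vector, backend)


class EvidenceDB:
    """In-memory descriptor store with metadata and cosine retrieval."""

    def __init__(self, backend_name: str = "hash") -> None:
        self.backend_name = backend_name
        self._vectors: dict[str, np.ndarray] = {}
        self._meta: dict[str, dict[str, str]] = {}
        self._panels: dict[str, Panel] = {}

    def __len__(self) -> int:
        return len(self._vectors)

    def __contains__(self, panel_id: str) -> bool:
        return panel_id in self._vectors

    @property
    def panel_ids(self) -> list[str]:
        return sorted(self._vectors)

    def add(self, descriptor: PanelDescriptor, doc_id: str, panel_type: str) -> None:
        if self._vectors and descriptor.dim != next(iter(self._vectors.values())).shape[0]:
            raise ValidationError("descriptor dimensionality mismatch")
        self._vectors[descriptor.panel_id] = descriptor.vector
        self._meta[descriptor.panel_id] = {"doc_id": doc_id, "panel_type": panel_type}

    def add_panel(
        self,
        panel: Panel,
        backend: str | None = None,
        conv_model: Callable[[np.ndarray], np.ndarray] | None = None,
        keep_raster: bool = True,
    ) -> PanelDescriptor:
        desc = describe_panel(panel, backend or self.backend_name, conv_model)
        self.add(desc, panel.doc_id, panel.panel_type)
        if keep_raster:
            self._panels[panel.panel_id] = panel
        return desc

    def meta(self, panel_id: str) -> dict[str, str]:
        try:
            return self._meta[panel_id]
        except KeyError:
            raise ValidationError(f"unknown panel id {panel_id!r}") from None

    def doc_id(self, panel_id: str) -> str:
        return self.meta(panel_id)["doc_id"]

    def panel(self, panel_id: str) -> Panel:
        try:
            return self._panels[panel_id]
        except KeyError:
            raise ValidationError(
                f"panel raster for {panel_id!r} not stored in this database"
            ) from None

    def vector(self, panel_id: str) -> np.ndarray:
        try:
            return self._vectors[panel_id]
        except KeyError:
            raise ValidationError(f"unknown panel id {panel_id!r}") from None

    def retrieve_similar(self, query: str, k: int) -> list[tuple[str, float]]:
        """Top-k same-type, other-document panels by cosine, descending.

        Ties are broken by ascending panel_id so rankings are reproducible
        across runs and platforms. The query itself is never returned.
        """
        q_meta = self.meta(query)
        q_vec = self._vectors[query]
        candidates = [
            pid
            for pid, m in self._meta.items()
            if pid != query
            and m["panel_type"] == q_meta["panel_type"]
            and m["doc_id"] != q_meta["doc_id"]
        ]
        if not candidates:
            return []
        candidates.sort()
        mat = np.stack([self._vectors[pid] for pid in candidates])
        cosines = mat @ q_vec
        order = np.lexsort((np.arange(len(candidates)), -cosines))
        return [(candidates[i], float(cosines[i])) for i in order[:k]]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist as a raw float64 array + JSON metadata sidecar."""
        path = Path(path)
        ids = self.panel_ids
        mat = np.stack([self._vectors[i] for i in ids]) if ids else np.zeros((0, 0))
        mat.astype(np.float64).tofile(path)
        sidecar = {
            "backend_name": self.backend_name,
            "dim": int(mat.shape[1]) if ids else 0,
            "panel_ids": ids,
            "meta": {i: self._meta[i] for i in ids},
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EvidenceDB":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        db = cls(sidecar["backend_name"])
        n, dim = len(sidecar["panel_ids"]), sidecar["dim"]
        mat = np.fromfile(path, dtype=np.float64).reshape(n, dim) if n else None
        for row, pid in enumerate(sidecar["panel_ids"]):
            m = sidecar["meta"][pid]
            db.add(PanelDescriptor(pid, mat[row], db.backend_name), m["doc_id"], m["panel_type"])
        return db


def build_evidence_db(
    panels: list[Panel],
    backend: str = "hash",
    conv_model: Callable[[np.ndarray], np.ndarray] | None = None,
) -> EvidenceDB:
    """Describe and index a list of panels (rasters kept for matching)."""
    db = EvidenceDB(backend)
    for panel in sorted(panels, key=lambda p: p.panel_id):
        db.add_panel(panel, backend, conv_model)
    return db
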