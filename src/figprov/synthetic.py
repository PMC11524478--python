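"""Synthetic corpora of compound figures with planted cross-document reuse.

The generator emulates the structure a paper-mill investigation faces: a
corpus of documents, most of them clean distractors, in which a few "mill"
documents share panels that were cropped, rescaled, mirrored, recolored,
recompressed or spliced before reuse. Panels are procedural stand-ins for the
five biomedical panel types (fluorescence-micrograph-like blob fields,
low-entropy blot bands, smooth body-imaging anatomy, sparse flow-cytometry
scatter, bar charts). Every planted reuse is recorded — members, documents,
links, transformation parameters — in a truth JSON, so the whole pipeline can
be scored with no external dataset.

Everything is driven by one integer seed; the same spec and seed reproduce a
byte-identical corpus.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize, rotate

from . import minipdf
from .errors import ValidationError
from .ingest import PANEL_TYPES
from .metrics import GroundTruth

PANEL_SIZE = 160       # base side of a synthesized panel, px
GUTTER = 14            # white gutter between panels inside a figure, px
MARGIN = 10            # white margin around a figure, px
GRID_COLS = 2

DEFAULT_TYPE_MIX = {
    "microscopy": 0.45,
    "blots": 0.15,
    "body_imaging": 0.15,
    "flow_cytometry": 0.15,
    "graphs_plots": 0.10,
}


@dataclass(frozen=True)
class TransformOp:
    """One reuse-time edit; parameters are recorded verbatim in the truth."""

    kind: str  # crop | rescale | hflip | vflip | color_shift | jpeg_recompress
    #          # | gaussian_noise | splice_onto_background | rotate
    params: tuple = ()

    def as_dict(self) -> dict:
        return {"kind": self.kind, "params": list(self.params)}


def apply_transform(raster: np.ndarray, op: TransformOp, rng: np.random.Generator) -> np.ndarray:
    h, w = raster.shape[:2]
    if op.kind == "crop":
        fx0, fy0, fx1, fy1 = op.params
        return raster[int(fy0 * h) : int(fy1 * h), int(fx0 * w) : int(fx1 * w)].copy()
    if op.kind == "rescale":
        (factor,) = op.params
        out = resize(
            raster, (round(h * factor), round(w * factor)), anti_aliasing=factor < 1
        )
        return (np.clip(out, 0, 1) * 255).astype(np.uint8)
    if op.kind == "hflip":
        return raster[:, ::-1].copy()
    if op.kind == "vflip":
        return raster[::-1, :].copy()
    if op.kind == "color_shift":
        shift = np.asarray(op.params, dtype=np.int16)  # (dr, dg, db)
        return np.clip(raster.astype(np.int16) + shift, 0, 255).astype(np.uint8)
    if op.kind == "jpeg_recompress":
        (quality,) = op.params
        buf = io.BytesIO()
        Image.fromarray(raster).save(buf, format="JPEG", quality=int(quality))
        buf.seek(0)
        return np.asarray(Image.open(buf).convert("RGB"))
    if op.kind == "gaussian_noise":
        sigma, seed = op.params
        noise_rng = np.random.default_rng(int(seed))
        noisy = raster.astype(np.float64) + noise_rng.normal(0, sigma, raster.shape)
        return np.clip(noisy, 0, 255).astype(np.uint8)
    if op.kind == "splice_onto_background":
        (pad,) = op.params
        pad = int(pad)
        canvas = np.full((h + 2 * pad, w + 2 * pad, 3), 246, dtype=np.uint8)
        canvas[pad : pad + h, pad : pad + w] = raster
        return canvas
    if op.kind == "rotate":
        (angle,) = op.params
        out = rotate(raster.astype(np.float64) / 255.0, angle, resize=False, mode="edge")
        return (np.clip(out, 0, 1) * 255).astype(np.uint8)
    raise ValidationError(f"unknown transform kind {op.kind!r}")


def apply_chain(
    raster: np.ndarray, chain: tuple[TransformOp, ...], rng: np.random.Generator
) -> np.ndarray:
    for op in chain:
        raster = apply_transform(raster, op, rng)
    return raster


#: Default per-copy edit chains, cycled through a reuse group. Copy 0 is the
#: untouched original; the rest stay inside the robustness envelope the
#: descriptors and matcher are designed for (scale 0.5-2.0, JPEG quality
#: >= 60, mild recolor/noise).
def default_chains(seed: int) -> list[tuple[TransformOp, ...]]:
    return [
        (),
        (TransformOp("rescale", (0.8,)), TransformOp("jpeg_recompress", (85,))),
        (TransformOp("hflip"), TransformOp("color_shift", (12, -8, 5))),
        (
            TransformOp("crop", (0.1, 0.1, 0.9, 0.9)),
            TransformOp("rescale", (1.25,)),
        ),
        (
            TransformOp("rotate", (5.0,)),
            TransformOp("gaussian_noise", (4.0, seed)),
        ),
        (TransformOp("splice_onto_background", (20,)), TransformOp("rescale", (0.9,))),
    ]


@dataclass(frozen=True)
class ReuseGroup:
    """A planted reuse category: `size` edited copies of one master panel,
    each placed in a distinct mill document."""

    label: str
    size: int
    panel_type: str = "microscopy"
    chains: tuple[tuple[TransformOp, ...], ...] | None = None  # per-copy; cycled


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_documents: int = 30
    n_mill_documents: int = 5
    figures_per_document: int = 1
    panels_per_figure: int = 4
    type_mix: tuple[tuple[str, float], ...] = tuple(DEFAULT_TYPE_MIX.items())
    reuse_groups: tuple[ReuseGroup, ...] = (
        ReuseGroup("G1", 3, "microscopy"),
        ReuseGroup("G2", 3, "flow_cytometry"),
        ReuseGroup("G3", 4, "body_imaging"),
    )
    panel_size: int = PANEL_SIZE
    as_pdf: bool = False

    def __post_init__(self) -> None:
        if self.n_mill_documents > self.n_documents:
            raise ValidationError("more mill documents than documents")
        for group in self.reuse_groups:
            if group.size > self.n_mill_documents:
                raise ValidationError(
                    f"group {group.label!r} needs {group.size} distinct mill "
                    f"documents but only {self.n_mill_documents} exist"
                )
            if group.panel_type not in PANEL_TYPES:
                raise ValidationError(f"unknown panel type {group.panel_type!r}")


def crop50_spec(seed: int = 0) -> FixtureSpec:
    """A corpus planting the canonical 50%-area crop reuse pair.

    The master panel is twice as wide as it is tall; the second copy is its
    left half, so the crop covers exactly 50% of the source's area. With
    matches spanning the whole crop, the directional content-sharing scores
    are 1.0 (crop w.r.t. source) and 0.5 (source w.r.t. crop).
    """
    return FixtureSpec(
        seed=seed,
        n_documents=4,
        n_mill_documents=2,
        reuse_groups=(
            ReuseGroup(
                "CROP50",
                2,
                "microscopy",
                chains=((), (TransformOp("crop", (0.0, 0.0, 0.5, 1.0)),)),
            ),
        ),
    )


# ---------------------------------------------------------------------------
# procedural panel synthesis
# ---------------------------------------------------------------------------

def _blob_field(h: int, w: int, rng: np.random.Generator, n_blobs: int) -> np.ndarray:
    img = rng.random((h, w)) * 0.15
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        x, y = rng.integers(0, w), rng.integers(0, h)
        r = rng.integers(2, max(3, min(h, w) // 18))
        img[(xx - x) ** 2 + (yy - y) ** 2 < r * r] = 0.3 + 0.7 * rng.random()
    return np.clip(img + rng.normal(0, 0.02, (h, w)), 0, 1)


def synth_panel(
    panel_type: str, rng: np.random.Generator, height: int = PANEL_SIZE, width: int | None = None
) -> np.ndarray:
    """Procedural RGB stand-in for one biomedical panel type.

    Microscopy and flow cytometry are keypoint-rich by construction; blots
    are intentionally low-entropy (few bands, blurred, undefined boundaries)
    because that is what makes real blots hard to match.
    """
    w = width or height
    h = height
    if panel_type == "microscopy":
        field = _blob_field(h, w, rng, n_blobs=int(2.4e-3 * h * w))
        tint = rng.dirichlet((2, 4, 2))  # fluorescence-like channel dominance
        img = np.stack([field * (0.4 + 0.6 * t) for t in tint], axis=-1)
        return (img * 255).astype(np.uint8)
    if panel_type == "blots":
        img = np.full((h, w), 0.86) + rng.normal(0, 0.015, (h, w))
        n_bands = rng.integers(2, 5)
        for _ in range(n_bands):
            cy = rng.integers(int(0.15 * h), int(0.85 * h))
            cx = rng.integers(int(0.2 * w), int(0.8 * w))
            bw, bh = rng.integers(w // 4, w // 2), rng.integers(h // 20, h // 10)
            yy, xx = np.mgrid[0:h, 0:w]
            band = ((xx - cx) / bw) ** 2 + ((yy - cy) / bh) ** 2 < 1
            img[band] -= 0.55 * rng.random() + 0.2
        img = ndimage.gaussian_filter(img, sigma=2.5)
        return (np.clip(img, 0, 1)[..., None] * np.array([255, 250, 245])).astype(np.uint8)
    if panel_type == "body_imaging":
        yy, xx = np.mgrid[0:h, 0:w]
        img = np.zeros((h, w))
        for _ in range(rng.integers(3, 6)):
            cx, cy = rng.integers(w // 4, 3 * w // 4), rng.integers(h // 4, 3 * h // 4)
            ax, ay = rng.integers(w // 6, w // 2), rng.integers(h // 6, h // 2)
            d = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
            img += np.exp(-2.5 * d) * (0.3 + 0.7 * rng.random())
        img = img / max(img.max(), 1e-9)
        # organ-like internal texture: blobs survive rescaling and
        # recompression, unlike per-pixel speckle
        texture = _blob_field(h, w, rng, n_blobs=int(3.0e-3 * h * w))
        img = np.clip(0.55 * img + 0.55 * texture, 0, 1)
        return (np.stack([img] * 3, axis=-1) * 255).astype(np.uint8)
    if panel_type == "flow_cytometry":
        img = np.full((h, w, 3), 255, dtype=np.uint8)
        img[h - 2 :, :] = 40  # axes
        img[:, :2] = 40
        n_pts = int(8.0e-3 * h * w)
        cx, cy = rng.uniform(0.3, 0.7, 2)
        xs = np.clip(rng.normal(cx * w, 0.12 * w, n_pts), 2, w - 4).astype(int)
        ys = np.clip(rng.normal(cy * h, 0.12 * h, n_pts), 2, h - 5).astype(int)
        colors = rng.integers(0, 140, (n_pts, 3))
        for x, y, c in zip(xs, ys, colors):
            img[y : y + 3, x : x + 3] = c  # 3-px events survive recompression
        return img
    if panel_type == "graphs_plots":
        img = np.full((h, w, 3), 255, dtype=np.uint8)
        img[h - 3 :, :] = 0
        img[:, :3] = 0
        n_bars = 5
        bw = (w - 10) // (n_bars + 1)
        for b in range(n_bars):
            bh = int(rng.uniform(0.2, 0.9) * (h - 10))
            x0 = 6 + b * (bw + 4)
            img[h - 3 - bh : h - 3, x0 : x0 + bw] = (70, 70, 180)
        return img
    if panel_type == "unknown":
        return (_blob_field(h, w, rng, 40)[..., None] * 255).astype(np.uint8).repeat(3, -1)
    raise ValidationError(f"unknown panel type {panel_type!r}")


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------

def _compose_figure(panels: list[np.ndarray]) -> tuple[np.ndarray, list[tuple[int, int, int, int]]]:
    """Lay panels out row-major on a white canvas; return canvas and bboxes."""
    rows = [panels[i : i + GRID_COLS] for i in range(0, len(panels), GRID_COLS)]
    row_heights = [max(p.shape[0] for p in row) for row in rows]
    col_widths = [0] * GRID_COLS
    for row in rows:
        for c, p in enumerate(row):
            col_widths[c] = max(col_widths[c], p.shape[1])
    width = 2 * MARGIN + sum(col_widths[: max(len(r) for r in rows)]) + GUTTER * (
        max(len(r) for r in rows) - 1
    )
    height = 2 * MARGIN + sum(row_heights) + GUTTER * (len(rows) - 1)
    canvas = np.full((height, width, 3), 255, dtype=np.uint8)
    bboxes = []
    y = MARGIN
    for row, rh in zip(rows, row_heights):
        x = MARGIN
        for c, p in enumerate(row):
            ph, pw = p.shape[:2]
            canvas[y : y + ph, x : x + pw] = p
            bboxes.append((x, y, x + pw, y + ph))
            x += col_widths[c] + GUTTER
        y += rh + GUTTER
    return canvas, bboxes


def _merge_doc_clusters(group_docs: dict[str, list[str]]) -> dict[str, list[str]]:
    """Merge image-level groups that share documents into doc-level categories."""
    import networkx as nx

    g = nx.Graph()
    for label, docs in group_docs.items():
        g.add_node(("g", label))
        for d in docs:
            g.add_edge(("g", label), ("d", d))
    clusters = {}
    for comp in nx.connected_components(g):
        labels = sorted(n[1] for n in comp if n[0] == "g")
        docs = sorted(n[1] for n in comp if n[0] == "d")
        clusters["+".join(labels)] = docs
    return clusters


def generate_corpus(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the corpus (PNG figures or PDFs) and truth.json; return the truth.

    Layout: ``out_dir/figures/<doc_id>/fig<k>.png`` (or
    ``out_dir/pdfs/<doc_id>.pdf``) plus ``out_dir/truth.json``.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    doc_ids = [f"doc{i:03d}" for i in range(spec.n_documents)]
    mill_docs = doc_ids[: spec.n_mill_documents]
    type_names = [t for t, _ in spec.type_mix]
    type_probs = np.array([p for _, p in spec.type_mix], dtype=float)
    type_probs /= type_probs.sum()

    # plant reuse copies: cycle through mill documents so every group's
    # copies land in distinct documents and the mill is fully covered
    planted: dict[str, list[tuple[str, int, np.ndarray, tuple[TransformOp, ...]]]] = {
        d: [] for d in doc_ids
    }
    group_members: dict[str, list[str]] = {}
    group_docs: dict[str, list[str]] = {}
    transforms_truth: dict[str, list[dict]] = {}
    slot_cursor = 0
    masters: dict[str, np.ndarray] = {}
    for group in spec.reuse_groups:
        if group.label == "CROP50" or (group.chains and any(
            op.kind == "crop" and op.params[2] - op.params[0] == 0.5
            for chain in group.chains
            for op in chain
        )):
            # 2:1 master so a half-width crop covers exactly 50% of the area
            master = synth_panel(group.panel_type, rng, spec.panel_size, 2 * spec.panel_size)
        else:
            master = synth_panel(group.panel_type, rng, spec.panel_size)
        masters[group.label] = master
        chains = group.chains or tuple(default_chains(spec.seed))
        docs = []
        for copy_idx in range(group.size):
            doc = mill_docs[slot_cursor % len(mill_docs)]
            while doc in docs:  # a group never reuses a document
                slot_cursor += 1
                doc = mill_docs[slot_cursor % len(mill_docs)]
            slot_cursor += 1
            chain = tuple(chains[copy_idx % len(chains)])
            raster = apply_chain(master, chain, rng)
            planted[doc].append((group.label, copy_idx, raster, chain))
            docs.append(doc)
        group_docs[group.label] = sorted(docs)
        group_members[group.label] = []  # panel ids filled during layout

    documents_json = []
    fig_dir = out_dir / ("pdfs" if spec.as_pdf else "figures")
    fig_dir.mkdir(parents=True, exist_ok=True)

    for doc_id in doc_ids:
        doc_planted = list(planted[doc_id])
        figures_json = []
        doc_figures: list[np.ndarray] = []
        for fig_idx in range(spec.figures_per_document):
            figure_id = f"{doc_id}/fig{fig_idx}"
            rasters, panel_meta = [], []
            for slot in range(spec.panels_per_figure):
                if doc_planted:
                    label, copy_idx, raster, chain = doc_planted.pop(0)
                    rasters.append(raster)
                    panel_meta.append(
                        {"type": labels_type(spec, label), "group": label, "chain": chain}
                    )
                else:
                    ptype = type_names[rng.choice(len(type_names), p=type_probs)]
                    rasters.append(synth_panel(ptype, rng, spec.panel_size))
                    panel_meta.append({"type": ptype, "group": None, "chain": None})
            canvas, bboxes = _compose_figure(rasters)
            # panel ids follow ingest's reading-order contract (by box center),
            # which differs from slot order when copies changed size
            order = sorted(
                range(len(bboxes)),
                key=lambda i: (
                    (bboxes[i][1] + bboxes[i][3]) / 2.0,
                    (bboxes[i][0] + bboxes[i][2]) / 2.0,
                    bboxes[i],
                ),
            )
            rank = {slot: k for k, slot in enumerate(order)}
            for slot, meta in enumerate(panel_meta):
                if meta["group"] is not None:
                    panel_id = f"{figure_id}/p{rank[slot]}"
                    group_members[meta["group"]].append(panel_id)
                    transforms_truth[panel_id] = [op.as_dict() for op in meta["chain"]]
            if spec.as_pdf:
                file_ref = f"{doc_id}.pdf#fig{fig_idx}"
                doc_figures.append(canvas)
            else:
                file_ref = f"{doc_id}/fig{fig_idx}.png"
                dest = fig_dir / doc_id
                dest.mkdir(exist_ok=True)
                Image.fromarray(canvas).save(dest / f"fig{fig_idx}.png")
            panels_json = [
                {
                    "bbox": list(bbox),
                    "type": meta["type"],
                    **({"group": meta["group"]} if meta["group"] else {}),
                }
                for bbox, meta in zip(bboxes, panel_meta)
            ]
            figures_json.append(
                {"figure_id": figure_id, "file": file_ref, "panels": panels_json}
            )
        if doc_planted:
            raise ValidationError(
                f"document {doc_id} has more planted reuse copies than panel slots; "
                "increase figures_per_document or panels_per_figure"
            )
        if spec.as_pdf:
            minipdf.write_pdf(fig_dir / f"{doc_id}.pdf", doc_figures)
        documents_json.append({"doc_id": doc_id, "figures": figures_json})

    group_members = {k: sorted(v) for k, v in group_members.items()}
    doc_categories = _merge_doc_clusters(group_docs)
    image_links = sorted(
        sorted([a, b])
        for members in group_members.values()
        for i, a in enumerate(members)
        for b in members[i + 1 :]
    )
    doc_links = sorted(
        sorted([a, b])
        for docs in doc_categories.values()
        for i, a in enumerate(docs)
        for b in docs[i + 1 :]
    )
    truth = {
        "documents": documents_json,
        "groups": {
            label: {
                "panel_type": next(
                    g.panel_type for g in spec.reuse_groups if g.label == label
                ),
                "members": members,
                "documents": group_docs[label],
            }
            for label, members in group_members.items()
        },
        "document_categories": doc_categories,
        "links": {"image": image_links, "document": doc_links},
        "suspicious": {
            "image": sorted(set().union(*group_members.values())) if group_members else [],
            "document": sorted(set().union(*group_docs.values())) if group_docs else [],
        },
        "transforms": transforms_truth,
        "spec": {
            "seed": spec.seed,
            "n_documents": spec.n_documents,
            "n_mill_documents": spec.n_mill_documents,
            "figures_per_document": spec.figures_per_document,
            "panels_per_figure": spec.panels_per_figure,
        },
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth


def labels_type(spec: FixtureSpec, label: str) -> str:
    return next(g.panel_type for g in spec.reuse_groups if g.label == label)


# ---------------------------------------------------------------------------
# ground-truth views for the evaluation module
# ---------------------------------------------------------------------------

def truth_image_level(truth: dict) -> GroundTruth:
    """Panel-level ground truth; corpus ids are all annotated panel ids."""
    corpus = {
        f"{fig['figure_id']}/p{k}"
        for doc in truth["documents"]
        for fig in doc["figures"]
        for k in range(len(fig["panels"]))
    }
    categories = {label: set(g["members"]) for label, g in truth["groups"].items()}
    return GroundTruth(categories, corpus)


def truth_document_level(truth: dict) -> GroundTruth:
    """Document-level ground truth with mill clusters as categories."""
    corpus = {doc["doc_id"] for doc in truth["documents"]}
    categories = {label: set(docs) for label, docs in truth["document_categories"].items()}
    return GroundTruth(categories, corpus)
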