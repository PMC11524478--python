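"""Figure and panel ingestion.

Turns a collection of article PDFs (or pre-extracted figure rasters) into
typed, cropped panels ready for evidence description. A compound biomedical
figure usually contains several independent panels (micrographs, blots, body
imaging, flow-cytometry plots, graphs); downstream provenance analysis
operates on panels, never whole figures, so that legend letters, diagrams and
analytically generated plots do not create false links.

Coordinates are 0-based with the origin at the top-left; bounding boxes are
half-open, ``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from PIL import Image

from . import minipdf
from .errors import ConfigurationError, IngestError, ValidationError

PANEL_TYPES = frozenset(
    {"microscopy", "blots", "body_imaging", "graphs_plots", "flow_cytometry", "unknown"}
)
#: graphs_plots is excluded by default: analytically generated charts look
#: alike across unrelated papers and flood the analysis with false links.
DEFAULT_ALLOWED_TYPES = frozenset(
    {"microscopy", "blots", "body_imaging", "flow_cytometry"}
)
DEFAULT_MIN_FIGURE_SIZE = 64  # px, smaller embedded rasters are logos/icons
DEFAULT_MIN_PANEL_SIZE = 64  # px on each side
DUPLICATE_IOU = 0.8

_RASTER_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclass(frozen=True)
class SourceDocument:
    """One article: a PDF file or a directory of figure rasters."""

    doc_id: str
    path: Path
    n_figures: int = 0


@dataclass
class FigureImage:
    """A compound figure raster extracted from a document."""

    figure_id: str
    doc_id: str
    raster: np.ndarray  # H x W x 3 uint8

    @property
    def height(self) -> int:
        return self.raster.shape[0]

    @property
    def width(self) -> int:
        return self.raster.shape[1]


@dataclass(frozen=True)
class PanelBox:
    bbox: tuple[int, int, int, int]  # x_min, y_min, x_max, y_max (half-open)
    panel_type: str = "unknown"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1) or x0 < 0 or y0 < 0:
            raise ValidationError(f"degenerate panel box {self.bbox}")
        if self.panel_type not in PANEL_TYPES:
            raise ValidationError(f"unknown panel type {self.panel_type!r}")

    @property
    def width(self) -> int:
        return self.bbox[2] - self.bbox[0]

    @property
    def height(self) -> int:
        return self.bbox[3] - self.bbox[1]

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass
class Panel:
    """A typed sub-image of a figure with provenance back-pointers."""

    panel_id: str
    doc_id: str
    figure_id: str
    box: PanelBox
    raster: np.ndarray

    @property
    def panel_type(self) -> str:
        return self.box.panel_type

    @property
    def width(self) -> int:
        return self.raster.shape[1]

    @property
    def height(self) -> int:
        return self.raster.shape[0]

    @property
    def area(self) -> float:
        return float(self.width * self.height)


def box_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    """Intersection over union of two half-open boxes."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0, ix1 - ix0) * max(0, iy1 - iy0)
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / float(area_a + area_b - inter)


def _load_raster(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def extract_figures(
    doc: SourceDocument | str | Path,
    doc_id: str | None = None,
    min_size: int = DEFAULT_MIN_FIGURE_SIZE,
) -> list[FigureImage]:
    """Extract figure rasters from a PDF or a directory of image files.

    PDF mode walks the embedded-raster object stream (page-then-stream
    order); directory mode reads raster files sorted by filename. Rasters
    whose smaller side is below ``min_size`` are dropped as icons/logos.
    Zero figures is a valid outcome, not an error.
    """
    if isinstance(doc, SourceDocument):
        path, doc_id = Path(doc.path), doc.doc_id
    else:
        path = Path(doc)
        doc_id = doc_id or path.stem

    if path.is_dir():
        rasters = [
            _load_raster(p)
            for p in sorted(path.iterdir())
            if p.suffix.lower() in _RASTER_SUFFIXES
        ]
    elif path.is_file():
        rasters = minipdf.extract_images(path)
    else:
        raise IngestError(f"no such document: {path}")

    figures = []
    for raster in rasters:
        if min(raster.shape[0], raster.shape[1]) < min_size:
            continue
        figures.append(
            FigureImage(f"{doc_id}/fig{len(figures)}", doc_id, raster)
        )
    return figures


# ---------------------------------------------------------------------------
# panel detection backends
# ---------------------------------------------------------------------------

def _clip_box(box: PanelBox, width: int, height: int) -> PanelBox | None:
    x0, y0, x1, y1 = box.bbox
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(width, x1), min(height, y1)
    if x0 >= x1 or y0 >= y1:
        return None
    return PanelBox((x0, y0, x1, y1), box.panel_type, box.confidence)


def _collapse_duplicates(boxes: list[PanelBox], iou: float = DUPLICATE_IOU) -> list[PanelBox]:
    kept: list[PanelBox] = []
    for box in sorted(boxes, key=lambda b: (-b.confidence, b.bbox)):
        if all(box_iou(box.bbox, k.bbox) <= iou for k in kept):
            kept.append(box)
    # restore reading order for stable downstream numbering
    kept.sort(key=lambda b: (b.center[1], b.center[0], b.bbox))
    return kept


def _gutter_runs(is_gutter: np.ndarray, min_gutter: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_gutter, excluding the borders."""
    runs, start = [], None
    for i, g in enumerate(is_gutter):
        if g and start is None:
            start = i
        elif not g and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(is_gutter)))
    return [
        (a, b)
        for a, b in runs
        if b - a >= min_gutter and a > 0 and b < len(is_gutter)
    ]


def _content_bbox(gray: np.ndarray, white: int) -> tuple[int, int, int, int] | None:
    mask = gray < white
    if not mask.any():
        return None
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def _split_recursive(
    gray: np.ndarray,
    x0: int,
    y0: int,
    x1: int,
    y1: int,
    min_gutter: int,
    white: int,
    out: list[tuple[int, int, int, int]],
) -> None:
    region = gray[y0:y1, x0:x1]
    sub = _content_bbox(region, white)
    if sub is None:
        return
    x0, y0, x1, y1 = x0 + sub[0], y0 + sub[1], x0 + sub[2], y0 + sub[3]
    region = gray[y0:y1, x0:x1]

    row_runs = _gutter_runs(region.min(axis=1) >= white, min_gutter)
    col_runs = _gutter_runs(region.min(axis=0) >= white, min_gutter)
    # split along the axis with the widest gutter first
    widest_row = max((b - a for a, b in row_runs), default=0)
    widest_col = max((b - a for a, b in col_runs), default=0)
    if widest_row == 0 and widest_col == 0:
        out.append((x0, y0, x1, y1))
        return
    if widest_row >= widest_col:
        cuts, horizontal = row_runs, True
    else:
        cuts, horizontal = col_runs, False
    prev = 0
    length = (y1 - y0) if horizontal else (x1 - x0)
    for a, b in cuts + [(length, length)]:
        if a > prev:
            if horizontal:
                _split_recursive(gray, x0, y0 + prev, x1, y0 + a, min_gutter, white, out)
            else:
                _split_recursive(gray, x0 + prev, y0, x0 + a, y1, min_gutter, white, out)
        prev = b


def heuristic_panel_boxes(
    figure: FigureImage, min_gutter: int = 10, white_threshold: int = 240
) -> list[PanelBox]:
    """Recursive whitespace-gutter splitting; panels come back untyped.

    A row/column is a gutter when every pixel in it is near-white. The figure
    is split along the widest gutter, recursively on alternating axes, and
    each leaf is tightened to its non-white content bounding box. A figure
    with no gutters yields a single box covering its content.
    """
    gray = np.asarray(
        np.round(figure.raster.astype(np.float64) @ [0.299, 0.587, 0.114]), np.uint8
    )
    leaves: list[tuple[int, int, int, int]] = []
    _split_recursive(gray, 0, 0, figure.width, figure.height, min_gutter, white_threshold, leaves)
    if not leaves:
        leaves = [(0, 0, figure.width, figure.height)]
    return [PanelBox(b, "unknown", 1.0) for b in leaves]


def detect_panels(
    figure: FigureImage,
    backend: str = "heuristic",
    annotations: Sequence[dict] | None = None,
    model: Callable[[np.ndarray], list[PanelBox]] | None = None,
    min_gutter: int = 10,
    white_threshold: int = 240,
) -> list[PanelBox]:
    """Locate panels in a compound figure.

    Backends: ``annotation`` passes through curated boxes (the JSON schema of
    :func:`read_annotations`), ``heuristic`` splits on whitespace gutters,
    ``model`` delegates to a supplied learned detector callable.
    """
    if backend == "annotation":
        boxes = [
            PanelBox(tuple(p["bbox"]), p.get("type", "unknown"), p.get("confidence", 1.0))
            for p in (annotations or [])
        ]
    elif backend == "heuristic":
        boxes = heuristic_panel_boxes(figure, min_gutter, white_threshold)
    elif backend == "model":
        if model is None:
            raise ConfigurationError(
                "model backend requested but no detector model configured"
            )
        boxes = list(model(figure.raster))
    else:
        raise ConfigurationError(f"unknown detector backend {backend!r}")

    clipped = [
        c for b in boxes if (c := _clip_box(b, figure.width, figure.height)) is not None
    ]
    return _collapse_duplicates(clipped)


def crop_and_filter(
    figure: FigureImage,
    boxes: Iterable[PanelBox],
    allowed_types: frozenset[str] | set[str] = DEFAULT_ALLOWED_TYPES,
    min_panel_size: int = DEFAULT_MIN_PANEL_SIZE,
) -> list[Panel]:
    """Crop boxes out of the figure and keep only informative panel types.

    Panel ids are assigned in reading order (top-left to bottom-right by box
    center) over *all* detected boxes before filtering, so ids are a pure
    function of (figure_id, boxes) and do not shift when the allowed-type
    set changes.
    """
    ordered = sorted(boxes, key=lambda b: (b.center[1], b.center[0], b.bbox))
    panels = []
    for k, box in enumerate(ordered):
        if box.panel_type not in allowed_types:
            continue
        if box.width < min_panel_size or box.height < min_panel_size:
            continue
        x0, y0, x1, y1 = box.bbox
        panels.append(
            Panel(
                panel_id=f"{figure.figure_id}/p{k}",
                doc_id=figure.doc_id,
                figure_id=figure.figure_id,
                box=box,
                raster=figure.raster[y0:y1, x0:x1].copy(),
            )
        )
    return panels


# ---------------------------------------------------------------------------
# annotation JSON (one record per document)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, dict]:
    """Read panel annotations keyed by figure file name.

    Schema (per document)::

        {"doc_id": ..., "figures": [{"figure_id": ..., "file": ...,
            "panels": [{"bbox": [x0, y0, x1, y1], "type": ..., "group": ...}]}]}

    The top level may be a single document object or a list of them. Returns
    ``{figure file: {"doc_id", "figure_id", "panels"}}``.
    """
    data = json.loads(Path(path).read_text())
    docs = data if isinstance(data, list) else data.get("documents", [data])
    table: dict[str, dict] = {}
    for doc in docs:
        for fig in doc.get("figures", []):
            table[fig["file"]] = {
                "doc_id": doc["doc_id"],
                "figure_id": fig["figure_id"],
                "panels": fig.get("panels", []),
            }
    return table


def ingest_corpus(
    figure_dir: str | Path | None = None,
    pdf_dir: str | Path | None = None,
    annotations: str | Path | None = None,
    backend: str = "heuristic",
    allowed_types: frozenset[str] | set[str] = DEFAULT_ALLOWED_TYPES,
    min_panel_size: int = DEFAULT_MIN_PANEL_SIZE,
) -> list[Panel]:
    """End-to-end ingest of a corpus directory into panels.

    ``figure_dir`` holds one sub-directory of rasters per document;
    ``pdf_dir`` holds one PDF per document. With the annotation backend the
    annotation file supplies boxes and types per figure file.
    """
    if backend == "annotation" and annotations is None:
        raise ConfigurationError("annotation backend requires an annotation file")
    ann = read_annotations(annotations) if annotations else {}
    panels: list[Panel] = []

    def _do_figure(figure: FigureImage, file_name: str) -> None:
        rec = ann.get(file_name)
        if backend == "annotation":
            if rec is None:
                return
            figure.figure_id = rec["figure_id"]
            figure.doc_id = rec["doc_id"]
            boxes = detect_panels(figure, "annotation", annotations=rec["panels"])
        else:
            boxes = detect_panels(figure, backend)
        panels.extend(crop_and_filter(figure, boxes, allowed_types, min_panel_size))

    if figure_dir is not None:
        root = Path(figure_dir)
        for doc_dir in sorted(p for p in root.iterdir() if p.is_dir()):
            files = sorted(
                p for p in doc_dir.iterdir() if p.suffix.lower() in _RASTER_SUFFIXES
            )
            for k, file in enumerate(files):
                figure = FigureImage(
                    f"{doc_dir.name}/fig{k}", doc_dir.name, _load_raster(file)
                )
                _do_figure(figure, f"{doc_dir.name}/{file.name}")
    if pdf_dir is not None:
        for pdf in sorted(Path(pdf_dir).glob("*.pdf")):
            for fig in extract_figures(pdf):
                k = fig.figure_id.rsplit("fig", 1)[1]
                _do_figure(fig, f"{pdf.name}#fig{k}")
    return panels
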