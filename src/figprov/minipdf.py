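"""Minimal PDF embedded-raster writer and reader.

Scientific articles ship figures as image XObjects inside their PDFs. For
provenance analysis we only need those embedded rasters back, not a rendered
page, so this module walks the object stream directly instead of laying out
pages. It understands the two encodings that cover the vast majority of
figure rasters: FlateDecode (zlib) arrays in DeviceRGB/DeviceGray and
DCTDecode (baseline JPEG) streams. Anything else is skipped.

The writer emits one figure per page, Flate-encoded 8-bit RGB, and exists so
synthetic corpora can exercise the full PDF ingest path without any external
document.
"""

from __future__ import annotations

import io
import re
import zlib
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import IngestError

_OBJ_RE = re.compile(rb"\d+\s+\d+\s+obj\s*(<<.*?>>)\s*stream\r?\n", re.S)
_INT_RE = {
    "width": re.compile(rb"/Width\s+(\d+)"),
    "height": re.compile(rb"/Height\s+(\d+)"),
    "bpc": re.compile(rb"/BitsPerComponent\s+(\d+)"),
}


def write_pdf(path: str | Path, images: list[np.ndarray]) -> None:
    """Write ``images`` (H x W x 3 uint8 arrays) as a one-image-per-page PDF."""
    objs: list[bytes] = []  # bodies, 1-indexed object numbers
    n_pages = len(images)
    page_ids = [4 + 3 * i for i in range(n_pages)]
    kids = b" ".join(b"%d 0 R" % pid for pid in page_ids)
    objs.append(b"<< /Type /Catalog /Pages 2 0 R >>")
    objs.append(b"<< /Type /Pages /Count %d /Kids [%s] >>" % (n_pages, kids))
    objs.append(b"<< /Producer (figprov minipdf) >>")
    for i, img in enumerate(images):
        img = np.ascontiguousarray(img, dtype=np.uint8)
        h, w = img.shape[:2]
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        data = zlib.compress(img.tobytes())
        pid, xid, cid = 4 + 3 * i, 5 + 3 * i, 6 + 3 * i
        content = b"q %d 0 0 %d 0 0 cm /Im%d Do Q" % (w, h, i)
        objs.append(
            b"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 %d %d] "
            b"/Resources << /XObject << /Im%d %d 0 R >> >> /Contents %d 0 R >>"
            % (w, h, i, xid, cid)
        )
        objs.append(
            b"<< /Type /XObject /Subtype /Image /Width %d /Height %d "
            b"/ColorSpace /DeviceRGB /BitsPerComponent 8 /Filter /FlateDecode "
            b"/Length %d >>\nstream\n" % (w, h, len(data))
            + data
            + b"\nendstream"
        )
        objs.append(
            b"<< /Length %d >>\nstream\n%s\nendstream" % (len(content), content)
        )

    out = io.BytesIO()
    out.write(b"%PDF-1.4\n")
    offsets = []
    for num, body in enumerate(objs, start=1):
        offsets.append(out.tell())
        out.write(b"%d 0 obj\n" % num + body + b"\nendobj\n")
    xref_at = out.tell()
    out.write(b"xref\n0 %d\n0000000000 65535 f \n" % (len(objs) + 1))
    for off in offsets:
        out.write(b"%010d 00000 n \n" % off)
    out.write(
        b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n"
        % (len(objs) + 1, xref_at)
    )
    Path(path).write_bytes(out.getvalue())


def _decode_image(header: bytes, stream: bytes) -> np.ndarray | None:
    vals = {}
    for key, rx in _INT_RE.items():
        m = rx.search(header)
        vals[key] = int(m.group(1)) if m else None
    w, h = vals["width"], vals["height"]
    if not w or not h:
        return None
    if b"/DCTDecode" in header:
        arr = np.asarray(Image.open(io.BytesIO(stream)).convert("RGB"))
        return arr
    if b"/FlateDecode" in header:
        if vals["bpc"] not in (8, None):
            return None
        try:
            raw = zlib.decompressobj().decompress(stream)
        except zlib.error:
            return None
        if b"/DeviceGray" in header and len(raw) >= w * h:
            gray = np.frombuffer(raw[: w * h], np.uint8).reshape(h, w)
            return np.stack([gray] * 3, axis=-1)
        if len(raw) >= w * h * 3:
            return np.frombuffer(raw[: w * h * 3], np.uint8).reshape(h, w, 3)
    return None


def extract_images(path: str | Path) -> list[np.ndarray]:
    """Return every decodable embedded raster, in object-stream order.

    Object-stream order coincides with page order for linearly written PDFs
    (including everything :func:`write_pdf` emits), which gives ingest the
    deterministic page-then-stream ordering it promises.
    """
    path = Path(path)
    try:
        data = path.read_bytes()
    except OSError as exc:
        raise IngestError(f"cannot read PDF {path}: {exc}") from exc
    if not data.startswith(b"%PDF"):
        raise IngestError(f"{path} is not a PDF (missing %PDF header)")
    if re.search(rb"/Encrypt\s+\d+\s+\d+\s+R", data):
        raise IngestError(f"{path} is encrypted; decrypt before ingest")

    images: list[np.ndarray] = []
    for m in _OBJ_RE.finditer(data):
        header = m.group(1)
        if b"/Subtype" not in header or b"/Image" not in header:
            continue
        end = data.find(b"endstream", m.end())
        if end < 0:
            continue
        stream = data[m.end() : end].rstrip(b"\r\n")
        img = _decode_image(header, stream)
        if img is not None:
            images.append(img)
    return images
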