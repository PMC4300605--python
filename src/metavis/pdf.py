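"""SVG to single-page PDF conversion for the renderer's own SVG subset.

This is a small, self-contained vector converter: it understands exactly
the elements :func:`metavis.render.render_svg` emits — ``rect``,
``circle``, ``line``, ``polygon``, ``text`` and ``g`` groups with
inheritable stroke attributes — and draws them into an uncompressed
one-page PDF (Helvetica for text, y-axis flipped from the SVG's y-down
convention).  Anything else in the input is ignored; input that is not
well-formed XML or has no ``<svg>`` root raises :class:`PdfConversionError`.
"""

from __future__ import annotations

import math
import re

from lxml import etree


class PdfConversionError(ValueError):
    pass


_KAPPA = 0.5522847498  # cubic-Bezier circle constant


def _color(value: str | None) -> tuple[float, float, float] | None:
    if not value or value == "none":
        return None
    value = value.strip()
    match = re.fullmatch(r"#([0-9a-fA-F]{6})", value)
    if match:
        raw = match.group(1)
        return tuple(int(raw[i:i + 2], 16) / 255.0 for i in (0, 2, 4))
    named = {"black": (0, 0, 0), "white": (1.0, 1.0, 1.0),
             "red": (1.0, 0, 0), "green": (0, 0.5, 0), "blue": (0, 0, 1.0)}
    if value in named:
        return named[value]
    return (0.0, 0.0, 0.0)


def _escape_pdf(text: str) -> str:
    return text.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")


class _Page:
    def __init__(self, min_x: float, min_y: float,
                 width: float, height: float):
        self.min_x, self.min_y = min_x, min_y
        self.width, self.height = width, height
        self.ops: list[str] = []

    def pt(self, x: float, y: float) -> tuple[float, float]:
        return x - self.min_x, self.height - (y - self.min_y)

    def set_colors(self, fill, stroke, stroke_width) -> tuple[bool, bool]:
        if fill is not None:
            self.ops.append("%.4f %.4f %.4f rg" % fill)
        if stroke is not None:
            self.ops.append("%.4f %.4f %.4f RG" % stroke)
            self.ops.append("%.3f w" % max(float(stroke_width or 1.0), 0.01))
        return fill is not None, stroke is not None

    def paint(self, has_fill: bool, has_stroke: bool) -> None:
        if has_fill and has_stroke:
            self.ops.append("B")
        elif has_fill:
            self.ops.append("f")
        elif has_stroke:
            self.ops.append("S")
        else:
            self.ops.append("n")


def _walk(el, page: _Page, inherited: dict[str, str]) -> None:
    tag = el.tag.rsplit("}", 1)[-1] if isinstance(el.tag, str) else ""
    attrs = dict(inherited)
    attrs.update(el.attrib)

    fill = _color(attrs.get("fill", "#000000" if tag == "text" else None))
    stroke = _color(attrs.get("stroke"))
    sw = attrs.get("stroke-width")

    if tag == "rect":
        x, y = float(attrs["x"]), float(attrs["y"])
        w, h = float(attrs["width"]), float(attrs["height"])
        px, py = page.pt(x, y + h)
        hf, hs = page.set_colors(fill, stroke, sw)
        page.ops.append(f"{px:.2f} {py:.2f} {w:.2f} {h:.2f} re")
        page.paint(hf, hs)
    elif tag == "circle":
        cx, cy, r = (float(attrs["cx"]), float(attrs["cy"]),
                     float(attrs["r"]))
        px, py = page.pt(cx, cy)
        k = _KAPPA * r
        hf, hs = page.set_colors(fill, stroke, sw)
        page.ops.append(f"{px + r:.2f} {py:.2f} m")
        for (x1, y1, x2, y2, x3, y3) in (
                (px + r, py + k, px + k, py + r, px, py + r),
                (px - k, py + r, px - r, py + k, px - r, py),
                (px - r, py - k, px - k, py - r, px, py - r),
                (px + k, py - r, px + r, py - k, px + r, py)):
            page.ops.append(
                f"{x1:.2f} {y1:.2f} {x2:.2f} {y2:.2f} {x3:.2f} {y3:.2f} c")
        page.paint(hf, hs)
    elif tag == "line":
        p1 = page.pt(float(attrs["x1"]), float(attrs["y1"]))
        p2 = page.pt(float(attrs["x2"]), float(attrs["y2"]))
        _, hs = page.set_colors(None, stroke or (0, 0, 0), sw)
        page.ops.append(f"{p1[0]:.2f} {p1[1]:.2f} m {p2[0]:.2f} {p2[1]:.2f} l")
        page.paint(False, True)
    elif tag == "polygon":
        points = [float(v) for v in
                  re.split(r"[\s,]+", attrs.get("points", "").strip()) if v]
        if len(points) >= 6:
            coords = [page.pt(points[i], points[i + 1])
                      for i in range(0, len(points) - 1, 2)]
            hf, hs = page.set_colors(fill, stroke, sw)
            page.ops.append(f"{coords[0][0]:.2f} {coords[0][1]:.2f} m")
            for x, y in coords[1:]:
                page.ops.append(f"{x:.2f} {y:.2f} l")
            page.ops.append("h")
            page.paint(hf, hs)
    elif tag == "text":
        size = float(attrs.get("font-size", 11))
        x, y = float(attrs.get("x", 0)), float(attrs.get("y", 0))
        text = "".join(el.itertext())
        if attrs.get("text-anchor") == "middle":
            x -= 0.25 * size * len(text)  # Helvetica average advance
        px, py = page.pt(x, y)
        if fill is not None:
            page.ops.append("%.4f %.4f %.4f rg" % fill)
        page.ops.append(
            f"BT /F1 {size:.1f} Tf {px:.2f} {py:.2f} Td "
            f"({_escape_pdf(text)}) Tj ET")

    for child in el:
        _walk(child, page, {k: v for k, v in attrs.items()
                            if k in ("stroke", "stroke-width", "fill",
                                     "font-family", "font-size")})


def svg_to_pdf(svg_text: str | bytes) -> bytes:
    """Convert a rendered SVG document to single-page PDF bytes."""
    if isinstance(svg_text, str):
        svg_text = svg_text.encode("utf-8")
    try:
        root = etree.fromstring(svg_text)
    except etree.XMLSyntaxError as exc:
        raise PdfConversionError(f"not well-formed SVG: {exc}") from exc
    if root.tag.rsplit("}", 1)[-1] != "svg":
        raise PdfConversionError("root element is not <svg>")

    viewbox = root.get("viewBox")
    if viewbox:
        min_x, min_y, width, height = (float(v) for v in viewbox.split())
    else:
        min_x = min_y = 0.0
        width = float(root.get("width", 100))
        height = float(root.get("height", 100))
    if width <= 0 or height <= 0:
        raise PdfConversionError("empty drawing area")

    page = _Page(min_x, min_y, width, height)
    for child in root:
        _walk(child, page, {})
    content = ("\n".join(page.ops) + "\n").encode("latin-1", "replace")

    objects: list[bytes] = [
        b"<< /Type /Catalog /Pages 2 0 R >>",
        f"<< /Type /Pages /Kids [3 0 R] /Count 1 >>".encode(),
        (f"<< /Type /Page /Parent 2 0 R "
         f"/MediaBox [0 0 {width:.2f} {height:.2f}] "
         f"/Resources << /Font << /F1 5 0 R >> >> "
         f"/Contents 4 0 R >>").encode(),
        (f"<< /Length {len(content)} >>\nstream\n".encode()
         + content + b"endstream"),
        b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>",
    ]

    out = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for i, obj in enumerate(objects, start=1):
        offsets.append(len(out))
        out += f"{i} 0 obj\n".encode() + obj + b"\nendobj\n"
    xref_at = len(out)
    out += f"xref\n0 {len(objects) + 1}\n".encode()
    out += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        out += f"{off:010d} 00000 n \n".encode()
    out += (f"trailer\n<< /Size {len(objects) + 1} /Root 1 0 R >>\n"
            f"startxref\n{xref_at}\n%%EOF\n").encode()
    return bytes(out)
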