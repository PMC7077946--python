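"""Semi-transparent template overlays on smile photographs.

Vector-first rendering: the template is drawn as SVG (1 mm = 1 user unit
when no transform is given, so a bare template export is true to scale),
or mapped through a :class:`~smilecurves.registration.SimilarityTransform`
into a photograph's pixel grid.  Raster output composites the line work
directly onto the photo with Pillow at the photo's own resolution, so
the photograph is never resampled.

The rectangular boxes and reference lines carry the metric meaning; the
rounded crown silhouettes drawn in the SVG are cosmetic only (fixed
quadratic-Bezier rounding of the box corners).
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from PIL import Image, ImageDraw

from .registration import SimilarityTransform
from .template import TemplateGeometry, TOOTH_IDS, CONNECTOR_PAIRS

__all__ = ["OverlayStyle", "OverlayRender", "render_svg", "render_overlay"]

Point = Tuple[float, float]

_IDENTITY = SimilarityTransform(scale=1.0, rotation=0.0, translation=(0.0, 0.0))

_DEFAULT_LINE_COLORS = {
    "cervical": "#d62728",
    "papillary": "#2ca02c",
    "contact": "#1f77b4",
    "incisal": "#ff7f0e",
}


@dataclass(frozen=True)
class OverlayStyle:
    """Colours, stroke weights and opacity of the rendered template."""

    box_color: str = "#ffffff"
    line_colors: Dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_LINE_COLORS)
    )
    connector_color: str = "#9467bd"
    stroke_mm: float = 0.15
    opacity: float = 0.6
    rounded_crowns: bool = True

    def __post_init__(self):
        if not (0.0 < self.opacity <= 1.0):
            raise ValueError("opacity must lie in (0, 1]")
        if self.stroke_mm <= 0:
            raise ValueError("stroke_mm must be positive")


@dataclass
class OverlayRender:
    """A registered, styled rendering of one template."""

    transform: SimilarityTransform
    style: OverlayStyle
    svg: Optional[str] = None
    image: Optional[Image.Image] = None
    warnings: List[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".svg":
            if self.svg is None:
                raise ValueError("no SVG content in this render")
            path.write_text(self.svg)
        else:
            if self.image is None:
                raise ValueError("no raster content in this render")
            self.image.save(path)


# ---------------------------------------------------------------------------
# geometry -> drawable primitives


def _template_elements(geom: TemplateGeometry):
    """Boxes (closed polygons), connector segments and reference polylines
    in template mm coordinates."""
    boxes = {}
    for tid in TOOTH_IDS:
        b = geom.boxes[tid]
        boxes[tid] = [
            (b.x_left, b.y_zenith),
            (b.x_right, b.y_zenith),
            (b.x_right, b.y_incisal),
            (b.x_left, b.y_incisal),
        ]
    connectors = {
        pair: [
            (geom.connectors[pair].x, geom.connectors[pair].y_papilla_tip),
            (geom.connectors[pair].x, geom.connectors[pair].y_contact_point),
        ]
        for pair in CONNECTOR_PAIRS
    }
    return boxes, connectors, geom.lines


def _bbox(points: Sequence[Point]) -> Tuple[float, float, float, float]:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return min(xs), min(ys), max(xs), max(ys)


def _fmt(v: float) -> str:
    return format(v, ".6f").rstrip("0").rstrip(".")


def _points_attr(pts: Sequence[Point]) -> str:
    return " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)


def _crown_path(box_pts: List[Point]) -> str:
    """Cosmetic rounded crown silhouette (quadratic-Bezier corners)."""
    (x0, yz), (x1, _), (_, yi), _ = box_pts
    w = x1 - x0
    h = yi - yz
    rg = 0.30 * w  # gingival rounding
    ri = 0.12 * min(w, abs(h) if h else w)  # incisal rounding
    return (
        f"M {_fmt(x0)} {_fmt(yi - ri)} "
        f"L {_fmt(x0)} {_fmt(yz + rg)} "
        f"Q {_fmt(x0)} {_fmt(yz)} {_fmt(x0 + rg)} {_fmt(yz)} "
        f"L {_fmt(x1 - rg)} {_fmt(yz)} "
        f"Q {_fmt(x1)} {_fmt(yz)} {_fmt(x1)} {_fmt(yz + rg)} "
        f"L {_fmt(x1)} {_fmt(yi - ri)} "
        f"Q {_fmt(x1)} {_fmt(yi)} {_fmt(x1 - ri)} {_fmt(yi)} "
        f"L {_fmt(x0 + ri)} {_fmt(yi)} "
        f"Q {_fmt(x0)} {_fmt(yi)} {_fmt(x0)} {_fmt(yi - ri)} Z"
    )


# ---------------------------------------------------------------------------
# SVG rendering


def render_svg(
    geom: TemplateGeometry,
    transform: Optional[SimilarityTransform] = None,
    image_path: Optional[str | Path] = None,
    canvas_size: Optional[Tuple[int, int]] = None,
    style: OverlayStyle = OverlayStyle(),
) -> str:
    """Render the template as an SVG document.

    Without a transform the document is in template millimetres
    (1 mm = 1 user unit) with the canvas fit to the geometry.  With a
    transform, coordinates are mapped into pixel space; ``image_path``
    adds the photograph as a linked ``<image>`` background and
    ``canvas_size`` fixes the canvas (defaults to the image size, or the
    transformed template bounding box).
    """
    transform = transform or _IDENTITY
    boxes, connectors, lines = _template_elements(geom)

    def tp(pts: Sequence[Point]) -> List[Point]:
        return [tuple(q) for q in transform.apply(pts)]

    all_pts: List[Point] = []
    boxes_t = {tid: tp(pts) for tid, pts in boxes.items()}
    conns_t = {pair: tp(pts) for pair, pts in connectors.items()}
    lines_t = {name: tp(pts) for name, pts in lines.items()}
    for group in (*boxes_t.values(), *conns_t.values(), *lines_t.values()):
        all_pts.extend(group)
    x0, y0, x1, y1 = _bbox(all_pts)

    if canvas_size is not None:
        width, height = canvas_size
        min_x = min_y = 0.0
    elif image_path is not None:
        with Image.open(image_path) as im:
            width, height = im.size
        min_x = min_y = 0.0
    else:
        margin = 0.05 * max(x1 - x0, y1 - y0)
        min_x, min_y = x0 - margin, y0 - margin
        width, height = (x1 - x0) + 2 * margin, (y1 - y0) + 2 * margin

    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=_fmt(width),
        height=_fmt(height),
        viewBox=f"{_fmt(min_x)} {_fmt(min_y)} {_fmt(width)} {_fmt(height)}",
    )
    if image_path is not None:
        ET.SubElement(
            svg,
            "image",
            href=str(image_path),
            x="0",
            y="0",
            width=_fmt(width),
            height=_fmt(height),
        )

    stroke = style.stroke_mm * transform.scale
    group = ET.SubElement(
        svg,
        "g",
        id="smilecurves-template",
        fill="none",
        attrib={"stroke-width": _fmt(stroke), "opacity": _fmt(style.opacity)},
    )
    for tid, pts in boxes_t.items():
        ET.SubElement(
            group,
            "polygon",
            id=f"box-{tid}",
            points=_points_attr(pts),
            stroke=style.box_color,
        )
        if style.rounded_crowns:
            # drawn in template frame then transformed via the matrix so the
            # Beziers follow the registration exactly
            m = transform.matrix
            ET.SubElement(
                group,
                "path",
                id=f"crown-{tid}",
                d=_crown_path(boxes[tid]),
                stroke=style.box_color,
                attrib={
                    "stroke-dasharray": "2,1",
                    "transform": "matrix({} {} {} {} {} {})".format(
                        *map(_fmt, (m[0, 0], m[1, 0], m[0, 1], m[1, 1], m[0, 2], m[1, 2]))
                    ),
                },
            )
    for pair, pts in conns_t.items():
        ET.SubElement(
            group,
            "polyline",
            id=f"connector-{pair}",
            points=_points_attr(pts),
            stroke=style.connector_color,
        )
    for name, pts in lines_t.items():
        ET.SubElement(
            group,
            "polyline",
            id=f"line-{name}",
            points=_points_attr(pts),
            stroke=style.line_colors.get(name, "#888888"),
        )
    return ET.tostring(svg, encoding="unicode")


# ---------------------------------------------------------------------------
# raster rendering


def _parse_color(color: str, alpha: int) -> Tuple[int, int, int, int]:
    c = color.lstrip("#")
    return (int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16), alpha)


def render_overlay(
    geom: TemplateGeometry,
    transform: Optional[SimilarityTransform] = None,
    image: Optional[str | Path | Image.Image] = None,
    canvas_size: Optional[Tuple[int, int]] = None,
    style: OverlayStyle = OverlayStyle(),
    out_path: Optional[str | Path] = None,
) -> OverlayRender:
    """Composite the registered template onto a photograph (or a blank
    canvas) and return the render; optionally save it.

    ``image`` may be a PNG/JPEG/TIFF path or a PIL image; when omitted a
    transparent canvas of ``canvas_size`` (or the template bounding box)
    is used, giving the pure-template semi-transparent PNG.  A transform
    that places the template partly outside the canvas triggers a
    warning; the render is clipped, not refused.
    """
    transform = transform or _IDENTITY
    render = OverlayRender(transform=transform, style=style)

    if isinstance(image, (str, Path)):
        base = Image.open(image).convert("RGBA")
    elif isinstance(image, Image.Image):
        base = image.convert("RGBA")
    else:
        boxes, conns, lines = _template_elements(geom)
        pts = transform.apply([p for g in (*boxes.values(), *lines.values()) for p in g])
        if canvas_size is None:
            canvas_size = (
                int(pts[:, 0].max() - min(0.0, pts[:, 0].min())) + 2,
                int(pts[:, 1].max() - min(0.0, pts[:, 1].min())) + 2,
            )
        base = Image.new("RGBA", canvas_size, (0, 0, 0, 0))

    boxes, connectors, lines = _template_elements(geom)
    all_template_pts = [
        p
        for group in (*boxes.values(), *connectors.values(), *lines.values())
        for p in group
    ]
    tx = transform.apply(all_template_pts)
    x0, y0, x1, y1 = tx[:, 0].min(), tx[:, 1].min(), tx[:, 0].max(), tx[:, 1].max()
    if x0 < 0 or y0 < 0 or x1 > base.width or y1 > base.height:
        msg = (
            "template maps partly outside the canvas "
            f"(bbox [{x0:.1f},{y0:.1f}]-[{x1:.1f},{y1:.1f}] vs "
            f"{base.width}x{base.height}); output is clipped"
        )
        render.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    layer = Image.new("RGBA", base.size, (0, 0, 0, 0))
    draw = ImageDraw.Draw(layer)
    alpha = int(round(255 * style.opacity))
    w = max(1, int(round(style.stroke_mm * transform.scale)))

    def draw_poly(pts: Sequence[Point], color: str, closed: bool = False) -> None:
        mapped = [tuple(q) for q in transform.apply(pts)]
        if closed:
            mapped.append(mapped[0])
        draw.line(mapped, fill=_parse_color(color, alpha), width=w)

    for tid, pts in boxes.items():
        draw_poly(pts, style.box_color, closed=True)
    for pair, pts in connectors.items():
        draw_poly(pts, style.connector_color)
    for name, pts in lines.items():
        draw_poly(pts, style.line_colors.get(name, "#888888"))

    render.image = Image.alpha_composite(base, layer)
    render.svg = render_svg(
        geom,
        transform,
        image_path=image if isinstance(image, (str, Path)) else None,
        canvas_size=base.size,
        style=style,
    )
    if out_path is not None:
        render.save(out_path)
    return render
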