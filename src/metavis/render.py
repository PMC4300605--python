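"""Static SVG rendering of layouts and overlays.

Shape vocabulary: reaction nodes are squares, regular metabolites circles,
currency metabolites small gray circles; edges are straight lines between
node borders.  Arrowheads are drawn as explicit filled triangles
(``<polygon class="arrowhead">``) rather than marker definitions, so their
count and color are directly inspectable: irreversible reactions arrow
their product edges only, reversible reactions arrow the metabolite end of
every edge.  Genetic-condition glyphs (red cross, up/down arrows) sit on or
above their reaction node.

Element order is deterministic (sorted by node id) so that rendered output
is stable across runs, and every visible node's SVG group carries the node
id — hidden nodes never appear in the text at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence
from xml.sax.saxutils import escape, quoteattr

from .layout import (Edge, EdgeRole, MetaboliteKind, MetabolicLayout,
                     VisibilityFilter, visible_node_ids)
from .overlay import RGB, Glyph, Overlay, StyleConfig


class RenderError(ValueError):
    pass


@dataclass
class RenderConfig:
    padding: float = 40.0
    reaction_size: float = 14.0     # square side
    metabolite_radius: float = 9.0
    currency_radius: float = 5.0
    #: which node attributes make up a label, in order; any of
    #: "label", "id", "model_ids"
    reaction_label_attrs: tuple[str, ...] = ("label",)
    metabolite_label_attrs: tuple[str, ...] = ("label",)
    background: Optional[str] = "#ffffff"
    style: StyleConfig = field(default_factory=StyleConfig)


def _hex(color: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*color)


def _label_text(node, attrs: Sequence[str]) -> str:
    parts = []
    for attr in attrs:
        if attr == "label":
            parts.append(node.label)
        elif attr == "id":
            parts.append(node.id)
        elif attr == "model_ids":
            parts.append(",".join(node.model_ids))
    return " ".join(p for p in parts if p)


def _shrink(p: tuple[float, float], q: tuple[float, float],
            by: float) -> tuple[float, float]:
    """Point on segment p→q at distance ``by`` before q."""
    dx, dy = q[0] - p[0], q[1] - p[1]
    dist = math.hypot(dx, dy)
    if dist <= by or dist == 0:
        return q
    t = (dist - by) / dist
    return (p[0] + dx * t, p[1] + dy * t)


def _arrowhead(tip: tuple[float, float], source: tuple[float, float],
               size: float, color: str) -> str:
    """Filled triangle with apex at ``tip`` pointing away from ``source``."""
    dx, dy = tip[0] - source[0], tip[1] - source[1]
    dist = math.hypot(dx, dy) or 1.0
    ux, uy = dx / dist, dy / dist
    bx, by = tip[0] - ux * size, tip[1] - uy * size
    px, py = -uy, ux
    half = size * 0.45
    points = (f"{tip[0]:.2f},{tip[1]:.2f} "
              f"{bx + px * half:.2f},{by + py * half:.2f} "
              f"{bx - px * half:.2f},{by - py * half:.2f}")
    return (f'<polygon class="arrowhead" points="{points}" '
            f'fill="{color}" />')


def render_svg(layout: MetabolicLayout,
               overlay: Optional[Overlay] = None,
               active_filters: Optional[Sequence[str | VisibilityFilter]] = None,
               config: Optional[RenderConfig] = None) -> str:
    """Render a positioned layout to an SVG 1.1 document string.

    ``active_filters`` selects hide-filters by name from the overlay (a
    :class:`VisibilityFilter` object is also accepted directly).  Every
    visible node must have a position; run the spring embedder first
    otherwise.
    """
    config = config or RenderConfig()
    style = config.style
    overlay = overlay or Overlay()

    filters: list[VisibilityFilter] = []
    for item in (active_filters or []):
        if isinstance(item, VisibilityFilter):
            filters.append(item)
        else:
            match = next((f for f in overlay.filters if f.name == item), None)
            if match is None:
                raise RenderError(f"no filter named {item!r} in overlay")
            filters.append(match)

    visible = visible_node_ids(layout, filters)
    vis_mets = [layout.metabolite_nodes[i]
                for i in sorted(set(layout.metabolite_nodes) & visible)]
    vis_rxns = [layout.reaction_nodes[i]
                for i in sorted(set(layout.reaction_nodes) & visible)]
    vis_infos = [layout.info_nodes[i]
                 for i in sorted(set(layout.info_nodes) & visible)]
    for node in vis_mets + vis_rxns:
        if node.position is None:
            raise RenderError(f"visible node {node.id!r} has no position; "
                              "run the layout engine first")

    positioned = [n.position for n in vis_mets + vis_rxns]
    if positioned:
        xs = [p[0] for p in positioned]
        ys = [p[1] for p in positioned]
        min_x, max_x = min(xs) - config.padding, max(xs) + config.padding
        min_y, max_y = min(ys) - config.padding, max(ys) + config.padding
    else:
        min_x = min_y = 0.0
        max_x = max_y = 2 * config.padding
    width, height = max_x - min_x, max_y - min_y

    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="UTF-8"?>')
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.0f}" height="{height:.0f}" '
        f'viewBox="{min_x:.2f} {min_y:.2f} {width:.2f} {height:.2f}">')
    if config.background:
        parts.append(f'<rect x="{min_x:.2f}" y="{min_y:.2f}" '
                     f'width="{width:.2f}" height="{height:.2f}" '
                     f'fill="{config.background}" />')

    # edges (under the nodes), sorted for stable output
    default_edge = _hex(style.edge_color)
    arrow_size = 9.0
    for edge in sorted((e for e in layout.edges
                        if e.reaction_id in visible
                        and e.metabolite_id in visible),
                       key=lambda e: (e.reaction_id, e.metabolite_id,
                                      e.role.value)):
        rxn = layout.reaction_nodes[edge.reaction_id]
        met = layout.metabolite_nodes[edge.metabolite_id]
        met_r = (config.currency_radius
                 if met.kind is MetaboliteKind.CURRENCY
                 else config.metabolite_radius)
        rxn_r = config.reaction_size / 2.0
        p_rxn = _shrink(met.position, rxn.position, rxn_r)
        p_met = _shrink(rxn.position, met.position, met_r)
        w = overlay.edge_width.get(edge, style.min_width)
        color = _hex(overlay.edge_color[edge]) \
            if edge in overlay.edge_color else default_edge
        parts.append(
            f'<line x1="{p_rxn[0]:.2f}" y1="{p_rxn[1]:.2f}" '
            f'x2="{p_met[0]:.2f}" y2="{p_met[1]:.2f}" '
            f'stroke="{color}" stroke-width="{w:.3f}" />')

        # arrowheads: reversible -> at the metabolite end of every edge;
        # irreversible -> at the metabolite end of product edges only
        back_color, fwd_color = overlay.direction_colors.get(
            edge.reaction_id, (None, None))
        if rxn.reversible or edge.role is EdgeRole.PRODUCT:
            head = (fwd_color if edge.role is EdgeRole.PRODUCT
                    else back_color)
            tip = _shrink(rxn.position, met.position, met_r)
            parts.append(_arrowhead(
                tip, rxn.position, arrow_size,
                _hex(head) if head else color))

    for node in vis_mets:
        x, y = node.position
        r = (config.currency_radius if node.kind is MetaboliteKind.CURRENCY
             else config.metabolite_radius)
        fill = _hex(style.currency_color
                    if node.kind is MetaboliteKind.CURRENCY
                    else style.node_color)
        label = _label_text(node, config.metabolite_label_attrs)
        parts.append(f'<g id={quoteattr(node.id)}>')
        parts.append(f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{r}" '
                     f'fill="{fill}" stroke="#222222" />')
        if label:
            parts.append(
                f'<text x="{x:.2f}" y="{y + r + style.font_size:.2f}" '
                f'text-anchor="middle" font-family="{style.font_family}" '
                f'font-size="{style.font_size}">{escape(label)}</text>')
        parts.append('</g>')

    half = config.reaction_size / 2.0
    for node in vis_rxns:
        x, y = node.position
        label = _label_text(node, config.reaction_label_attrs)
        suffix = overlay.label_suffix.get(node.id)
        if suffix:
            label = f"{label} {suffix}" if label else suffix
        parts.append(f'<g id={quoteattr(node.id)}>')
        parts.append(
            f'<rect x="{x - half:.2f}" y="{y - half:.2f}" '
            f'width="{config.reaction_size}" '
            f'height="{config.reaction_size}" '
            f'fill="#ffffff" stroke="#222222" />')
        glyph = overlay.node_glyph.get(node.id, Glyph.NONE)
        if glyph is Glyph.KNOCKOUT_CROSS:
            c = _hex(style.knockout_color)
            s = config.reaction_size * 0.9
            parts.append(
                f'<g class="glyph knockout_cross" stroke="{c}" '
                f'stroke-width="2.5">'
                f'<line x1="{x - s:.2f}" y1="{y - s:.2f}" '
                f'x2="{x + s:.2f}" y2="{y + s:.2f}" />'
                f'<line x1="{x - s:.2f}" y1="{y + s:.2f}" '
                f'x2="{x + s:.2f}" y2="{y - s:.2f}" /></g>')
        elif glyph in (Glyph.UP_ARROW, Glyph.DOWN_ARROW):
            up = glyph is Glyph.UP_ARROW
            c = _hex(style.over_color if up else style.under_color)
            base_y = y - half - 4
            tip_y = base_y - 12 if up else base_y
            flat_y = base_y if up else base_y - 12
            parts.append(
                f'<polygon class="glyph {glyph.value}" '
                f'points="{x:.2f},{tip_y:.2f} {x - 6:.2f},{flat_y:.2f} '
                f'{x + 6:.2f},{flat_y:.2f}" fill="{c}" />')
        if label:
            parts.append(
                f'<text x="{x:.2f}" y="{y + half + style.font_size:.2f}" '
                f'text-anchor="middle" font-family="{style.font_family}" '
                f'font-size="{style.font_size}">{escape(label)}</text>')
        parts.append('</g>')

    for info in vis_infos:
        rxn = layout.reaction_nodes[info.reaction_id]
        if rxn.position is None:
            continue
        x, y = rxn.position
        parts.append(
            f'<text id={quoteattr(info.id)} class="info" '
            f'x="{x + half + 6:.2f}" y="{y - half - 4:.2f}" '
            f'font-family="{style.font_family}" '
            f'font-size="{style.font_size * 0.85:.1f}" '
            f'fill="#666666">{escape(info.text)}</text>')

    parts.append('</svg>')
    return "\n".join(parts)
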