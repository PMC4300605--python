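"""Conversion of analysis results into visual overlays.

An :class:`Overlay` is the single channel from phenotype-simulation results
to the renderer: per-edge widths and colors, per-reaction glyphs (knockout
cross, up/down expression arrows), label suffixes carrying flux values, and
named hide-filters.

Width rule — flux magnitudes are normalized linearly against the largest
mapped magnitude F: every edge incident to a node with flux f gets width
``min_width + (max_width - min_width) * |f| / F`` (all ``min_width`` when
F = 0), so the strongest flux attains ``max_width`` exactly and widths are
invariant under rescaling all fluxes by a positive constant.

Comparison rule — for two simulations, per node a = |fA| and b = |fB|; the
edge color blends the neutral color (black: no difference) toward the first
simulation's color when a > b and toward the second's when b > a, with
scale-free weight ``|a - b| / max(a, b)``; widths use the per-node mean
(a + b)/2 normalized as above; on reversible reactions whose fluxes run in
opposite directions, each arrowhead end takes the color of the simulation
flowing the way it points.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .layout import Edge, MetabolicLayout, VisibilityFilter
from .mapping import (FluxDistribution, GeneticConditions, ModelMapping,
                      fluxes_per_reaction_node, mapped_reaction_nodes)

RGB = tuple[int, int, int]


class Glyph(enum.Enum):
    NONE = "none"
    KNOCKOUT_CROSS = "knockout_cross"
    UP_ARROW = "up_arrow"
    DOWN_ARROW = "down_arrow"


@dataclass
class StyleConfig:
    min_width: float = 1.0
    max_width: float = 8.0
    knockout_color: RGB = (0xCC, 0x00, 0x00)   # red
    over_color: RGB = (0x00, 0xAA, 0x00)       # green
    under_color: RGB = (0xE6, 0x95, 0x00)      # orange
    sim1_color: RGB = (0xCC, 0x00, 0x00)       # red
    sim2_color: RGB = (0x00, 0xAA, 0x00)       # green
    neutral_color: RGB = (0, 0, 0)             # black: equal fluxes
    flux_label_decimals: int = 3
    node_color: RGB = (0x33, 0x66, 0x99)
    currency_color: RGB = (0xAA, 0xAA, 0xAA)
    edge_color: RGB = (0x55, 0x55, 0x55)
    font_family: str = "sans-serif"
    font_size: float = 11.0

    def __post_init__(self) -> None:
        if not self.min_width < self.max_width:
            raise ValueError("min_width must be smaller than max_width")


@dataclass
class Overlay:
    edge_width: dict[Edge, float] = field(default_factory=dict)
    edge_color: dict[Edge, RGB] = field(default_factory=dict)
    node_glyph: dict[str, Glyph] = field(default_factory=dict)
    label_suffix: dict[str, str] = field(default_factory=dict)
    filters: list[VisibilityFilter] = field(default_factory=list)
    #: reaction id -> (color at substrate-pointing ends, color at
    #: product-pointing ends); only set by comparison overlays on
    #: reversible reactions whose two fluxes run in opposite directions.
    direction_colors: dict[str, tuple[RGB, RGB]] = field(default_factory=dict)
    #: condition model ids that resolved to no layout node
    unmapped_condition_ids: list[str] = field(default_factory=list)

    def merge(self, other: "Overlay") -> "Overlay":
        """Later overlay wins on conflicts; filters are concatenated."""
        out = Overlay(
            edge_width={**self.edge_width, **other.edge_width},
            edge_color={**self.edge_color, **other.edge_color},
            node_glyph={**self.node_glyph, **other.node_glyph},
            label_suffix={**self.label_suffix, **other.label_suffix},
            filters=self.filters + other.filters,
            direction_colors={**self.direction_colors,
                              **other.direction_colors},
            unmapped_condition_ids=(self.unmapped_condition_ids
                                    + other.unmapped_condition_ids))
        return out


def _normalized_widths(layout: MetabolicLayout,
                       node_flux: dict[str, float],
                       style: StyleConfig) -> dict[Edge, float]:
    peak = max((abs(v) for v in node_flux.values()), default=0.0)
    widths: dict[Edge, float] = {}
    for node_id, value in node_flux.items():
        if peak > 0:
            # ratio first: |f|/F is exactly 1.0 at the peak, so the widest
            # edge attains max_width without rounding error
            width = style.min_width + (style.max_width - style.min_width) \
                * (abs(value) / peak)
        else:
            width = style.min_width
        for edge in layout.edges:
            if edge.reaction_id == node_id:
                widths[edge] = width
    return widths


def _format_flux(value: float, style: StyleConfig) -> str:
    return f"{value:.{style.flux_label_decimals}f}"


def flux_overlay(layout: MetabolicLayout, mapping: ModelMapping,
                 flux: FluxDistribution,
                 style: Optional[StyleConfig] = None) -> Overlay:
    """Paint one flux distribution: normalized edge widths plus the numeric
    flux value appended to each mapped reaction's label."""
    style = style or StyleConfig()
    node_flux = fluxes_per_reaction_node(layout, mapping, flux)
    overlay = Overlay(edge_width=_normalized_widths(layout, node_flux, style))
    for node_id, value in node_flux.items():
        overlay.label_suffix[node_id] = _format_flux(value, style)
    return overlay


def genetic_overlay(layout: MetabolicLayout, mapping: ModelMapping,
                    conditions: GeneticConditions,
                    style: Optional[StyleConfig] = None) -> Overlay:
    """Mark genetic modifications: knocked-out reactions get a red cross
    and red incident edges, over-expressed a green up-arrow and green
    edges, under-expressed an orange down-arrow and orange edges.
    Condition ids with no mapped node land in the overlay's diagnostics."""
    style = style or StyleConfig()
    overlay = Overlay()
    for ids, glyph, color in (
            (conditions.knockouts, Glyph.KNOCKOUT_CROSS, style.knockout_color),
            (conditions.over_expressed, Glyph.UP_ARROW, style.over_color),
            (conditions.under_expressed, Glyph.DOWN_ARROW, style.under_color)):
        resolved = mapped_reaction_nodes(mapping, ids)
        overlay.unmapped_condition_ids += sorted(set(ids) - set(resolved))
        for node_ids in resolved.values():
            for node_id in node_ids:
                overlay.node_glyph[node_id] = glyph
                for edge in layout.edges:
                    if edge.reaction_id == node_id:
                        overlay.edge_color[edge] = color
    return overlay


def _blend(base: RGB, target: RGB, weight: float) -> RGB:
    return tuple(round(b + (t - b) * weight)
                 for b, t in zip(base, target))  # type: ignore[return-value]


def comparison_overlay(layout: MetabolicLayout, mapping: ModelMapping,
                       flux_a: FluxDistribution, flux_b: FluxDistribution,
                       style: Optional[StyleConfig] = None,
                       conditions_a: Optional[GeneticConditions] = None,
                       conditions_b: Optional[GeneticConditions] = None
                       ) -> Overlay:
    """Compare two simulations on one layout.

    Edge colors span the first simulation's color ↔ black ↔ the second's;
    widths come from the per-node mean |flux|; each simulation contributes
    a hide-zero filter and (optionally) its genetic-condition glyphs."""
    style = style or StyleConfig()
    fa = fluxes_per_reaction_node(layout, mapping, flux_a)
    fb = fluxes_per_reaction_node(layout, mapping, flux_b)
    nodes = set(fa) | set(fb)

    means = {n: (abs(fa.get(n, 0.0)) + abs(fb.get(n, 0.0))) / 2.0
             for n in nodes}
    overlay = Overlay(edge_width=_normalized_widths(layout, means, style))

    for node_id in nodes:
        a, b = abs(fa.get(node_id, 0.0)), abs(fb.get(node_id, 0.0))
        peak = max(a, b)
        if peak == 0.0:
            continue  # both zero: keep the default edge style
        weight = abs(a - b) / peak
        target = style.sim1_color if a > b else style.sim2_color
        color = _blend(style.neutral_color, target, weight) \
            if a != b else style.neutral_color
        for edge in layout.edges:
            if edge.reaction_id == node_id:
                overlay.edge_color[edge] = color
        overlay.label_suffix[node_id] = (
            f"{_format_flux(fa.get(node_id, 0.0), style)} | "
            f"{_format_flux(fb.get(node_id, 0.0), style)}")

        node = layout.reaction_nodes.get(node_id)
        va, vb = fa.get(node_id, 0.0), fb.get(node_id, 0.0)
        if node is not None and node.reversible and va * vb < 0:
            # opposite directions: arrowheads take the color of the
            # simulation flowing the way they point (product ends point
            # forward, substrate ends backward)
            forward = style.sim1_color if va > 0 else style.sim2_color
            backward = style.sim2_color if va > 0 else style.sim1_color
            overlay.direction_colors[node_id] = (backward, forward)

    for name, values in (("hide-zero-in-A", fa), ("hide-zero-in-B", fb)):
        hidden = {n for n in layout.reaction_nodes
                  if values.get(n, 0.0) == 0.0}
        overlay.filters.append(VisibilityFilter(name, hidden))

    genetic = Overlay()
    if conditions_a is not None:
        genetic = genetic.merge(
            genetic_overlay(layout, mapping, conditions_a, style))
    if conditions_b is not None:
        genetic = genetic.merge(
            genetic_overlay(layout, mapping, conditions_b, style))
    # genetic glyph colors win over gradient colors on touched edges
    return overlay.merge(genetic)


def efm_overlay(layout: MetabolicLayout, mapping: ModelMapping,
                efm_flux: FluxDistribution,
                style: Optional[StyleConfig] = None) -> Overlay:
    """Paint one elementary flux mode: widths and labels as for a flux
    distribution (no recoloring, no glyphs) plus a filter hiding the
    reactions outside the mode together with their orphaned metabolites."""
    style = style or StyleConfig()
    overlay = flux_overlay(layout, mapping, efm_flux, style)
    node_flux = fluxes_per_reaction_node(layout, mapping, efm_flux)
    hidden_reactions = {n for n in layout.reaction_nodes
                        if node_flux.get(n, 0.0) == 0.0}
    hidden = set(hidden_reactions)
    for met_id in layout.metabolite_nodes:
        neighbors = {e.reaction_id for e in layout.edges
                     if e.metabolite_id == met_id}
        if neighbors and neighbors <= hidden_reactions:
            hidden.add(met_id)
    overlay.filters.append(VisibilityFilter("hide-zero-flux", hidden))
    return overlay
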