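"""Resolution of model identifiers onto layout nodes, and flux aggregation.

A layout can depict part of one genome-scale model, be reused across model
versions, or replicate nodes for readability, so the link between model
reaction/metabolite ids and layout nodes is many-to-many.  Mappings are
built either from an explicit two-column table (layout id, model id), from
regex canonicalization of the ids on both sides, or — the default — from the
model-id lists the layout nodes already carry.

Flux values keyed by model reaction id are pushed onto reaction nodes by
summation: when several model reactions map to one node their values are
added; when one model reaction maps to several replica nodes each replica
receives the full value (replicas depict the same reaction, so their visual
weight should agree).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from .layout import MetabolicLayout


class MappingError(Exception):
    pass


class MappingParseError(MappingError, ValueError):
    """Malformed mapping/flux/condition table; carries the 1-based line."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class ModelMapping:
    reaction_map: dict[str, set[str]] = field(default_factory=dict)
    metabolite_map: dict[str, set[str]] = field(default_factory=dict)
    unmatched_model_ids: list[str] = field(default_factory=list)
    unmatched_layout_ids: list[str] = field(default_factory=list)


@dataclass
class FluxDistribution:
    """Model reaction id -> flux value (conventionally mmol gDW^-1 h^-1;
    the sign encodes direction relative to the declared orientation)."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite flux for {rid!r}: {v}")


@dataclass
class GeneticConditions:
    """Genetic modifications of a simulated mutant: reaction knockouts and
    over/under-expressed reactions.  The three sets must be disjoint."""

    knockouts: set[str] = field(default_factory=set)
    over_expressed: set[str] = field(default_factory=set)
    under_expressed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.knockouts & self.over_expressed
                or self.knockouts & self.under_expressed
                or self.over_expressed & self.under_expressed):
            raise ValueError("knockout/over/under sets must be disjoint")


# ---------------------------------------------------------------------------
# text tables


def load_mapping_table(stream: TextIO | Iterable[str]) -> list[tuple[str, str]]:
    """Parse a two-column ``layout_id model_id`` table (whitespace- or
    tab-delimited, ``#`` comments).  Duplicate pairs are dropped, order is
    preserved."""
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 2:
            raise MappingParseError(
                f"expected 2 columns, found {len(cols)}", lineno)
        pair = (cols[0], cols[1])
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return pairs


def read_flux_tsv(stream: TextIO | Iterable[str]) -> FluxDistribution:
    """Read a flux distribution from two-column TSV ``reaction_id<TAB>value``
    with an optional header line."""
    values: dict[str, float] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) != 2:
            raise MappingParseError(
                f"expected 2 columns, found {len(cols)}", lineno)
        try:
            value = float(cols[1])
        except ValueError:
            if lineno == 1:  # header
                continue
            raise MappingParseError(
                f"non-numeric flux value {cols[1]!r}", lineno) from None
        values[cols[0]] = value
    return FluxDistribution(values)


def write_flux_tsv(flux: FluxDistribution, stream: TextIO) -> None:
    stream.write("reaction_id\tflux\n")
    for rid, v in flux.values.items():
        stream.write(f"{rid}\t{v:.10g}\n")


_CONDITION_KINDS = {"KO", "OVER", "UNDER"}


def read_conditions_tsv(stream: TextIO | Iterable[str]) -> GeneticConditions:
    """Read genetic conditions from TSV ``reaction_id<TAB>{KO|OVER|UNDER}``."""
    ko: set[str] = set()
    over: set[str] = set()
    under: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) != 2 or cols[1].upper() not in _CONDITION_KINDS:
            raise MappingParseError(
                "expected 'reaction_id<TAB>{KO|OVER|UNDER}'", lineno)
        {"KO": ko, "OVER": over, "UNDER": under}[cols[1].upper()].add(cols[0])
    return GeneticConditions(ko, over, under)


def write_conditions_tsv(conditions: GeneticConditions, stream: TextIO) -> None:
    for rid in sorted(conditions.knockouts):
        stream.write(f"{rid}\tKO\n")
    for rid in sorted(conditions.over_expressed):
        stream.write(f"{rid}\tOVER\n")
    for rid in sorted(conditions.under_expressed):
        stream.write(f"{rid}\tUNDER\n")


# ---------------------------------------------------------------------------
# mapping construction


def _apply_regex(rule: Optional[tuple[str, str]], ident: str) -> str:
    if rule is None:
        return ident
    pattern, replacement = rule
    return re.sub(pattern, replacement, ident)


def build_mapping(layout: MetabolicLayout,
                  model_reaction_ids: Iterable[str],
                  model_metabolite_ids: Iterable[str],
                  pairs: Optional[Sequence[tuple[str, str]]] = None,
                  layout_regex: Optional[tuple[str, str]] = None,
                  model_regex: Optional[tuple[str, str]] = None) -> ModelMapping:
    """Resolve model ids to layout nodes.

    Exactly one mode applies per call:

    * ``pairs`` — map exactly the listed (layout id, model id) pairs;
    * regex mode (either regex given) — apply the substitutions to layout
      node ids and model ids and match equal canonical strings, plus any
      model id already listed verbatim in a node's ``model_ids``;
    * default — match model ids against the nodes' ``model_ids`` lists.

    Matching is case-sensitive (SBML ids are).  Unmatched ids on either side
    are collected for diagnostics, never fatal.
    """
    if pairs is not None and (layout_regex or model_regex):
        raise MappingError("use either explicit pairs or regex mode, not both")
    for rule in (layout_regex, model_regex):
        if rule is not None:
            try:
                re.compile(rule[0])
            except re.error as exc:
                raise MappingError(f"invalid regex {rule[0]!r}: {exc}") from exc

    model_rxn = sorted(set(model_reaction_ids))
    model_met = sorted(set(model_metabolite_ids))
    mapping = ModelMapping()

    if pairs is not None:
        rxn_set, met_set = set(model_rxn), set(model_met)
        for layout_id, model_id in pairs:
            if layout_id in layout.reaction_nodes and model_id in rxn_set:
                mapping.reaction_map.setdefault(model_id, set()).add(layout_id)
            elif layout_id in layout.metabolite_nodes and model_id in met_set:
                mapping.metabolite_map.setdefault(model_id, set()).add(layout_id)
            else:
                mapping.unmatched_layout_ids.append(layout_id)
    else:
        use_canonical = layout_regex is not None or model_regex is not None
        for model_ids, nodes, target in (
                (model_rxn, layout.reaction_nodes, mapping.reaction_map),
                (model_met, layout.metabolite_nodes, mapping.metabolite_map)):
            canon_nodes: dict[str, set[str]] = {}
            verbatim: dict[str, set[str]] = {}
            for node_id, node in nodes.items():
                if use_canonical:
                    canon_nodes.setdefault(
                        _apply_regex(layout_regex, node_id), set()).add(node_id)
                for mid in node.model_ids:
                    verbatim.setdefault(mid, set()).add(node_id)
            for model_id in model_ids:
                hits = set(verbatim.get(model_id, set()))
                if use_canonical:
                    hits |= canon_nodes.get(
                        _apply_regex(model_regex, model_id), set())
                if hits:
                    target[model_id] = hits

    matched_models = set(mapping.reaction_map) | set(mapping.metabolite_map)
    mapping.unmatched_model_ids = [
        mid for mid in model_rxn + model_met if mid not in matched_models]
    mapped_layout = {nid for nodes in mapping.reaction_map.values()
                     for nid in nodes}
    mapped_layout |= {nid for nodes in mapping.metabolite_map.values()
                      for nid in nodes}
    mapping.unmatched_layout_ids += sorted(
        (set(layout.reaction_nodes) | set(layout.metabolite_nodes))
        - mapped_layout - set(mapping.unmatched_layout_ids))
    return mapping


def fluxes_per_reaction_node(layout: MetabolicLayout,
                             mapping: ModelMapping,
                             flux: FluxDistribution) -> dict[str, float]:
    """Aggregate model-level fluxes onto reaction nodes by summation.
    Nodes with no mapped flux value are absent from the result."""
    out: dict[str, float] = {}
    for model_id, node_ids in mapping.reaction_map.items():
        if model_id not in flux.values:
            continue
        for node_id in node_ids:
            if node_id in layout.reaction_nodes:
                out[node_id] = out.get(node_id, 0.0) + flux.values[model_id]
    return out


def mapped_reaction_nodes(mapping: ModelMapping,
                          model_ids: Iterable[str]) -> dict[str, set[str]]:
    """Model ids from ``model_ids`` resolved to layout node ids; ids with no
    mapped node are simply absent (callers collect them as diagnostics)."""
    return {mid: set(mapping.reaction_map[mid])
            for mid in model_ids if mid in mapping.reaction_map}
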