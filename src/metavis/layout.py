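"""Abstract metabolic layout: a bipartite reaction-compound graph.

A :class:`MetabolicLayout` holds reaction nodes, metabolite nodes, free-text
information nodes attached to reactions, and substrate/product edges that may
only connect a reaction to a metabolite (bipartiteness).  Arrowhead semantics
are derived from reaction reversibility at render time and never stored:
irreversible reactions draw arrows toward products only, reversible reactions
draw arrows at both metabolite ends.

Every node carries a list of *model identifiers* linking it to reactions or
species of a genome-scale metabolic model; several nodes may share the same
model id (replicas of a currency metabolite, duplicated reactions) and one
node may aggregate several model ids.  Coordinates live on an abstract
unitless canvas with the origin at the top-left and y increasing downward,
matching SVG.

All editing operations are pure: they return a new layout and leave their
input untouched.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence


class MetaboliteKind(enum.Enum):
    """Metabolite classes: regular compounds vs. highly connected currency
    hubs (water, ATP, cofactors) that are usually replicated or hidden."""

    REGULAR = "regular"
    CURRENCY = "currency"


class EdgeRole(enum.Enum):
    SUBSTRATE = "substrate"
    PRODUCT = "product"


class LayoutError(Exception):
    """Base class for layout editing errors."""


class NodeNotFoundError(LayoutError, KeyError):
    pass


class WrongNodeKindError(LayoutError, TypeError):
    pass


class SameCompoundViolation(LayoutError, ValueError):
    """Metabolite nodes do not represent the same compound (model ids or
    kind differ), so they may not be merged."""


class MergeIllegalError(LayoutError, ValueError):
    """Reaction nodes are not exactly the same (neighbors, roles or
    reversibility differ), so they may not be merged."""


@dataclass
class MetaboliteNode:
    id: str
    label: str = ""
    model_ids: list[str] = field(default_factory=list)
    kind: MetaboliteKind = MetaboliteKind.REGULAR
    position: Optional[tuple[float, float]] = None
    fixed: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be a non-empty string")
        if self.fixed and self.position is None:
            raise ValueError(f"fixed node {self.id!r} must have a position")


@dataclass
class ReactionNode:
    id: str
    label: str = ""
    model_ids: list[str] = field(default_factory=list)
    reversible: bool = False
    position: Optional[tuple[float, float]] = None
    fixed: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be a non-empty string")
        if self.fixed and self.position is None:
            raise ValueError(f"fixed node {self.id!r} must have a position")


@dataclass
class InfoNode:
    """Free-text annotation attached to a reaction node.  Information nodes
    are laid out beside their reaction and take no part in layout forces."""

    id: str
    text: str
    reaction_id: str


@dataclass(frozen=True)
class Edge:
    reaction_id: str
    metabolite_id: str
    role: EdgeRole


@dataclass(frozen=True)
class Violation:
    """One violated layout invariant, reported by :func:`validate_layout`."""

    code: str  # dangling_edge | duplicate_node_id | duplicate_edge | not_bipartite | bad_info_ref | fixed_without_position
    message: str
    subject: str  # offending node id or edge repr


@dataclass
class VisibilityFilter:
    """A named set of node ids to hide.  Hiding a node hides its incident
    edges and any attached information nodes."""

    name: str
    hidden_node_ids: set[str] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)


@dataclass
class MetabolicLayout:
    name: str = "layout"
    metabolite_nodes: dict[str, MetaboliteNode] = field(default_factory=dict)
    reaction_nodes: dict[str, ReactionNode] = field(default_factory=dict)
    info_nodes: dict[str, InfoNode] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------
    def add_metabolite(self, node: MetaboliteNode) -> None:
        self._check_fresh(node.id)
        self.metabolite_nodes[node.id] = node

    def add_reaction(self, node: ReactionNode) -> None:
        self._check_fresh(node.id)
        self.reaction_nodes[node.id] = node

    def add_info(self, node: InfoNode) -> None:
        self._check_fresh(node.id)
        self.info_nodes[node.id] = node

    def add_edge(self, reaction_id: str, metabolite_id: str,
                 role: EdgeRole | str) -> None:
        if isinstance(role, str):
            role = EdgeRole(role)
        edge = Edge(reaction_id, metabolite_id, role)
        if edge not in set(self.edges):
            self.edges.append(edge)

    def _check_fresh(self, node_id: str) -> None:
        if node_id in self.metabolite_nodes or node_id in self.reaction_nodes \
                or node_id in self.info_nodes:
            raise ValueError(f"duplicate node id {node_id!r}")

    # -- queries --------------------------------------------------------------
    def node_ids(self) -> set[str]:
        return (set(self.metabolite_nodes) | set(self.reaction_nodes)
                | set(self.info_nodes))

    def edges_of(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges
                if node_id in (e.reaction_id, e.metabolite_id)]

    def degree(self, node_id: str) -> int:
        return len(self.edges_of(node_id))

    def copy(self) -> "MetabolicLayout":
        return copy.deepcopy(self)

    def fresh_id(self, base: str) -> str:
        """First id of the form ``base__k`` (k = 1, 2, ...) not yet taken."""
        taken = self.node_ids()
        k = 1
        while f"{base}__{k}" in taken:
            k += 1
        return f"{base}__{k}"


# ---------------------------------------------------------------------------
# validation


def validate_layout(layout: MetabolicLayout) -> list[Violation]:
    """Check every structural invariant; return one record per violation.

    Validation reports and never raises.  An empty list means the layout is
    valid.  Checks: duplicate node ids across the three node collections,
    edges whose endpoints do not exist (dangling), edges that do not connect
    a reaction to a metabolite (bipartiteness), duplicate
    (reaction, metabolite, role) triples, info nodes pointing at
    non-reactions, and fixed nodes without coordinates.
    """
    violations: list[Violation] = []
    seen: set[str] = set()
    for collection in (layout.metabolite_nodes, layout.reaction_nodes,
                       layout.info_nodes):
        for node_id in collection:
            if node_id in seen:
                violations.append(Violation(
                    "duplicate_node_id",
                    f"node id {node_id!r} used by more than one node",
                    node_id))
            seen.add(node_id)

    for node in list(layout.metabolite_nodes.values()) + \
            list(layout.reaction_nodes.values()):
        if node.fixed and node.position is None:
            violations.append(Violation(
                "fixed_without_position",
                f"node {node.id!r} is fixed but has no position", node.id))

    seen_edges: set[Edge] = set()
    for edge in layout.edges:
        for endpoint in (edge.reaction_id, edge.metabolite_id):
            if endpoint not in layout.metabolite_nodes \
                    and endpoint not in layout.reaction_nodes:
                violations.append(Violation(
                    "dangling_edge",
                    f"edge {edge} references missing node {endpoint!r}",
                    endpoint))
        r_ok = edge.reaction_id in layout.reaction_nodes
        m_ok = edge.metabolite_id in layout.metabolite_nodes
        if not (r_ok and m_ok):
            # Only a bipartiteness problem when both endpoints exist but are
            # of the wrong class; missing endpoints were reported above.
            wrong_r = edge.reaction_id in layout.metabolite_nodes
            wrong_m = edge.metabolite_id in layout.reaction_nodes
            if wrong_r or wrong_m:
                violations.append(Violation(
                    "not_bipartite",
                    f"edge {edge} does not connect a reaction to a metabolite",
                    repr(edge)))
        if edge in seen_edges:
            violations.append(Violation(
                "duplicate_edge", f"duplicate edge {edge}", repr(edge)))
        seen_edges.add(edge)

    for info in layout.info_nodes.values():
        if info.reaction_id not in layout.reaction_nodes:
            violations.append(Violation(
                "bad_info_ref",
                f"info node {info.id!r} annotates missing reaction "
                f"{info.reaction_id!r}", info.id))
    return violations


# ---------------------------------------------------------------------------
# editing operations


def _require_metabolite(layout: MetabolicLayout, node_id: str) -> MetaboliteNode:
    if node_id in layout.reaction_nodes or node_id in layout.info_nodes:
        raise WrongNodeKindError(f"{node_id!r} is not a metabolite node")
    try:
        return layout.metabolite_nodes[node_id]
    except KeyError:
        raise NodeNotFoundError(f"no node {node_id!r}") from None


def _require_reaction(layout: MetabolicLayout, node_id: str) -> ReactionNode:
    if node_id in layout.metabolite_nodes or node_id in layout.info_nodes:
        raise WrongNodeKindError(f"{node_id!r} is not a reaction node")
    try:
        return layout.reaction_nodes[node_id]
    except KeyError:
        raise NodeNotFoundError(f"no node {node_id!r}") from None


def split_metabolite_node(layout: MetabolicLayout,
                          node_id: str) -> MetabolicLayout:
    """Replicate a metabolite into one node per distinct incident reaction.

    Each replica inherits the label, model ids and kind of the original and
    keeps exactly the edges linking it to its one reaction.  Replica ids are
    ``<original>__k`` with k assigned in sorted order of the neighbor
    reaction ids.  A metabolite attached to a single reaction is returned
    unchanged (degree-1 split is a no-op, so batch scripts are idempotent).
    """
    node = _require_metabolite(layout, node_id)
    incident = [e for e in layout.edges if e.metabolite_id == node_id]
    reactions = sorted({e.reaction_id for e in incident})
    if len(reactions) <= 1:
        return layout.copy()

    out = layout.copy()
    del out.metabolite_nodes[node_id]
    out.edges = [e for e in out.edges if e.metabolite_id != node_id]
    for k, reaction_id in enumerate(reactions, start=1):
        replica_id = f"{node_id}__{k}"
        if replica_id in out.node_ids():
            replica_id = out.fresh_id(node_id)
        out.add_metabolite(MetaboliteNode(
            id=replica_id, label=node.label, model_ids=list(node.model_ids),
            kind=node.kind, position=node.position, fixed=node.fixed))
        for e in incident:
            if e.reaction_id == reaction_id:
                out.add_edge(reaction_id, replica_id, e.role)
    return out


def merge_metabolite_nodes(layout: MetabolicLayout,
                           node_ids: Sequence[str]) -> MetabolicLayout:
    """Merge metabolite nodes that represent the same compound.

    "Same compound" is taken strictly: identical model-id sets and identical
    kind.  The lexicographically lowest id survives, inherits the union of
    incident edges (duplicates collapsed) and sits at the centroid of the
    merged nodes' positions (positionless nodes are ignored for the
    centroid).
    """
    if len(node_ids) < 2:
        raise ValueError("merge needs at least two metabolite nodes")
    nodes = [_require_metabolite(layout, i) for i in node_ids]
    ref = nodes[0]
    for other in nodes[1:]:
        if set(other.model_ids) != set(ref.model_ids):
            raise SameCompoundViolation(
                f"{other.id!r} and {ref.id!r} have different model ids")
        if other.kind != ref.kind:
            raise SameCompoundViolation(
                f"{other.id!r} and {ref.id!r} have different kinds")

    survivor_id = min(node_ids)
    merged = set(node_ids)
    positions = [n.position for n in nodes if n.position is not None]
    centroid = None
    if positions:
        centroid = (sum(p[0] for p in positions) / len(positions),
                    sum(p[1] for p in positions) / len(positions))

    out = layout.copy()
    for node_id in merged - {survivor_id}:
        del out.metabolite_nodes[node_id]
    survivor = out.metabolite_nodes[survivor_id]
    survivor.position = centroid
    if centroid is None:
        survivor.fixed = False

    new_edges: list[Edge] = []
    seen: set[Edge] = set()
    for e in out.edges:
        if e.metabolite_id in merged:
            e = Edge(e.reaction_id, survivor_id, e.role)
        if e not in seen:
            seen.add(e)
            new_edges.append(e)
    out.edges = new_edges
    return out


def replicate_reaction_node(layout: MetabolicLayout, node_id: str,
                            n: int) -> MetabolicLayout:
    """Duplicate a reaction node into ``n`` copies total, each connected to
    the same metabolite set with the same roles and reversibility."""
    node = _require_reaction(layout, node_id)
    if n < 2:
        raise ValueError("replication count must be at least 2")
    incident = [e for e in layout.edges if e.reaction_id == node_id]
    out = layout.copy()
    for _ in range(n - 1):
        replica_id = out.fresh_id(node_id)
        out.add_reaction(ReactionNode(
            id=replica_id, label=node.label, model_ids=list(node.model_ids),
            reversible=node.reversible, position=node.position,
            fixed=node.fixed))
        for e in incident:
            out.add_edge(replica_id, e.metabolite_id, e.role)
    return out


def _neighbor_signature(layout: MetabolicLayout,
                        reaction_id: str) -> tuple[tuple[str, str], ...]:
    return tuple(sorted((e.metabolite_id, e.role.value)
                        for e in layout.edges
                        if e.reaction_id == reaction_id))


def merge_reaction_nodes(layout: MetabolicLayout,
                         node_ids: Sequence[str]) -> MetabolicLayout:
    """Merge reaction nodes that are exactly the same: identical
    (metabolite, role) edge sets and identical reversibility.  The surviving
    node takes the union of the model-id lists."""
    if len(node_ids) < 2:
        raise ValueError("merge needs at least two reaction nodes")
    nodes = [_require_reaction(layout, i) for i in node_ids]
    ref = nodes[0]
    ref_sig = _neighbor_signature(layout, ref.id)
    for other in nodes[1:]:
        if other.reversible != ref.reversible:
            raise MergeIllegalError(
                f"{other.id!r} and {ref.id!r} differ in reversibility")
        sig = _neighbor_signature(layout, other.id)
        if sig != ref_sig:
            mismatch = (set(sig) ^ set(ref_sig))
            first = sorted(mismatch)[0] if mismatch else sig
            raise MergeIllegalError(
                f"{other.id!r} and {ref.id!r} differ in neighbors/roles "
                f"(first mismatch: {first})")

    survivor_id = min(node_ids)
    merged = set(node_ids)
    out = layout.copy()
    model_ids: list[str] = []
    for node_id in sorted(merged):
        for mid in layout.reaction_nodes[node_id].model_ids:
            if mid not in model_ids:
                model_ids.append(mid)
    for node_id in merged - {survivor_id}:
        del out.reaction_nodes[node_id]
    out.reaction_nodes[survivor_id].model_ids = model_ids

    new_edges: list[Edge] = []
    seen: set[Edge] = set()
    for e in out.edges:
        if e.reaction_id in merged:
            e = Edge(survivor_id, e.metabolite_id, e.role)
        if e not in seen:
            seen.add(e)
            new_edges.append(e)
    out.edges = new_edges
    for info in out.info_nodes.values():
        if info.reaction_id in merged:
            info.reaction_id = survivor_id
    return out


def set_metabolite_kind(layout: MetabolicLayout, node_id: str,
                        kind: MetaboliteKind | str) -> MetabolicLayout:
    _require_metabolite(layout, node_id)
    if isinstance(kind, str):
        kind = MetaboliteKind(kind)
    out = layout.copy()
    out.metabolite_nodes[node_id].kind = kind
    return out


def set_fixed(layout: MetabolicLayout, node_id: str,
              fixed: bool) -> MetabolicLayout:
    """Pin or release a node.  Fixing a positionless node assigns (0, 0).
    Unfixing keeps the stored coordinates (they seed the next layout run);
    it only makes the node movable again."""
    out = layout.copy()
    node = out.metabolite_nodes.get(node_id) or out.reaction_nodes.get(node_id)
    if node is None:
        raise NodeNotFoundError(f"no node {node_id!r}")
    if fixed and node.position is None:
        node.position = (0.0, 0.0)
    node.fixed = fixed
    return out


def fix_by_kind(layout: MetabolicLayout, node_kind: str,
                fixed: bool) -> MetabolicLayout:
    """Fix/unfix all reaction or all metabolite nodes at once.
    ``node_kind`` is ``"reaction"`` or ``"metabolite"``."""
    if node_kind not in ("reaction", "metabolite"):
        raise ValueError("node_kind must be 'reaction' or 'metabolite'")
    out = layout.copy()
    nodes = (out.reaction_nodes if node_kind == "reaction"
             else out.metabolite_nodes).values()
    for node in nodes:
        if fixed and node.position is None:
            node.position = (0.0, 0.0)
        node.fixed = fixed
    return out


# ---------------------------------------------------------------------------
# visibility filters


def filter_by_kind(layout: MetabolicLayout, selector: str) -> VisibilityFilter:
    """Build a hide-filter from a node-type selector: one of
    ``currency_metabolites``, ``all_metabolites``, ``reactions``."""
    if selector == "currency_metabolites":
        hidden = {n.id for n in layout.metabolite_nodes.values()
                  if n.kind is MetaboliteKind.CURRENCY}
    elif selector == "all_metabolites":
        hidden = set(layout.metabolite_nodes)
    elif selector == "reactions":
        hidden = set(layout.reaction_nodes)
    else:
        raise ValueError(f"unknown selector {selector!r}")
    return VisibilityFilter(name=f"hide {selector}", hidden_node_ids=hidden)


def filter_by_reaction_ids(layout: MetabolicLayout,
                           ids: Iterable[str]) -> VisibilityFilter:
    """Hide reactions named by layout node id or by model reaction id.
    Unknown ids are ignored but listed in the filter's metadata."""
    hidden: set[str] = set()
    unknown: list[str] = []
    by_model: dict[str, set[str]] = {}
    for node in layout.reaction_nodes.values():
        for mid in node.model_ids:
            by_model.setdefault(mid, set()).add(node.id)
    for ident in ids:
        if ident in layout.reaction_nodes:
            hidden.add(ident)
        elif ident in by_model:
            hidden |= by_model[ident]
        else:
            unknown.append(ident)
    return VisibilityFilter(name="hide reactions by id",
                            hidden_node_ids=hidden,
                            metadata={"unknown_ids": unknown})


def visible_node_ids(layout: MetabolicLayout,
                     filters: Sequence[VisibilityFilter]) -> set[str]:
    """Node ids that survive the given hide-filters.  Hiding a node also
    hides its attached info nodes; incident edges are dropped by the
    renderer when either endpoint is hidden."""
    hidden: set[str] = set()
    for f in filters:
        hidden |= f.hidden_node_ids
    out = layout.node_ids() - hidden
    for info in layout.info_nodes.values():
        if info.reaction_id in hidden:
            out.discard(info.id)
    return out
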