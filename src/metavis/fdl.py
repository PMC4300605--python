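"""Coordinate computation: spring-embedder layout with pinned nodes, and
de-novo layout generation from a model's reactions or pathways.

The force-directed layout (FDL) is a Fruchterman-Reingold-style spring
embedder extended with fixed-node support: pinned nodes act as anchors that
exert forces but never move.  Unpinned nodes feel

* spring attraction along every incident edge toward ``spring_length``,
* pairwise inverse-square repulsion, and
* a weak gravity pull toward the anchor centroid (keeps disconnected
  components from drifting away),

with per-step displacement capped by a linearly cooling temperature.

Determinism and id-independence: positionless nodes are initialized from a
random stream seeded by (seed, structural hash of the node), where the
structural hash is a Weisfeiler-Lehman subgraph hash over node classes and
pinned coordinates.  Forces are accumulated in structural-hash order.  The
resulting coordinates therefore depend on the graph's structure and the
seed, not on how node ids happen to sort; relabeling the nodes of an
automorphism-free layout relocates nobody.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .layout import (Edge, EdgeRole, MetaboliteKind, MetaboliteNode,
                     MetabolicLayout, ReactionNode)


@dataclass
class FdlParams:
    iterations: int = 500
    spring_length: float = 80.0
    spring_coefficient: float = 0.05
    repulsion_constant: float = 40000.0
    seed: int = 0
    movable_gravity: float = 0.01

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if self.spring_length <= 0 or self.spring_coefficient <= 0:
            raise ValueError("spring parameters must be positive")
        if self.repulsion_constant < 0 or self.movable_gravity < 0:
            raise ValueError("force constants must be non-negative")


@dataclass
class ModelReaction:
    id: str
    name: str = ""
    reversible: bool = False
    substrates: list[tuple[str, float]] = field(default_factory=list)
    products: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class ModelMetabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class ModelDigest:
    """The slice of a genome-scale model the layout machinery needs:
    reactions with stoichiometric participants, metabolites, optional
    pathway (subsystem) membership, and gene ids for bookkeeping."""

    reactions: dict[str, ModelReaction] = field(default_factory=dict)
    metabolites: dict[str, ModelMetabolite] = field(default_factory=dict)
    pathways: dict[str, list[str]] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)
    name: str = "model"


class SelectionError(ValueError):
    """Unknown reaction or pathway names in a layout-generation request."""

    def __init__(self, offenders: Sequence[str]):
        super().__init__(f"unknown reactions/pathways: {sorted(offenders)}")
        self.offenders = sorted(offenders)


# ---------------------------------------------------------------------------
# force-directed layout


def _wl_graph(layout: MetabolicLayout) -> nx.Graph:
    g = nx.Graph()
    for node in layout.metabolite_nodes.values():
        pin = f"@{node.position}" if node.fixed else ""
        g.add_node(node.id, cls=f"met:{node.kind.value}{pin}")
    for node in layout.reaction_nodes.values():
        pin = f"@{node.position}" if node.fixed else ""
        g.add_node(node.id, cls=f"rxn:{node.reversible}{pin}")
    for e in layout.edges:
        if e.reaction_id in g and e.metabolite_id in g:
            g.add_edge(e.reaction_id, e.metabolite_id, role=e.role.value)
    return g


def _node_seed(seed: int, wl_hash: str, orbit_rank: int) -> int:
    digest = hashlib.sha256(
        f"{seed}|{wl_hash}|{orbit_rank}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def run_fdl(layout: MetabolicLayout, params: FdlParams | None = None
            ) -> MetabolicLayout:
    """Run the spring embedder; returns a copy with every reaction and
    metabolite node positioned.  Fixed nodes keep their input coordinates
    bit-identically.  Deterministic for a given (layout, params)."""
    params = params or FdlParams()
    out = layout.copy()
    nodes = {**out.metabolite_nodes, **out.reaction_nodes}
    if not nodes:
        return out

    hashes = nx.weisfeiler_lehman_subgraph_hashes(
        _wl_graph(out), node_attr="cls", edge_attr="role", iterations=3)
    final_hash = {nid: h[-1] for nid, h in hashes.items()}
    # Structural ordering: invariant under id relabeling up to graph
    # automorphism, where any order within an orbit gives an equivalent
    # drawing.
    order = sorted(nodes, key=lambda nid: (final_hash[nid], nid))
    index = {nid: i for i, nid in enumerate(order)}
    n = len(order)

    orbit_rank: dict[str, int] = {}
    by_hash: dict[str, int] = {}
    for nid in order:
        h = final_hash[nid]
        orbit_rank[nid] = by_hash.get(h, 0)
        by_hash[h] = orbit_rank[nid] + 1

    fixed_mask = np.zeros(n, dtype=bool)
    pos = np.zeros((n, 2))
    anchors = [np.asarray(nodes[nid].position, dtype=float)
               for nid in order if nodes[nid].fixed]
    center = (np.mean(anchors, axis=0) if anchors else np.zeros(2))

    for nid in order:
        i = index[nid]
        node = nodes[nid]
        if node.fixed:
            fixed_mask[i] = True
            pos[i] = node.position
        elif node.position is not None:
            pos[i] = node.position
        else:
            rng = np.random.default_rng(
                _node_seed(params.seed, final_hash[nid], orbit_rank[nid]))
            r = params.spring_length * np.sqrt(rng.uniform(0.02, 1.0))
            theta = rng.uniform(0.0, 2 * np.pi)
            pos[i] = center + [r * np.cos(theta), r * np.sin(theta)]

    edge_idx = np.array(
        [[index[e.reaction_id], index[e.metabolite_id]]
         for e in out.edges
         if e.reaction_id in index and e.metabolite_id in index],
        dtype=int).reshape(-1, 2)

    movable = ~fixed_mask
    if movable.any():
        temp0 = 2.0 * params.spring_length
        for step in range(params.iterations):
            force = np.zeros((n, 2))
            # pairwise repulsion
            if params.repulsion_constant > 0:
                delta = pos[:, None, :] - pos[None, :, :]
                dist2 = np.einsum("ijk,ijk->ij", delta, delta)
                np.fill_diagonal(dist2, np.inf)
                dist2 = np.maximum(dist2, 1e-4)
                rep = params.repulsion_constant / dist2
                force += np.einsum(
                    "ij,ijk->ik", rep / np.sqrt(dist2), delta)
            # spring attraction along edges
            if len(edge_idx):
                d = pos[edge_idx[:, 1]] - pos[edge_idx[:, 0]]
                dist = np.maximum(np.linalg.norm(d, axis=1), 1e-6)
                f = (params.spring_coefficient
                     * (dist - params.spring_length))[:, None] * d / dist[:, None]
                np.add.at(force, edge_idx[:, 0], f)
                np.add.at(force, edge_idx[:, 1], -f)
            # gravity toward the anchor centroid
            force += params.movable_gravity * (center - pos)

            temp = temp0 * (1.0 - step / params.iterations)
            mag = np.maximum(np.linalg.norm(force, axis=1), 1e-12)
            step_len = np.minimum(mag, temp)
            disp = force / mag[:, None] * step_len[:, None]
            disp[fixed_mask] = 0.0
            pos += disp

    for nid in order:
        node = nodes[nid]
        if not node.fixed:
            node.position = (float(pos[index[nid], 0]),
                             float(pos[index[nid], 1]))
    return out


# ---------------------------------------------------------------------------
# pathway layout generation

#: hub compounds treated as currency by default, matched after lower-casing
#: and stripping an SBML "M_" prefix and a trailing compartment suffix.
DEFAULT_CURRENCY = ("h", "h2o", "atp", "adp", "pi", "nad", "nadh",
                    "nadp", "nadph", "co2", "coa")
DEFAULT_CURRENCY_DEGREE = 8


def _canonical_met(metabolite_id: str) -> str:
    ident = metabolite_id.lower()
    if ident.startswith("m_"):
        ident = ident[2:]
    parts = ident.rsplit("_", 1)
    if len(parts) == 2 and 1 <= len(parts[1]) <= 2 and parts[1].isalnum():
        ident = parts[0]
    return ident


def generate_pathway_layout(model: ModelDigest,
                            selection: Sequence[str],
                            basis: Optional[MetabolicLayout] = None,
                            currency_ids: Optional[Sequence[str]] = None,
                            currency_degree_threshold: Optional[int] = None,
                            name: Optional[str] = None) -> MetabolicLayout:
    """Build a layout from a list of reaction ids and/or pathway names.

    Pathway names expand to their member reactions.  Regular metabolites
    become shared nodes; metabolites in ``currency_ids`` (default: common
    cofactors) or whose degree within the selection exceeds
    ``currency_degree_threshold`` (default 8) are typed currency and
    instantiated as one replica per reaction.  With a ``basis`` layout the
    basis is extended: reactions already present (matched by model id) are
    reused and only new ones appended.  All newly created nodes are unfixed
    and positionless; run :func:`run_fdl` to place them.
    """
    offenders = [s for s in selection
                 if s not in model.reactions and s not in model.pathways]
    if offenders:
        raise SelectionError(offenders)

    reaction_ids: list[str] = []
    for s in selection:
        members = model.pathways[s] if s in model.pathways else [s]
        for rid in members:
            if rid not in model.reactions:
                raise SelectionError([rid])
            if rid not in reaction_ids:
                reaction_ids.append(rid)

    currency = {_canonical_met(c) for c in
                (currency_ids if currency_ids is not None else DEFAULT_CURRENCY)}
    threshold = (currency_degree_threshold
                 if currency_degree_threshold is not None
                 else DEFAULT_CURRENCY_DEGREE)

    out = basis.copy() if basis is not None else MetabolicLayout(
        name=name or f"{model.name} pathway layout")
    existing_rxn_models = {mid for node in out.reaction_nodes.values()
                           for mid in node.model_ids}
    met_node_by_model: dict[str, str] = {}
    for node in out.metabolite_nodes.values():
        if node.kind is MetaboliteKind.REGULAR:
            for mid in node.model_ids:
                met_node_by_model.setdefault(mid, node.id)

    new_ids = [rid for rid in reaction_ids if rid not in existing_rxn_models]

    # degree of each metabolite within the *new* selection
    degree: dict[str, int] = {}
    for rid in new_ids:
        rxn = model.reactions[rid]
        touched = {m for m, _ in rxn.substrates} | {m for m, _ in rxn.products}
        for m in touched:
            degree[m] = degree.get(m, 0) + 1

    def is_currency(met_id: str) -> bool:
        return (_canonical_met(met_id) in currency
                or degree.get(met_id, 0) > threshold)

    for rid in new_ids:
        rxn = model.reactions[rid]
        rnode_id = rid if rid not in out.node_ids() else out.fresh_id(rid)
        out.add_reaction(ReactionNode(
            id=rnode_id, label=rxn.name or rid, model_ids=[rid],
            reversible=rxn.reversible))
        for participants, role in ((rxn.substrates, EdgeRole.SUBSTRATE),
                                   (rxn.products, EdgeRole.PRODUCT)):
            for met_id, _coef in participants:
                meta = model.metabolites.get(met_id)
                label = meta.name if meta and meta.name else met_id
                if is_currency(met_id):
                    # one replica per reaction participation
                    replica_id = out.fresh_id(met_id)
                    out.add_metabolite(MetaboliteNode(
                        id=replica_id, label=label, model_ids=[met_id],
                        kind=MetaboliteKind.CURRENCY))
                    out.add_edge(rnode_id, replica_id, role)
                else:
                    node_id = met_node_by_model.get(met_id)
                    if node_id is None:
                        node_id = (met_id if met_id not in out.node_ids()
                                   else out.fresh_id(met_id))
                        out.add_metabolite(MetaboliteNode(
                            id=node_id, label=label, model_ids=[met_id]))
                        met_node_by_model[met_id] = node_id
                    out.add_edge(rnode_id, node_id, role)
    return out
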