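"""KGML (KEGG Markup Language) pathway reader.

Each ``<reaction>`` element becomes a reaction node; its KEGG names
(whitespace-separated, e.g. ``"rn:R01068 rn:R01070"``) become the node's
model ids and the ``type`` attribute sets reversibility.  Substrates and
products are resolved through the compound ``<entry>`` elements; entries
with ``<graphics x=".." y=".."/>`` yield fixed nodes at KEGG pixel
coordinates, which match the y-down canvas directly.  Reaction positions
come from the gene/ortholog entry sharing the reaction's id, when present.
Read-only: KGML is an import format.
"""

from __future__ import annotations

from lxml import etree

from ..layout import (EdgeRole, MetaboliteNode, MetabolicLayout, ReactionNode)
from .report import FormatError, FormatReport


def read_kgml(stream) -> tuple[MetabolicLayout, FormatReport]:
    try:
        root = etree.parse(stream).getroot()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc
    if root.tag != "pathway":
        raise FormatError(f"expected <pathway> root, found <{root.tag}>")
    report = FormatReport("kgml")
    layout = MetabolicLayout(name=root.get("title") or root.get("name")
                             or "kgml pathway")

    entries: dict[str, dict] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        if eid is None:
            continue
        graphics = entry.find("graphics")
        position = None
        label = entry.get("name", eid)
        if graphics is not None:
            if graphics.get("name"):
                label = graphics.get("name").split(",")[0].strip()
            try:
                position = (float(graphics.get("x")), float(graphics.get("y")))
            except (TypeError, ValueError):
                position = None
        entries[eid] = {"type": entry.get("type"),
                        "name": entry.get("name", ""),
                        "label": label, "position": position}

    def metabolite_node(entry_id: str) -> str | None:
        node_id = f"cpd{entry_id}"
        if node_id in layout.metabolite_nodes:
            return node_id
        info = entries.get(entry_id)
        if info is None or info["type"] != "compound":
            return None
        layout.add_metabolite(MetaboliteNode(
            id=node_id, label=info["label"],
            model_ids=info["name"].split(),
            position=info["position"],
            fixed=info["position"] is not None))
        return node_id

    n_reactions = 0
    for reaction in root.findall("reaction"):
        rid = reaction.get("id") or reaction.get("name", "")
        names = (reaction.get("name") or "").split()
        node_id = f"rxn{rid}" if rid else f"rxn{n_reactions}"
        if node_id in layout.node_ids():
            node_id = layout.fresh_id(node_id)
        owner = entries.get(reaction.get("id", ""))
        position = owner["position"] if owner else None
        layout.add_reaction(ReactionNode(
            id=node_id,
            label=(names[0] if names else node_id),
            model_ids=names,
            reversible=reaction.get("type") == "reversible",
            position=position, fixed=position is not None))
        n_reactions += 1
        for el, role in ((reaction.findall("substrate"), EdgeRole.SUBSTRATE),
                         (reaction.findall("product"), EdgeRole.PRODUCT)):
            for participant in el:
                met = metabolite_node(participant.get("id", ""))
                if met is None:
                    report.warn(
                        f"reaction {node_id}: participant "
                        f"{participant.get('id')!r} has no compound entry, "
                        "skipped")
                    continue
                layout.add_edge(node_id, met, role)

    if n_reactions == 0:
        report.warn("KGML file contains no <reaction> elements "
                    "(relation-only pathways carry no metabolic structure)")
    report.counts = {"nodes": len(layout.node_ids()),
                     "edges": len(layout.edges),
                     "reactions": len(layout.reaction_nodes)}
    return layout, report
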