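"""XGMML layout reader/writer.

XGMML is a generic XML graph format with no metabolic vocabulary, so a small
documented dialect carries the layout semantics (Cytoscape still opens the
files):

* node ``<att name="nodetype" value="reaction|metabolite|currency|info"/>``
  (a node without it is read as a regular metabolite, with a warning);
* ``<att name="model_ids" value="a,b"/>`` comma-joined model identifiers;
* ``<att name="reversible" value="true|false"/>`` on reaction nodes;
* ``<att name="fixed" value="true|false"/>``;
* ``<graphics x=".." y=".."/>`` for coordinates (y down, as in SVG);
* info nodes carry ``<att name="text">`` and ``<att name="reaction_id">``;
* edges run reaction→metabolite with ``<att name="role"
  value="substrate|product"/>``.

Round-trips are lossless for ids, labels, kinds, reversibility, positions,
fixed flags and model-id lists.  Foreign attributes are tolerated on read.
"""

from __future__ import annotations

from typing import BinaryIO, TextIO, Union

from lxml import etree

from ..layout import (EdgeRole, InfoNode, MetaboliteKind, MetaboliteNode,
                      MetabolicLayout, ReactionNode)
from .report import FormatError, FormatReport

XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def _parse(stream) -> etree._Element:
    try:
        tree = etree.parse(stream)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc
    return tree.getroot()


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _atts(node: etree._Element) -> dict[str, str]:
    out = {}
    for child in node:
        if _local(child.tag) == "att" and child.get("name") is not None:
            out[child.get("name")] = child.get("value", "")
    return out


def read_xgmml(stream) -> tuple[MetabolicLayout, FormatReport]:
    root = _parse(stream)
    if _local(root.tag) != "graph":
        raise FormatError(f"expected <graph> root, found <{_local(root.tag)}>")
    report = FormatReport("xgmml")
    layout = MetabolicLayout(name=root.get("label") or "layout")

    pending_info: list[tuple[str, str, str]] = []
    for el in root:
        if _local(el.tag) != "node":
            continue
        node_id = el.get("id")
        if not node_id:
            report.warn("node without id skipped")
            continue
        label = el.get("label") or node_id
        atts = _atts(el)
        position = None
        fixed = atts.get("fixed", "").lower() == "true"
        for child in el:
            if _local(child.tag) == "graphics" \
                    and child.get("x") is not None and child.get("y") is not None:
                try:
                    position = (float(child.get("x")), float(child.get("y")))
                except ValueError:
                    report.warn(f"node {node_id}: non-numeric coordinates")
        if position is None:
            fixed = False
        model_ids = [m for m in atts.get("model_ids", "").split(",") if m]
        nodetype = atts.get("nodetype")
        if nodetype is None:
            report.warn(f"node {node_id}: no nodetype att, assuming metabolite")
            nodetype = "metabolite"
        if nodetype == "reaction":
            layout.add_reaction(ReactionNode(
                id=node_id, label=label, model_ids=model_ids,
                reversible=atts.get("reversible", "").lower() == "true",
                position=position, fixed=fixed))
        elif nodetype == "info":
            pending_info.append((node_id, atts.get("text", ""),
                                 atts.get("reaction_id", "")))
        else:
            kind = (MetaboliteKind.CURRENCY if nodetype == "currency"
                    else MetaboliteKind.REGULAR)
            layout.add_metabolite(MetaboliteNode(
                id=node_id, label=label, model_ids=model_ids, kind=kind,
                position=position, fixed=fixed))

    for node_id, text, reaction_id in pending_info:
        if reaction_id in layout.reaction_nodes:
            layout.add_info(InfoNode(node_id, text, reaction_id))
        else:
            report.warn(f"info node {node_id}: unknown reaction "
                        f"{reaction_id!r}, dropped")

    for el in root:
        if _local(el.tag) != "edge":
            continue
        source, target = el.get("source"), el.get("target")
        atts = _atts(el)
        role = atts.get("role", "substrate")
        # orientation tolerance: accept metabolite→reaction too
        if source in layout.metabolite_nodes and target in layout.reaction_nodes:
            source, target = target, source
        if source not in layout.reaction_nodes \
                or target not in layout.metabolite_nodes:
            report.warn(f"edge {source}->{target}: unresolved endpoints, "
                        "dropped")
            continue
        try:
            layout.add_edge(source, target, EdgeRole(role))
        except ValueError:
            report.warn(f"edge {source}->{target}: unknown role {role!r}, "
                        "read as substrate")
            layout.add_edge(source, target, EdgeRole.SUBSTRATE)

    report.counts = {"nodes": len(layout.node_ids()),
                     "edges": len(layout.edges),
                     "reactions": len(layout.reaction_nodes)}
    return layout, report


def _att(parent: etree._Element, name: str, value: str, type_: str = "string"):
    etree.SubElement(parent, f"{{{XGMML_NS}}}att",
                     name=name, value=value, type=type_)


def write_xgmml(layout: MetabolicLayout, stream: BinaryIO) -> None:
    root = etree.Element(f"{{{XGMML_NS}}}graph",
                         nsmap={None: XGMML_NS},
                         label=layout.name, directed="1")
    for node in sorted(layout.metabolite_nodes.values(), key=lambda n: n.id):
        el = etree.SubElement(root, f"{{{XGMML_NS}}}node",
                              id=node.id, label=node.label)
        _att(el, "nodetype",
             "currency" if node.kind is MetaboliteKind.CURRENCY
             else "metabolite")
        _att(el, "model_ids", ",".join(node.model_ids))
        _att(el, "fixed", "true" if node.fixed else "false")
        if node.position is not None:
            etree.SubElement(el, f"{{{XGMML_NS}}}graphics",
                             x=repr(node.position[0]), y=repr(node.position[1]))
    for node in sorted(layout.reaction_nodes.values(), key=lambda n: n.id):
        el = etree.SubElement(root, f"{{{XGMML_NS}}}node",
                              id=node.id, label=node.label)
        _att(el, "nodetype", "reaction")
        _att(el, "model_ids", ",".join(node.model_ids))
        _att(el, "reversible", "true" if node.reversible else "false")
        _att(el, "fixed", "true" if node.fixed else "false")
        if node.position is not None:
            etree.SubElement(el, f"{{{XGMML_NS}}}graphics",
                             x=repr(node.position[0]), y=repr(node.position[1]))
    for node in sorted(layout.info_nodes.values(), key=lambda n: n.id):
        el = etree.SubElement(root, f"{{{XGMML_NS}}}node",
                              id=node.id, label=node.text)
        _att(el, "nodetype", "info")
        _att(el, "text", node.text)
        _att(el, "reaction_id", node.reaction_id)
    for edge in layout.edges:
        el = etree.SubElement(root, f"{{{XGMML_NS}}}edge",
                              source=edge.reaction_id,
                              target=edge.metabolite_id)
        _att(el, "role", edge.role.value)

    etree.ElementTree(root).write(stream, xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)
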