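"""SBGN-ML Process Description reader/writer.

Mapping between the layout model and PD glyphs:

* reaction node → ``process`` glyph with two ports (``<id>.1`` for the
  substrate side, ``<id>.2`` for the product side);
* regular metabolite → ``simple chemical`` glyph; currency metabolite →
  ``simple chemical`` with a clone marker;
* substrate edge → ``consumption`` arc (metabolite → port .1) for
  irreversible reactions; product edge → ``production`` arc (port .2 →
  metabolite).  Reversible reactions are written with production arcs on
  *both* sides, per PD convention; on read the substrate/product role is
  recovered from the port the arc attaches to (.1 vs .2);
* glyph bbox centers → node positions; glyphs read from file are fixed;
* fields with no native PD slot (model-id lists, the fixed flag) ride in
  the glyph ``<extension>`` element, which the SBGN-ML schema allows;
* info nodes → ``annotation`` glyphs with the target reaction id in the
  extension.

Maps in the ER or AF languages are rejected.  Macromolecules and other
out-of-scope glyph classes are skipped with a warning.
"""

from __future__ import annotations

from lxml import etree

from ..layout import (EdgeRole, InfoNode, MetaboliteKind, MetaboliteNode,
                      MetabolicLayout, ReactionNode)
from .report import FormatError, FormatReport

SBGN_NS = "http://sbgn.org/libsbgn/0.2"
EXT_NS = "https://metavis.invalid/sbgn-extension"

_GLYPH_W = 40.0
_GLYPH_H = 40.0
_PROC_W = 20.0

_METAB_CLASSES = {"simple chemical", "unspecified entity"}


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def read_sbgnml_pd(stream) -> tuple[MetabolicLayout, FormatReport]:
    try:
        root = etree.parse(stream).getroot()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc
    maps = [el for el in root.iter() if _local(el.tag) == "map"]
    if not maps:
        raise FormatError("no <map> element found")
    sbgn_map = maps[0]
    language = sbgn_map.get("language", "")
    if "process description" not in language.lower():
        raise FormatError(
            f"unsupported SBGN language {language!r}; only Process "
            "Description maps are readable")

    report = FormatReport("sbgnml_pd")
    layout = MetabolicLayout(name=sbgn_map.get("id") or "sbgn layout")
    port_owner: dict[str, str] = {}       # port id -> process glyph id
    port_side: dict[str, EdgeRole] = {}   # port id -> substrate/product side
    pending_info: list[tuple[str, str, str]] = []

    for glyph in sbgn_map:
        if _local(glyph.tag) != "glyph":
            continue
        cls = glyph.get("class", "")
        gid = glyph.get("id")
        if not gid:
            report.warn("glyph without id skipped")
            continue
        label = gid
        position = None
        cloned = False
        had_ext = False
        ext: dict[str, str] = {}
        for child in glyph:
            tag = _local(child.tag)
            if tag == "label" and child.get("text"):
                label = child.get("text")
            elif tag == "bbox":
                try:
                    x = float(child.get("x")) + float(child.get("w", 0)) / 2
                    y = float(child.get("y")) + float(child.get("h", 0)) / 2
                    position = (x, y)
                except (TypeError, ValueError):
                    report.warn(f"glyph {gid}: bad bbox")
            elif tag == "clone":
                cloned = True
            elif tag == "extension":
                for info in child.iter():
                    if _local(info.tag) == "metavis":
                        had_ext = True
                        ext.update(info.attrib)
            elif tag == "port":
                pid = child.get("id", "")
                port_owner[pid] = gid
                port_side[pid] = (EdgeRole.SUBSTRATE if pid.endswith(".1")
                                  else EdgeRole.PRODUCT)
        model_ids = [m for m in ext.get("model_ids", "").split(",") if m]
        if had_ext:
            # our own files: the extension is authoritative, including the
            # absence of coordinates (the bbox is then just a placeholder)
            if ext.get("x") is not None and ext.get("y") is not None:
                position = (float(ext["x"]), float(ext["y"]))
            else:
                position = None
        fixed = ext.get("fixed", "true" if position else "false") == "true"
        if position is None:
            fixed = False

        if cls == "process":
            layout.add_reaction(ReactionNode(
                id=gid, label=label, model_ids=model_ids,
                reversible=ext.get("reversible") == "true",
                position=position, fixed=fixed))
        elif cls in _METAB_CLASSES:
            kind = (MetaboliteKind.CURRENCY if cloned
                    or ext.get("kind") == "currency"
                    else MetaboliteKind.REGULAR)
            layout.add_metabolite(MetaboliteNode(
                id=gid, label=label, model_ids=model_ids, kind=kind,
                position=position, fixed=fixed))
        elif cls == "annotation":
            pending_info.append((gid, label, ext.get("reaction_id", "")))
        else:
            report.warn(f"glyph {gid}: class {cls!r} not supported, skipped")

    for gid, text, reaction_id in pending_info:
        if reaction_id in layout.reaction_nodes:
            layout.add_info(InfoNode(gid, text, reaction_id))
        else:
            report.warn(f"annotation {gid}: unknown reaction "
                        f"{reaction_id!r}, dropped")

    def resolve(ref: str) -> tuple[str | None, EdgeRole | None]:
        if ref in port_owner:
            return port_owner[ref], port_side[ref]
        if ref in layout.reaction_nodes or ref in layout.metabolite_nodes:
            return ref, None
        return None, None

    for arc in sbgn_map:
        if _local(arc.tag) != "arc":
            continue
        cls = arc.get("class", "")
        src, src_side = resolve(arc.get("source", ""))
        tgt, tgt_side = resolve(arc.get("target", ""))
        if src is None or tgt is None:
            report.warn(f"arc {arc.get('id')}: unresolved endpoint, dropped")
            continue
        if src in layout.metabolite_nodes and tgt in layout.reaction_nodes:
            metabolite, reaction, side = src, tgt, tgt_side
        elif src in layout.reaction_nodes and tgt in layout.metabolite_nodes:
            metabolite, reaction, side = tgt, src, src_side
        else:
            report.warn(f"arc {arc.get('id')}: not reaction-metabolite, "
                        "dropped")
            continue
        if cls == "consumption":
            role = EdgeRole.SUBSTRATE
        elif cls == "production":
            role = side if side is not None else EdgeRole.PRODUCT
        else:
            report.warn(f"arc {arc.get('id')}: class {cls!r} not supported, "
                        "skipped")
            continue
        layout.add_edge(reaction, metabolite, role)

    report.counts = {"nodes": len(layout.node_ids()),
                     "edges": len(layout.edges),
                     "reactions": len(layout.reaction_nodes)}
    return layout, report


def _bbox(parent, position, w, h):
    x, y = position if position is not None else (0.0, 0.0)
    etree.SubElement(parent, f"{{{SBGN_NS}}}bbox",
                     x=repr(x - w / 2), y=repr(y - h / 2),
                     w=repr(w), h=repr(h))


def _extension(parent, **attrs):
    ext = etree.SubElement(parent, f"{{{SBGN_NS}}}extension")
    etree.SubElement(ext, f"{{{EXT_NS}}}metavis",
                     nsmap={"mv": EXT_NS}, **attrs)


def write_sbgnml_pd(layout: MetabolicLayout, stream) -> None:
    root = etree.Element(f"{{{SBGN_NS}}}sbgn", nsmap={None: SBGN_NS})
    sbgn_map = etree.SubElement(root, f"{{{SBGN_NS}}}map",
                                language="process description",
                                id=layout.name or "map")

    for node in sorted(layout.metabolite_nodes.values(), key=lambda n: n.id):
        glyph = etree.SubElement(sbgn_map, f"{{{SBGN_NS}}}glyph",
                                 id=node.id, **{"class": "simple chemical"})
        etree.SubElement(glyph, f"{{{SBGN_NS}}}label", text=node.label)
        ext: dict[str, str] = {
            "model_ids": ",".join(node.model_ids),
            "fixed": "true" if node.fixed else "false",
            "kind": node.kind.value,
        }
        if node.position is not None:
            ext["x"], ext["y"] = repr(node.position[0]), repr(node.position[1])
        _extension(glyph, **ext)
        _bbox(glyph, node.position, _GLYPH_W, _GLYPH_H)
        if node.kind is MetaboliteKind.CURRENCY:
            etree.SubElement(glyph, f"{{{SBGN_NS}}}clone")

    for node in sorted(layout.reaction_nodes.values(), key=lambda n: n.id):
        glyph = etree.SubElement(sbgn_map, f"{{{SBGN_NS}}}glyph",
                                 id=node.id, **{"class": "process"})
        etree.SubElement(glyph, f"{{{SBGN_NS}}}label", text=node.label)
        ext = {
            "model_ids": ",".join(node.model_ids),
            "fixed": "true" if node.fixed else "false",
            "reversible": "true" if node.reversible else "false",
        }
        if node.position is not None:
            ext["x"], ext["y"] = repr(node.position[0]), repr(node.position[1])
        _extension(glyph, **ext)
        _bbox(glyph, node.position, _PROC_W, _PROC_W)
        x, y = node.position if node.position is not None else (0.0, 0.0)
        for k, dx in ((1, -_PROC_W), (2, _PROC_W)):
            etree.SubElement(glyph, f"{{{SBGN_NS}}}port",
                             id=f"{node.id}.{k}", x=repr(x + dx), y=repr(y))

    for node in sorted(layout.info_nodes.values(), key=lambda n: n.id):
        glyph = etree.SubElement(sbgn_map, f"{{{SBGN_NS}}}glyph",
                                 id=node.id, **{"class": "annotation"})
        etree.SubElement(glyph, f"{{{SBGN_NS}}}label", text=node.text)
        _extension(glyph, reaction_id=node.reaction_id)
        _bbox(glyph, None, _GLYPH_W, _GLYPH_H / 2)

    for i, edge in enumerate(layout.edges):
        reaction = layout.reaction_nodes[edge.reaction_id]
        port = f"{edge.reaction_id}.1" if edge.role is EdgeRole.SUBSTRATE \
            else f"{edge.reaction_id}.2"
        if edge.role is EdgeRole.SUBSTRATE and not reaction.reversible:
            cls, src, tgt = "consumption", edge.metabolite_id, port
        else:
            # product edges always, and both sides of reversible processes,
            # are production arcs pointing at the metabolite
            cls, src, tgt = "production", port, edge.metabolite_id
        arc = etree.SubElement(sbgn_map, f"{{{SBGN_NS}}}arc",
                               id=f"arc{i}", source=src, target=tgt,
                               **{"class": cls})
        etree.SubElement(arc, f"{{{SBGN_NS}}}start", x="0", y="0")
        etree.SubElement(arc, f"{{{SBGN_NS}}}end", x="0", y="0")

    etree.ElementTree(root).write(stream, xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)
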