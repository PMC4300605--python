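"""CellDesigner-SBML layout reader (read-only).

CellDesigner stores its drawing in annotation elements of an SBML file
(namespace ``http://www.sbml.org/2001/ns/celldesigner``).  Each
``speciesAlias`` — one of possibly several visual copies of a species —
becomes a metabolite node positioned at the center of its ``bounds``, so
CellDesigner duplicates arrive as replicas sharing the same model id.
Reactions become reaction nodes; participants connect to the alias named by
the reaction's ``baseReactant``/``baseProduct`` annotations when present,
else to the first alias of the species (with a warning when ambiguous).

SBML input without the CellDesigner namespace falls back to
:func:`~metavis.io.sbml_model.read_sbml_model` followed by
:func:`~metavis.fdl.generate_pathway_layout` over all reactions, with a
warning in the report.
"""

from __future__ import annotations

from lxml import etree

from ..fdl import generate_pathway_layout
from ..layout import (EdgeRole, MetaboliteNode, MetabolicLayout, ReactionNode)
from .report import FormatError, FormatReport
from .sbml_model import read_sbml_model

CD_NS = "http://www.sbml.org/2001/ns/celldesigner"


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def read_cd_sbml(stream) -> tuple[MetabolicLayout, FormatReport]:
    data = stream.read() if hasattr(stream, "read") else stream
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc

    if CD_NS not in data.decode("utf-8", errors="replace"):
        digest, model_report = read_sbml_model(data.decode("utf-8"))
        layout = generate_pathway_layout(digest, list(digest.reactions))
        report = FormatReport("cd_sbml", warnings=list(model_report.warnings))
        report.warn("no CellDesigner annotations found; built layout from "
                    "plain SBML reactions (positions unset)")
        report.counts = {"nodes": len(layout.node_ids()),
                         "edges": len(layout.edges),
                         "reactions": len(layout.reaction_nodes)}
        return layout, report

    report = FormatReport("cd_sbml")
    model_el = next((el for el in root.iter() if _local(el.tag) == "model"),
                    None)
    if model_el is None:
        raise FormatError("no <model> element in SBML document")
    layout = MetabolicLayout(name=model_el.get("id") or "celldesigner layout")

    species_name: dict[str, str] = {}
    for el in root.iter():
        if _local(el.tag) == "species" and el.get("id"):
            species_name[el.get("id")] = el.get("name") or el.get("id")

    aliases_of: dict[str, list[str]] = {}
    for alias in root.iter(f"{{{CD_NS}}}speciesAlias"):
        alias_id = alias.get("id")
        species = alias.get("species")
        if not alias_id or not species:
            report.warn("speciesAlias without id/species skipped")
            continue
        position = None
        bounds = alias.find(f"{{{CD_NS}}}bounds")
        if bounds is not None:
            try:
                x = float(bounds.get("x")) + float(bounds.get("w", 0)) / 2
                y = float(bounds.get("y")) + float(bounds.get("h", 0)) / 2
                position = (x, y)
            except (TypeError, ValueError):
                report.warn(f"alias {alias_id}: bad bounds")
        layout.add_metabolite(MetaboliteNode(
            id=alias_id, label=species_name.get(species, species),
            model_ids=[species], position=position,
            fixed=position is not None))
        aliases_of.setdefault(species, []).append(alias_id)

    for rxn in (el for el in root.iter() if _local(el.tag) == "reaction"):
        rid = rxn.get("id")
        if not rid:
            continue
        node_id = rid if rid not in layout.node_ids() else layout.fresh_id(rid)
        layout.add_reaction(ReactionNode(
            id=node_id, label=rxn.get("name") or rid, model_ids=[rid],
            reversible=rxn.get("reversible", "true").lower() != "false"))

        # alias links from the CellDesigner annotation, if any
        alias_link: dict[str, str] = {}
        for base in rxn.iter(f"{{{CD_NS}}}baseReactant",
                             f"{{{CD_NS}}}baseProduct"):
            if base.get("species") and base.get("alias"):
                alias_link[base.get("species")] = base.get("alias")

        for list_tag, role in (("listOfReactants", EdgeRole.SUBSTRATE),
                               ("listOfProducts", EdgeRole.PRODUCT)):
            list_el = next((el for el in rxn
                            if _local(el.tag) == list_tag), None)
            if list_el is None:
                continue
            for ref in list_el:
                if _local(ref.tag) != "speciesReference":
                    continue
                species = ref.get("species")
                alias_id = alias_link.get(species)
                if alias_id is None:
                    candidates = aliases_of.get(species, [])
                    if not candidates:
                        report.warn(f"reaction {rid}: species {species!r} "
                                    "has no alias, participant skipped")
                        continue
                    if len(candidates) > 1:
                        report.warn(f"reaction {rid}: species {species!r} "
                                    "has several aliases and no base link; "
                                    "using the first")
                    alias_id = candidates[0]
                if alias_id not in layout.metabolite_nodes:
                    report.warn(f"reaction {rid}: alias {alias_id!r} "
                                "unknown, participant skipped")
                    continue
                layout.add_edge(node_id, alias_id, role)

    report.counts = {"nodes": len(layout.node_ids()),
                     "edges": len(layout.edges),
                     "reactions": len(layout.reaction_nodes)}
    return layout, report
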