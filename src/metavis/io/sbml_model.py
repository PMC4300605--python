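"""Genome-scale model reading/writing (SBML Level 2/3, via libSBML).

``read_sbml_model`` digests just what the layout machinery needs: reactions
with reversibility and stoichiometric participants, metabolites with
compartments, gene identifiers (from the fbc package when present, else
parsed out of legacy ``GENE_ASSOCIATION`` notes), and pathway membership
(from the groups package when present, else ``SUBSYSTEM:`` notes lines).

``write_sbml_model`` emits a Level 3 Version 1 document; pathway membership
is stored as a ``SUBSYSTEM:`` line in each reaction's notes so that a
written model reads back with the same pathway table.
"""

from __future__ import annotations

import re
from typing import IO, Union

import libsbml

from ..fdl import ModelDigest, ModelMetabolite, ModelReaction
from .report import FormatError, FormatReport

_GENE_SPLIT = re.compile(r"[\s()]+|\band\b|\bor\b|\bAND\b|\bOR\b")
_SUBSYSTEM = re.compile(r"SUBSYSTEM:\s*([^<\n]+)")
_GENE_ASSOC = re.compile(r"GENE[ _]?ASSOCIATION:\s*([^<\n]+)")


def _read_document(source) -> libsbml.SBMLDocument:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, bytes):
            data = data.decode("utf-8")
        doc = libsbml.readSBMLFromString(data)
    else:
        doc = libsbml.readSBMLFromString(str(source))
    return doc


def read_sbml_model(stream) -> tuple[ModelDigest, FormatReport]:
    doc = _read_document(stream)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0 \
            or doc.getModel() is None:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR) \
            if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) else None
        detail = first.getMessage() if first else "no model element"
        raise FormatError(f"invalid SBML: {detail}")
    model = doc.getModel()
    report = FormatReport("sbml_model")
    digest = ModelDigest(name=model.getId() or model.getName() or "model")

    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        digest.metabolites[sp.getId()] = ModelMetabolite(
            id=sp.getId(), name=sp.getName() or sp.getId(),
            compartment=sp.getCompartment() or "")

    genes: dict[str, None] = {}
    fbc = model.getPlugin("fbc")
    if fbc is not None and hasattr(fbc, "getNumGeneProducts"):
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            genes[gp.getId()] = None

    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        reaction = ModelReaction(
            id=rxn.getId(), name=rxn.getName() or rxn.getId(),
            reversible=bool(rxn.getReversible()))
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            if ref.getSpecies() not in digest.metabolites:
                report.warn(f"reaction {rxn.getId()}: unknown species "
                            f"{ref.getSpecies()!r}")
            reaction.substrates.append(
                (ref.getSpecies(), ref.getStoichiometry() or 1.0))
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            if ref.getSpecies() not in digest.metabolites:
                report.warn(f"reaction {rxn.getId()}: unknown species "
                            f"{ref.getSpecies()!r}")
            reaction.products.append(
                (ref.getSpecies(), ref.getStoichiometry() or 1.0))
        digest.reactions[reaction.id] = reaction

        notes = rxn.getNotesString() if rxn.isSetNotes() else ""
        for match in _SUBSYSTEM.finditer(notes):
            pathway = match.group(1).strip()
            if pathway:
                digest.pathways.setdefault(pathway, []).append(reaction.id)
        for match in _GENE_ASSOC.finditer(notes):
            for token in _GENE_SPLIT.split(match.group(1)):
                token = token.strip()
                if token and token.lower() not in ("and", "or", "none",
                                                   "unknown", ""):
                    genes[token] = None

    groups = model.getPlugin("groups")
    if groups is not None and hasattr(groups, "getNumGroups"):
        for i in range(groups.getNumGroups()):
            group = groups.getGroup(i)
            name = group.getName() or group.getId()
            members = []
            for j in range(group.getNumMembers()):
                member = group.getMember(j)
                ref = member.getIdRef() or member.getMetaIdRef()
                if ref in digest.reactions:
                    members.append(ref)
            if members:
                digest.pathways[name] = members

    digest.genes = sorted(genes)
    report.counts = {"reactions": len(digest.reactions),
                     "metabolites": len(digest.metabolites),
                     "genes": len(digest.genes),
                     "pathways": len(digest.pathways)}
    return digest, report


def write_sbml_model(digest: ModelDigest, stream: IO) -> None:
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId(re.sub(r"\W", "_", digest.name) or "model")

    compartments = {m.compartment or "c" for m in digest.metabolites.values()}
    for cid in sorted(compartments):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for met in digest.metabolites.values():
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment or "c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    pathway_of: dict[str, list[str]] = {}
    for name, members in digest.pathways.items():
        for rid in members:
            pathway_of.setdefault(rid, []).append(name)

    for rxn in digest.reactions.values():
        out = model.createReaction()
        out.setId(rxn.id)
        out.setName(rxn.name)
        out.setReversible(rxn.reversible)
        out.setFast(False)
        for met_id, coef in rxn.substrates:
            ref = out.createReactant()
            ref.setSpecies(met_id)
            ref.setStoichiometry(coef)
            ref.setConstant(True)
        for met_id, coef in rxn.products:
            ref = out.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(coef)
            ref.setConstant(True)
        for pathway in pathway_of.get(rxn.id, []):
            out.appendNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>SUBSYSTEM: {pathway}</p></body>")

    text = libsbml.writeSBMLToString(doc)
    if hasattr(stream, "write"):
        try:
            stream.write(text)
        except TypeError:
            stream.write(text.encode("utf-8"))
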