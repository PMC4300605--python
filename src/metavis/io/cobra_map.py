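"""COBRA/BiGG ``.map`` text layout reader (read-only, best effort).

The historical BiGG map dialects vary; this reader is versioned and accepts
the documented dialect below (version 1).  Files must start with a header
line ``COBRA-MAP<TAB>1`` (tolerating a plain ``COBRA-MAP`` header) followed
by tab-delimited records:

* ``M<TAB>id<TAB>label<TAB>x<TAB>y`` — metabolite;
* ``R<TAB>id<TAB>label<TAB>x<TAB>y<TAB>0|1`` — reaction (last column:
  reversible);
* ``E<TAB>reaction_id<TAB>metabolite_id<TAB>substrate|product`` — edge.

``#`` lines are comments.  Nodes with parseable coordinates are fixed;
records with non-numeric coordinates degrade to unfixed nodes with a
warning, and otherwise unparseable records are collected as warnings.
"""

from __future__ import annotations

from typing import Iterable, TextIO

from ..layout import (EdgeRole, MetaboliteNode, MetabolicLayout, ReactionNode)
from .report import FormatError, FormatReport


def read_cobra_map(stream: TextIO | Iterable[str]
                   ) -> tuple[MetabolicLayout, FormatReport]:
    lines = [line.rstrip("\n") for line in stream]
    content = [(i + 1, ln) for i, ln in enumerate(lines)
               if ln.strip() and not ln.lstrip().startswith("#")]
    if not content:
        raise FormatError("empty COBRA map file")
    header_no, header = content[0]
    if not header.split("\t")[0].strip().upper() == "COBRA-MAP":
        raise FormatError(
            f"line {header_no}: unrecognized header {header!r}; expected "
            "'COBRA-MAP'")
    report = FormatReport("cobra_map")
    layout = MetabolicLayout(name="cobra map")

    def coords(xs: str, ys: str, node_id: str):
        try:
            return (float(xs), float(ys)), True
        except ValueError:
            report.warn(f"node {node_id}: non-numeric coordinates "
                        f"({xs!r}, {ys!r}); node left unfixed")
            return None, False

    pending_edges: list[tuple[int, str, str, str]] = []
    for lineno, line in content[1:]:
        cols = line.split("\t")
        kind = cols[0].strip().upper()
        try:
            if kind == "M" and len(cols) == 5:
                position, fixed = coords(cols[3], cols[4], cols[1])
                layout.add_metabolite(MetaboliteNode(
                    id=cols[1], label=cols[2], model_ids=[cols[1]],
                    position=position, fixed=fixed))
            elif kind == "R" and len(cols) == 6:
                position, fixed = coords(cols[3], cols[4], cols[1])
                layout.add_reaction(ReactionNode(
                    id=cols[1], label=cols[2], model_ids=[cols[1]],
                    reversible=cols[5].strip() in ("1", "true"),
                    position=position, fixed=fixed))
            elif kind == "E" and len(cols) == 4:
                pending_edges.append((lineno, cols[1], cols[2], cols[3]))
            else:
                report.warn(f"line {lineno}: unparseable record {line!r}")
        except ValueError as exc:
            report.warn(f"line {lineno}: {exc}")

    for lineno, rid, mid, role in pending_edges:
        if rid not in layout.reaction_nodes \
                or mid not in layout.metabolite_nodes \
                or role not in ("substrate", "product"):
            report.warn(f"line {lineno}: unresolved edge record")
            continue
        layout.add_edge(rid, mid, EdgeRole(role))

    report.counts = {"nodes": len(layout.node_ids()),
                     "edges": len(layout.edges),
                     "reactions": len(layout.reaction_nodes)}
    return layout, report
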