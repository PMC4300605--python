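# Methods

## The layout model

A metabolic drawing is modelled as a bipartite reaction–compound graph:
reaction nodes, metabolite nodes (regular or currency), free-text
information nodes attached to reactions, and substrate/product edges that
may only connect a reaction to a metabolite.  The model is deliberately
qualitative: stoichiometric coefficients are not stored on edges (a
metabolite appearing on both sides of a reaction simply yields two edges
with different roles), and arrowhead semantics are derived from the
reaction's reversibility at render time rather than stored per edge.
Coordinates live on an abstract unitless canvas, origin top-left,
y increasing downward; this matches SVG and the pixel conventions of KEGG
maps, so format readers never flip axes.

Every reaction and metabolite node carries a *list* of model identifiers.
This many-to-many link (several model reactions summed onto one node,
one model species spread over replica nodes) is what lets a partial
layout be reused across strains and model versions, and is the sole
bridge between simulation results and the drawing.

Editing operations (`split_metabolite_node`, `merge_metabolite_nodes`,
`replicate_reaction_node`, `merge_reaction_nodes`, kind/fixed changes)
are pure functions returning new layouts, and all preserve the bipartite
invariants checked by `validate_layout`.  Design choices where the
concept itself is open:

* **"Same compound"** for a metabolite merge means *identical* model-id
  sets and identical kind — the strictest safe reading.  Overlapping but
  unequal id lists are rejected; users who want those merges can edit the
  id lists first.
* Replica ids are `<original>__k`, with k assigned in sorted order of the
  neighbouring reaction ids, so repeated runs produce identical files.
* Splitting a degree-1 metabolite is a no-op rather than an error, which
  keeps batch scripts idempotent.
* Unfixing a node clears only its *pinned* flag; the stored coordinates
  are kept as the spring-embedder's starting point.  Dropping them
  entirely would make every re-layout start from random positions, i.e.
  non-reproducible.  Fixing a positionless node assigns (0, 0).
* Information nodes are drawn beside their reaction and are excluded from
  layout forces; when reactions are merged their information nodes are
  re-pointed at the survivor.

## Identifier mapping and flux aggregation

Mappings are built in one of three modes: explicit two-column pairs;
regex canonicalization (apply a substitution to layout ids and/or model
ids, match equal canonical strings, plus verbatim hits against the nodes'
model-id lists); or the default verbatim mode using only the model-id
lists.  Matching is case-sensitive because SBML ids are.  Unmatched ids
on either side are diagnostics, never errors — partial layouts are the
normal case, not a failure.

Flux aggregation is summation: all model-reaction values mapped to a node
are added.  A model reaction mapped to k replica nodes contributes its
full value to each replica — replicas depict the same reaction, so their
visual weight must agree; splitting the value across replicas would make
the same flux look weaker wherever a drawing happens to duplicate a node.

## Overlay arithmetic

Widths are normalized linearly against the largest mapped flux magnitude
F: `w = w_min + (w_max − w_min)·|f|/F` (all `w_min` when F = 0), with
defaults `w_min = 1`, `w_max = 8` canvas units.  Linear max-scaling is
monotone, attains both bounds exactly, and is invariant under rescaling
all fluxes by a positive constant.  The ratio `|f|/F` is computed before
multiplying by the width span so the peak node reaches `w_max` without
floating-point shortfall.  Magnitudes drive widths and gradients; the
signed value appears in the label (fixed-point, 3 decimals by default,
appended after a single space).

Comparison overlays use, per node, a = |f₁| and b = |f₂|: the edge color
is the neutral color (black) blended toward the dominant simulation's
color with weight `|a − b|/max(a, b)` — a scale-free choice, so doubling
both simulations changes nothing.  Equal nonzero fluxes give exactly
black; a zero on one side gives the pure color of the other.  Nodes with
a = b = 0 keep the default edge style instead of black, distinguishing
"no flux anywhere" from "equal nonzero flux".  Widths use the per-node
mean (a + b)/2, normalized after averaging against the largest mean.  On
reversible reactions whose two fluxes run in opposite directions, the
forward-pointing arrowheads (product ends) take the color of the
simulation with positive flux and the backward-pointing ones the other
color; elsewhere arrows stay schematic.  Genetic-condition glyphs
(knockout cross, up/down arrows) are merged on top and win over gradient
colors on the edges they touch.

Elementary-flux-mode overlays reuse the width/label rules, add no glyphs
or recoloring, and generate a filter hiding zero/absent-flux reactions
together with metabolites whose every neighbouring reaction is hidden.

## Force-directed layout with pinned nodes

The embedder is a Fruchterman–Reingold-style spring model: attraction
`k_s(d − L)` along edges toward the rest length L, pairwise repulsion
`k_r/d²`, a weak gravity pull toward the centroid of the pinned nodes
(keeps disconnected fragments from drifting), and a linearly cooling cap
on per-step displacement.  Pinned nodes exert forces but never move — the
output coordinates of a fixed node are bit-identical to its input.

Defaults: 500 iterations, `L = 80` canvas units, `k_s = 0.05`,
`k_r = 40 000`, gravity 0.01.  They are tuned for the intended drawing
scale of roughly 30–50 nodes (up to ~15 reactions), where they leave no
overlapping nodes; with repulsion disabled a single spring settles at its
rest length to ~10⁻¹⁰ relative error.

Determinism and id-independence: positionless nodes are initialized from
a random stream seeded by (seed, structural hash of the node), where the
hash is a Weisfeiler–Lehman subgraph hash over node classes, reversibility
and pinned coordinates; force accumulation also iterates in structural
order.  Coordinates therefore depend on the graph's structure and the
seed, not on how ids sort — relabeling an automorphism-free layout moves
nobody.  Automorphic nodes are distinguished by an orbit rank, so they may
exchange places under relabeling, which is the best any structural scheme
can do.

## Layout generation from a model

`generate_pathway_layout` builds one reaction node per selected reaction
(selection by reaction id or pathway name), shares regular metabolites,
and instantiates currency metabolites as one degree-1 replica per
reaction participation.  Currency status comes from an id list (default:
h, h2o, atp, adp, pi, nad(h), nadp(h), co2, coa, matched after lower-
casing, stripping an `M_` prefix and a trailing compartment suffix) or
from exceeding a degree threshold (default 8) within the selection — hub
compounds have no crisp definition, so both routes are exposed.  With a
basis layout, reactions already present (matched by model id) are reused
and only new ones appended; new nodes arrive unpinned and positionless
for the embedder to place.

## Formats

XGMML and SBGN-ML PD are read *and* written and round-trip losslessly;
KGML, CellDesigner-SBML and COBRA/BiGG `.map` are import-only; models are
read from SBML Level 2/3 (and written, for generated fixtures).  Format
notes:

* XGMML has no metabolic vocabulary, so a small documented dialect of
  `att` elements carries node type, model ids, reversibility and the
  pinned flag.
* SBGN-ML PD: processes carry two ports (`.1` substrate side, `.2`
  product side).  Reversible reactions are written, per PD convention,
  with production arcs on both sides; roles are recovered from the port
  an arc attaches to, which is deterministic where arc geometry would be
  ambiguous.  Fields with no native slot (model ids, pinned flag, exact
  coordinates) ride in the glyph's `extension` element, which the schema
  permits and other tools ignore.
* The historical COBRA `.map` dialects vary and are poorly documented;
  the reader accepts a versioned line-record dialect (header
  `COBRA-MAP 1`, `M`/`R`/`E` records) described in the module docstring,
  and degrades records with bad coordinates to unpinned nodes rather
  than failing the file.
* Model digests harvest pathway membership from the SBML groups package
  or legacy `SUBSYSTEM:` notes, and gene ids from the fbc package or
  legacy `GENE_ASSOCIATION` notes.

Rendering emits plain SVG 1.1: squares for reactions, circles for
metabolites (small gray for currency), straight edges, arrowheads as
explicit filled triangles (`polygon class="arrowhead"`) so structural
tests can count them, deterministic element order (sorted by node id).
PDF export is a small built-in vector converter that understands exactly
the SVG subset the renderer emits and draws it into a one-page PDF with
Helvetica text; it is not a general-purpose SVG rasterizer.

## Synthetic fixtures

`make_toy_scenario` emulates the analysis workflow end to end at toy
scale: a connected reaction chain with random side branches (branch
probability per reaction, default layouts use 0.3–0.5), ~30 % reversible
reactions, optional ATP→ADP currency pairs at a given rate, a wild-type
flux vector carrying a constant rate (10 mmol·gDW⁻¹·h⁻¹, a typical
central-metabolism magnitude) down the main chain, and a mutant vector
that reroutes the chain tail through the deepest-rooted side branch —
the rerouted reactions become the knockout set, mimicking a strain
design.  Flux vectors conserve mass at every internal metabolite of the
active route, so overlays look like steady-state simulation output
without implementing FBA.

What the generator does *not* emulate: genome-scale size, compartments,
gene–protein–reaction rules, realistic stoichiometric coefficients,
loops/parallel routes (the skeleton is a tree), or LP-derived flux
values.  Passing tests therefore demonstrate the correctness of the
layout/overlay machinery on structurally faithful miniatures, not
numerical agreement with any published simulation.  The two published
four-reaction knockout sets (succinate and glycine production in
*E. coli*) are shipped verbatim and embedded in small hand-simplified
pathway contexts for overlay tests; the full genome-scale flux solutions
are out of scope since they require the original models and an LP solver.

## Problem sizes and limitations

Tests and the acceptance script run on layouts of 5–10 reactions
(10–60 nodes), 100-fold round-trip batches and 200-pair merge checks —
the scale the drawing conventions target, chosen so the whole suite runs
in seconds.  Known limitations: no compartment-aware placement or
routing, no hierarchical/circular layout alternatives, no edge-crossing
minimization, no omics overlays, no interactive output, CellDesigner and
COBRA maps are import-only, and KGML files must be supplied by the user
(no automatic retrieval).
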