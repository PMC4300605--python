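# metavis

Metabolic-network visualization for metabolic engineering: a scriptable
library and CLI that represents pathway drawings as abstract bipartite
reaction–compound graphs, connects them to genome-scale metabolic models
(GSMMs), and paints phenotype-simulation results — flux distributions,
genetic conditions, simulation comparisons, elementary flux modes — onto
static SVG/PDF figures.

It is aimed at strain designers and systems biologists who run
constraint-based simulations (FBA and relatives) and want their flux
vectors and knockout designs drawn on curated pathway maps, in batch,
without a GUI.

## The model

A layout is a bipartite graph: reaction nodes **R** and metabolite nodes
**M**, with substrate/product edges only between the two classes.
Metabolites are *regular* or *currency* (highly connected hubs such as
H₂O or ATP, replicated per reaction or hidden to declutter).  Each node
carries a list of model identifiers linking it to one or more GSMM
reactions/species, so a partial layout can be reused across models and
replicated nodes stay tied to their entity.  Arrowheads are derived, not
stored: irreversible reactions arrow their product edges only, reversible
reactions arrow every metabolite end.

Overlays follow three rules:

* **widths** — per reaction node *n* with aggregated flux *f(n)* (several
  model reactions mapping to one node are summed), and
  *F = max<sub>n</sub> |f(n)|*:

  `w(n) = w_min + (w_max − w_min) · |f(n)| / F`

  so the strongest flux attains `w_max` exactly and widths are invariant
  under rescaling all fluxes;
* **genetic conditions** — knockouts draw a red cross and red edges,
  over-expression a green up-arrow, under-expression an orange down-arrow;
* **comparisons** — with *a = |f₁(n)|*, *b = |f₂(n)|*, edge colors blend
  from black (no difference) toward simulation 1's color (red) when
  *a > b* or simulation 2's (green) when *b > a*, with scale-free weight
  `|a − b| / max(a, b)`; widths use the per-node mean `(a + b)/2`; on
  reversible reactions running in opposite directions each arrowhead takes
  the color of the simulation flowing its way.

Coordinates come from loaded maps (XGMML, SBGN-ML PD, KGML,
CellDesigner-SBML, COBRA/BiGG `.map`) or from a force-directed spring
embedder that honors pinned nodes; layouts can also be generated straight
from a model's reactions or pathways.

## Worked example

```python
from metavis import *

scenario = make_toy_scenario(n_reactions=6, branching=0.4,
                             currency_rate=0.3, seed=42)
print("reactions:", len(scenario.layout.reaction_nodes),
      "metabolites:", len(scenario.layout.metabolite_nodes),
      "edges:", len(scenario.layout.edges))
print("knockouts:", sorted(scenario.conditions.knockouts))

ov = comparison_overlay(scenario.layout, scenario.mapping,
                        scenario.wild_flux, scenario.mutant_flux)
print("edge widths:", sorted({round(w, 2) for w in ov.edge_width.values()}))
for f in ov.filters:
    print(f"filter {f.name}: hides {len(f.hidden_node_ids)} reaction(s)")

svg = render_svg(run_fdl(scenario.layout, FdlParams(seed=42)), ov)
```

prints

```
reactions: 6 metabolites: 11 edges: 16
knockouts: ['R_rxn5']
edge widths: [1.0, 4.5, 8.0]
filter hide-zero-in-A: hides 2 reaction(s)
filter hide-zero-in-B: hides 2 reaction(s)
```

The toy mutant reroutes the chain tail through a side branch, knocking
out `R_rxn5`.  Reactions active in both simulations at the full rate get
the maximum width 8.0; the rerouted/diverting pair carries half the mean
flux (width 4.5); silent reactions stay at the minimum 1.0.  Each
simulation also contributes a hide-zero filter naming its inactive
reactions.  `svg` is the finished drawing; `svg_to_pdf(svg)` converts it
to a one-page PDF.

The same pipeline from the shell:

```sh
metavis fixtures -n 6 --seed 42 -o scen
metavis render scen/layout.xgmml --flux scen/wild.tsv \
        --conditions scen/conditions.tsv -o wild.svg
metavis compare scen/layout.xgmml --flux-a scen/wild.tsv \
        --flux-b scen/mutant.tsv -o compare.svg
```

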