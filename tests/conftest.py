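import pytest

from metavis.layout import (EdgeRole, MetaboliteKind, MetaboliteNode,
                            MetabolicLayout, ReactionNode)


def build_layout(reactions, positions=False):
    """Build a layout from {rid: (reversible, [substrates], [products])};
    metabolites are created on first mention."""
    layout = MetabolicLayout(name="test")
    x = 0.0
    for rid, (reversible, subs, prods) in reactions.items():
        layout.add_reaction(ReactionNode(
            id=rid, label=rid, model_ids=[f"mdl_{rid}"],
            reversible=reversible,
            position=(x, 0.0) if positions else None, fixed=positions))
        x += 100.0
        for met, role in [(m, EdgeRole.SUBSTRATE) for m in subs] \
                + [(m, EdgeRole.PRODUCT) for m in prods]:
            if met not in layout.metabolite_nodes:
                kind = (MetaboliteKind.CURRENCY if met.startswith("cur_")
                        else MetaboliteKind.REGULAR)
                layout.add_metabolite(MetaboliteNode(
                    id=met, label=met, model_ids=[f"mdl_{met}"], kind=kind,
                    position=(x, 80.0) if positions else None,
                    fixed=positions))
            layout.add_edge(rid, met, role)
    return layout


@pytest.fixture
def two_reaction_layout():
    """A -> R1 -> B -> R2(rev) -> C, with a currency cofactor on R1."""
    return build_layout({
        "R1": (False, ["A", "cur_h2o"], ["B"]),
        "R2": (True, ["B"], ["C"]),
    })


@pytest.fixture
def positioned_layout():
    return build_layout({
        "R1": (False, ["A"], ["B"]),
        "R2": (True, ["B"], ["C"]),
        "R3": (False, ["C", "cur_atp"], ["D"]),
    }, positions=True)
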