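"""Core bipartite-layout model: validation, editing algebra, filters."""

import numpy as np
import pytest

from metavis.fixtures import make_toy_scenario
from metavis.layout import (Edge, EdgeRole, MergeIllegalError,
                            MetaboliteKind, MetaboliteNode, MetabolicLayout,
                            NodeNotFoundError, ReactionNode,
                            SameCompoundViolation, WrongNodeKindError,
                            filter_by_kind, filter_by_reaction_ids,
                            fix_by_kind, merge_metabolite_nodes,
                            merge_reaction_nodes, replicate_reaction_node,
                            set_fixed, set_metabolite_kind,
                            split_metabolite_node, validate_layout)

from conftest import build_layout


def incidence_multiset(layout):
    """Multiset of (reaction model ids, metabolite model ids, role) —
    invariant under node replication/merging."""
    out = []
    for e in layout.edges:
        out.append((tuple(layout.reaction_nodes[e.reaction_id].model_ids),
                    tuple(layout.metabolite_nodes[e.metabolite_id].model_ids),
                    e.role.value))
    return sorted(out)


class TestValidation:
    def test_valid_toy_layout_has_no_violations(self, two_reaction_layout):
        assert validate_layout(two_reaction_layout) == []

    def test_edge_to_reaction_as_metabolite_is_bipartiteness_violation(self):
        layout = build_layout({"R1": (False, ["A"], ["B"]),
                               "R2": (False, ["B"], ["C"])})
        layout.edges.append(Edge("R1", "R2", EdgeRole.PRODUCT))
        codes = [v.code for v in validate_layout(layout)]
        assert codes == ["not_bipartite"]

    def test_deleted_node_leaves_one_dangling_violation_per_edge(self):
        layout = build_layout({"R1": (False, ["A"], ["B"]),
                               "R2": (False, ["B"], ["C"])})
        # brute-force oracle: every edge endpoint checked against id set
        del layout.metabolite_nodes["B"]
        expected = sum(
            1 for e in layout.edges for end in (e.reaction_id, e.metabolite_id)
            if end not in layout.node_ids())
        dangling = [v for v in validate_layout(layout)
                    if v.code == "dangling_edge"]
        assert len(dangling) == expected == 2

    def test_duplicate_edge_reported(self, two_reaction_layout):
        two_reaction_layout.edges.append(two_reaction_layout.edges[0])
        codes = [v.code for v in validate_layout(two_reaction_layout)]
        assert codes == ["duplicate_edge"]


class TestSplitMetabolite:
    def test_split_creates_one_replica_per_reaction(self):
        layout = build_layout({"R1": (False, ["M"], ["X"]),
                               "R2": (False, ["M"], ["Y"]),
                               "R3": (True, ["Z"], ["M"])})
        before = incidence_multiset(layout)
        out = split_metabolite_node(layout, "M")
        assert "M" not in out.metabolite_nodes
        replicas = [n for n in out.metabolite_nodes.values()
                    if n.id.startswith("M__")]
        assert len(replicas) == 3
        assert all(out.degree(r.id) == 1 for r in replicas)
        assert incidence_multiset(out) == before
        assert validate_layout(out) == []

    def test_degree_one_split_is_noop(self, two_reaction_layout):
        out = split_metabolite_node(two_reaction_layout, "A")
        assert set(out.node_ids()) == set(two_reaction_layout.node_ids())
        assert out.edges == two_reaction_layout.edges

    def test_currency_split_conserves_edges_and_kind(self):
        layout = build_layout({"R1": (False, ["cur_h2o"], ["X"]),
                               "R2": (False, ["Y"], ["cur_h2o"])})
        out = split_metabolite_node(layout, "cur_h2o")
        replicas = [n for n in out.metabolite_nodes.values()
                    if n.id.startswith("cur_h2o__")]
        assert len(replicas) == 2
        assert all(r.kind is MetaboliteKind.CURRENCY for r in replicas)
        assert len(out.edges) == len(layout.edges)

    def test_errors(self, two_reaction_layout):
        with pytest.raises(NodeNotFoundError):
            split_metabolite_node(two_reaction_layout, "nope")
        with pytest.raises(WrongNodeKindError):
            split_metabolite_node(two_reaction_layout, "R1")


class TestMergeMetabolites:
    def test_split_then_merge_is_identity_up_to_renaming(self):
        layout = build_layout({"R1": (False, ["M"], ["X"]),
                               "R2": (False, ["M"], ["Y"]),
                               "R3": (True, ["M"], ["Z"])})
        split = split_metabolite_node(layout, "M")
        replicas = [n.id for n in split.metabolite_nodes.values()
                    if n.id.startswith("M__")]
        merged = merge_metabolite_nodes(split, replicas)
        assert incidence_multiset(merged) == incidence_multiset(layout)
        assert len(merged.node_ids()) == len(layout.node_ids())
        assert validate_layout(merged) == []

    def test_different_compounds_refuse_to_merge(self):
        layout = build_layout({"R1": (False, ["Ma"], ["Mb"])})
        with pytest.raises(SameCompoundViolation):
            merge_metabolite_nodes(layout, ["Ma", "Mb"])

    def test_merge_replicas_yields_degree_two_node(self):
        layout = MetabolicLayout()
        for rid in ("R1", "R2"):
            layout.add_reaction(ReactionNode(rid))
        for mid in ("pyr_a", "pyr_b"):
            layout.add_metabolite(MetaboliteNode(mid, model_ids=["pyr"]))
        layout.add_edge("R1", "pyr_a", EdgeRole.PRODUCT)
        layout.add_edge("R2", "pyr_b", EdgeRole.SUBSTRATE)
        out = merge_metabolite_nodes(layout, ["pyr_a", "pyr_b"])
        assert out.degree("pyr_a") == 2  # lowest id survives
        assert "pyr_b" not in out.metabolite_nodes

    def test_merge_position_is_centroid(self):
        layout = MetabolicLayout()
        layout.add_reaction(ReactionNode("R1"))
        layout.add_metabolite(MetaboliteNode(
            "m1", model_ids=["glc"], position=(0.0, 0.0)))
        layout.add_metabolite(MetaboliteNode(
            "m2", model_ids=["glc"], position=(10.0, 20.0)))
        layout.add_edge("R1", "m1", EdgeRole.SUBSTRATE)
        layout.add_edge("R1", "m2", EdgeRole.SUBSTRATE)
        out = merge_metabolite_nodes(layout, ["m1", "m2"])
        assert out.metabolite_nodes["m1"].position == (5.0, 10.0)


class TestReactionReplicateMerge:
    def test_replicate_doubles_neighbor_degrees(self):
        layout = build_layout({"R1": (False, ["A", "B"], ["C"])})
        out = replicate_reaction_node(layout, "R1", 2)
        copies = [n for n in out.reaction_nodes.values()]
        assert len(copies) == 2
        assert all(out.degree(n.id) == 3 for n in copies)
        for met in ("A", "B", "C"):
            assert out.degree(met) == 2 * layout.degree(met)
        assert validate_layout(out) == []

    def test_replicate_then_merge_is_identity(self):
        layout = build_layout({"R1": (True, ["A"], ["B", "C"])})
        replicated = replicate_reaction_node(layout, "R1", 3)
        merged = merge_reaction_nodes(replicated,
                                      sorted(replicated.reaction_nodes))
        assert incidence_multiset(merged) == incidence_multiset(layout)
        assert set(merged.node_ids()) == set(layout.node_ids())

    def test_copies_inherit_reversibility(self):
        layout = build_layout({"R1": (False, ["A"], ["B"])})
        out = replicate_reaction_node(layout, "R1", 4)
        assert all(not n.reversible for n in out.reaction_nodes.values())

    def test_replicate_requires_n_at_least_two(self, two_reaction_layout):
        with pytest.raises(ValueError):
            replicate_reaction_node(two_reaction_layout, "R1", 1)

    def test_reversibility_mismatch_blocks_merge(self):
        layout = build_layout({"R1": (True, ["A"], ["B"]),
                               "R1b": (False, ["A"], ["B"])})
        with pytest.raises(MergeIllegalError, match="reversibility"):
            merge_reaction_nodes(layout, ["R1", "R1b"])

    def test_neighbor_mismatch_blocks_merge(self):
        layout = build_layout({"R1": (False, ["A"], ["B"]),
                               "R2": (False, ["A"], ["C"])})
        with pytest.raises(MergeIllegalError, match="neighbors"):
            merge_reaction_nodes(layout, ["R1", "R2"])

    @pytest.mark.parametrize("seed", range(8))
    def test_merge_acceptance_matches_brute_force_predicate(self, seed):
        """Mergeable iff identical sorted (neighbor, role) list and equal
        reversible flag — compared against the brute-force predicate on
        random reaction pairs."""
        rng = np.random.default_rng(seed)
        mets = [f"M{i}" for i in range(4)]
        layout = MetabolicLayout()
        for m in mets:
            layout.add_metabolite(MetaboliteNode(m))
        for r in range(6):
            rid = f"R{r}"
            layout.add_reaction(ReactionNode(
                rid, reversible=bool(rng.random() < 0.5)))
            for m in mets:
                if rng.random() < 0.5:
                    layout.add_edge(rid, m, EdgeRole(
                        "substrate" if rng.random() < 0.5 else "product"))
        pairs_checked = 0
        for a in layout.reaction_nodes:
            for b in layout.reaction_nodes:
                if a >= b:
                    continue
                pairs_checked += 1
                brute = (
                    sorted((e.metabolite_id, e.role.value)
                           for e in layout.edges if e.reaction_id == a)
                    == sorted((e.metabolite_id, e.role.value)
                              for e in layout.edges if e.reaction_id == b)
                    and layout.reaction_nodes[a].reversible
                    == layout.reaction_nodes[b].reversible)
                try:
                    merge_reaction_nodes(layout, [a, b])
                    accepted = True
                except MergeIllegalError:
                    accepted = False
                assert accepted == brute, (a, b)
        assert pairs_checked == 15


class TestFlagsAndFilters:
    def test_set_kind_updates_currency_filter(self, two_reaction_layout):
        out = set_metabolite_kind(two_reaction_layout, "A", "currency")
        assert "A" in filter_by_kind(out, "currency_metabolites").hidden_node_ids
        back = set_metabolite_kind(out, "A", MetaboliteKind.REGULAR)
        assert "A" not in filter_by_kind(back,
                                         "currency_metabolites").hidden_node_ids

    def test_set_kind_idempotent(self, two_reaction_layout):
        out = set_metabolite_kind(two_reaction_layout, "A",
                                  MetaboliteKind.REGULAR)
        assert out.metabolite_nodes["A"].kind is MetaboliteKind.REGULAR
        assert out.edges == two_reaction_layout.edges

    def test_fix_by_kind_touches_only_that_kind(self, positioned_layout):
        layout = fix_by_kind(positioned_layout, "metabolite", False)
        out = fix_by_kind(layout, "reaction", True)
        assert all(n.fixed for n in out.reaction_nodes.values())
        assert not any(n.fixed for n in out.metabolite_nodes.values())

    def test_fixing_positionless_node_assigns_origin(self, two_reaction_layout):
        out = set_fixed(two_reaction_layout, "A", True)
        assert out.metabolite_nodes["A"].position == (0.0, 0.0)
        assert out.metabolite_nodes["A"].fixed

    def test_unfix_keeps_coordinates(self, positioned_layout):
        pos = positioned_layout.metabolite_nodes["A"].position
        out = set_fixed(positioned_layout, "A", False)
        assert not out.metabolite_nodes["A"].fixed
        assert out.metabolite_nodes["A"].position == pos

    def test_filter_by_kind_counts(self):
        scenario_layout = build_layout({
            "R1": (False, ["A", "cur_x"], ["B"]),
            "R2": (False, ["B", "cur_y"], ["C", "D"]),
        })
        # 2 of 6 metabolites are currency (brute-force kind scan)
        brute = {n.id for n in scenario_layout.metabolite_nodes.values()
                 if n.kind is MetaboliteKind.CURRENCY}
        filt = filter_by_kind(scenario_layout, "currency_metabolites")
        assert filt.hidden_node_ids == brute
        assert len(filt.hidden_node_ids) == 2

    def test_empty_layout_gives_empty_filter(self):
        assert filter_by_kind(MetabolicLayout(),
                              "all_metabolites").hidden_node_ids == set()

    def test_filter_by_model_reaction_id(self):
        layout = build_layout({"R_TKT1": (True, ["e4p"], ["f6p"])})
        filt = filter_by_reaction_ids(layout, ["mdl_R_TKT1"])
        assert filt.hidden_node_ids == {"R_TKT1"}
        filt2 = filter_by_reaction_ids(layout, ["R_TKT1", "bogus"])
        assert filt2.hidden_node_ids == {"R_TKT1"}
        assert filt2.metadata["unknown_ids"] == ["bogus"]


@pytest.mark.parametrize("seed", range(6))
def test_every_edit_preserves_validity_on_random_layouts(seed):
    """Bipartiteness after every operation: validate_layout stays empty."""
    scenario = make_toy_scenario(6, 0.5, 0.5, seed=seed)
    layout = scenario.layout
    assert validate_layout(layout) == []
    shared = [m for m in layout.metabolite_nodes
              if layout.degree(m) >= 2]
    if shared:
        layout = split_metabolite_node(layout, shared[0])
        assert validate_layout(layout) == []
    rid = next(iter(layout.reaction_nodes))
    layout = replicate_reaction_node(layout, rid, 2)
    assert validate_layout(layout) == []
    layout = merge_reaction_nodes(
        layout, [rid, next(i for i in layout.reaction_nodes
                           if i.startswith(f"{rid}__"))])
    assert validate_layout(layout) == []
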