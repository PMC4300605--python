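"""Overlay math: width normalization, genetic glyphs, comparison gradient,
elementary-mode filters."""

import pytest
from hypothesis import given, settings, strategies as st

from metavis.fixtures import case_study_knockouts, case_study_scenario
from metavis.layout import MetabolicLayout, MetaboliteNode, ReactionNode
from metavis.mapping import (FluxDistribution, GeneticConditions,
                             build_mapping)
from metavis.overlay import (Glyph, StyleConfig, comparison_overlay,
                             efm_overlay, flux_overlay, genetic_overlay)

from conftest import build_layout


def star_layout(n):
    """n reactions N1..Nn, each with its own substrate and product."""
    return build_layout({f"N{i}": (False, [f"s{i}"], [f"p{i}"])
                         for i in range(1, n + 1)})


def mapping_for(layout):
    model_ids = [f"mdl_{r}" for r in layout.reaction_nodes]
    return build_mapping(layout, model_ids, [])


class TestFluxOverlay:
    def test_linear_normalization_matches_formula(self):
        layout = star_layout(3)
        flux = FluxDistribution({"mdl_N1": 10.0, "mdl_N2": 5.0,
                                 "mdl_N3": 0.0})
        ov = flux_overlay(layout, mapping_for(layout), flux)
        widths = {e.reaction_id: w for e, w in ov.edge_width.items()}
        assert widths["N1"] == pytest.approx(8.0, abs=1e-9)
        assert widths["N2"] == pytest.approx(4.5, abs=1e-9)
        assert widths["N3"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_distribution_gives_min_width_everywhere(self):
        layout = star_layout(2)
        ov = flux_overlay(layout, mapping_for(layout), FluxDistribution({}))
        assert ov.edge_width == {}
        assert ov.label_suffix == {}

    def test_negative_flux_uses_magnitude_for_width_sign_for_label(self):
        layout = star_layout(2)
        flux = FluxDistribution({"mdl_N1": -6.0, "mdl_N2": 3.0})
        ov = flux_overlay(layout, mapping_for(layout), flux)
        widths = {e.reaction_id: w for e, w in ov.edge_width.items()}
        assert widths["N1"] == pytest.approx(8.0)
        assert widths["N1"] > widths["N2"]
        assert ov.label_suffix["N1"] == "-6.000"

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=6),
           st.floats(0.001, 1000.0))
    def test_width_bounds_and_scale_invariance(self, values, scale):
        layout = star_layout(len(values))
        mapping = mapping_for(layout)
        flux = FluxDistribution(
            {f"mdl_N{i+1}": v for i, v in enumerate(values)})
        scaled = FluxDistribution(
            {k: v * scale for k, v in flux.values.items()})
        style = StyleConfig()
        ov = flux_overlay(layout, mapping, flux, style)
        ov_scaled = flux_overlay(layout, mapping, scaled, style)
        peak = max(abs(v) for v in values)
        for edge, width in ov.edge_width.items():
            assert style.min_width <= width <= style.max_width
            if abs(flux.values[f"mdl_{edge.reaction_id}"]) == peak and peak > 0:
                assert width == style.max_width  # exact attainment
            assert ov_scaled.edge_width[edge] == pytest.approx(width,
                                                               rel=1e-9)


class TestGeneticOverlay:
    def test_published_knockout_sets_mark_exactly_four_crosses(self):
        for case in ("succinate", "glycine"):
            layout, mapping, conditions = case_study_scenario(case)
            ov = genetic_overlay(layout, mapping, conditions)
            crosses = [n for n, g in ov.node_glyph.items()
                       if g is Glyph.KNOCKOUT_CROSS]
            assert len(crosses) == 4
            assert ov.unmapped_condition_ids == []

    def test_published_sets_are_four_each_and_disjoint(self):
        succinate, glycine = case_study_knockouts()
        assert len(succinate.knockouts) == 4
        assert len(glycine.knockouts) == 4
        assert succinate.knockouts.isdisjoint(glycine.knockouts)

    def test_empty_conditions_touch_nothing(self):
        layout = star_layout(2)
        ov = genetic_overlay(layout, mapping_for(layout),
                             GeneticConditions())
        assert ov.node_glyph == {} and ov.edge_color == {}

    def test_over_green_up_arrow_under_orange_down_arrow(self):
        layout = star_layout(2)
        style = StyleConfig()
        ov = genetic_overlay(
            layout, mapping_for(layout),
            GeneticConditions(over_expressed={"mdl_N1"},
                              under_expressed={"mdl_N2"}), style)
        assert ov.node_glyph["N1"] is Glyph.UP_ARROW
        assert ov.node_glyph["N2"] is Glyph.DOWN_ARROW
        colors = {e.reaction_id: c for e, c in ov.edge_color.items()}
        assert colors["N1"] == style.over_color
        assert colors["N2"] == style.under_color

    def test_touches_exactly_the_mapped_condition_nodes(self):
        layout = star_layout(3)
        conditions = GeneticConditions(knockouts={"mdl_N1", "ghost"})
        ov = genetic_overlay(layout, mapping_for(layout), conditions)
        assert set(ov.node_glyph) == {"N1"}
        assert ov.unmapped_condition_ids == ["ghost"]


class TestComparisonOverlay:
    def overlay_for(self, fa, fb, **kw):
        layout = star_layout(max(len(fa), len(fb), 2))
        mapping = mapping_for(layout)
        return layout, comparison_overlay(
            layout, mapping,
            FluxDistribution({f"mdl_N{i+1}": v for i, v in enumerate(fa)}),
            FluxDistribution({f"mdl_N{i+1}": v for i, v in enumerate(fb)}),
            **kw)

    def test_equal_fluxes_give_black(self):
        _, ov = self.overlay_for([3.0], [3.0])
        colors = {e.reaction_id: c for e, c in ov.edge_color.items()}
        assert colors["N1"] == (0, 0, 0)

    def test_zero_in_one_simulation_gives_pure_color_and_filter(self):
        style = StyleConfig()
        _, ov = self.overlay_for([5.0, 1.0], [0.0, 1.0], style=style)
        colors = {e.reaction_id: c for e, c in ov.edge_color.items()}
        assert colors["N1"] == style.sim1_color
        hide_b = next(f for f in ov.filters if f.name == "hide-zero-in-B")
        assert "N1" in hide_b.hidden_node_ids
        assert "N2" not in hide_b.hidden_node_ids

    def test_half_difference_blends_halfway_and_width_uses_mean(self):
        style = StyleConfig()
        layout, ov = self.overlay_for([6.0, 9.0], [3.0, 9.0], style=style)
        colors = {e.reaction_id: c for e, c in ov.edge_color.items()}
        expected = tuple(round(0.5 * c) for c in style.sim1_color)
        assert colors["N1"] == expected
        widths = {e.reaction_id: w for e, w in ov.edge_width.items()}
        # means: N1 -> 4.5, N2 -> 9.0 (the maximum mean)
        assert widths["N2"] == style.max_width
        assert widths["N1"] == pytest.approx(
            style.min_width
            + (style.max_width - style.min_width) * 4.5 / 9.0)

    def test_both_zero_keeps_default_edge_style(self):
        _, ov = self.overlay_for([0.0], [0.0])
        assert all(e.reaction_id != "N1" for e in ov.edge_color)

    def test_swapping_simulations_and_colors_is_symmetric(self):
        style = StyleConfig()
        swapped = StyleConfig(sim1_color=style.sim2_color,
                              sim2_color=style.sim1_color)
        fa = [6.0, 2.0, 0.0, 4.0]
        fb = [3.0, 2.0, 5.0, 0.0]
        _, ov1 = self.overlay_for(fa, fb, style=style)
        _, ov2 = self.overlay_for(fb, fa, style=swapped)
        assert ov1.edge_color == ov2.edge_color

    def test_opposite_directions_on_reversible_reaction_color_arrowheads(self):
        layout = build_layout({"N1": (True, ["s"], ["p"])})
        mapping = mapping_for(layout)
        style = StyleConfig()
        ov = comparison_overlay(
            layout, mapping, FluxDistribution({"mdl_N1": 4.0}),
            FluxDistribution({"mdl_N1": -2.0}), style)
        backward, forward = ov.direction_colors["N1"]
        assert forward == style.sim1_color  # simulation A runs forward
        assert backward == style.sim2_color

    def test_genetic_conditions_from_both_simulations_apply(self):
        layout = star_layout(2)
        mapping = mapping_for(layout)
        ov = comparison_overlay(
            layout, mapping, FluxDistribution({"mdl_N1": 1.0}),
            FluxDistribution({"mdl_N1": 1.0}),
            conditions_a=GeneticConditions(knockouts={"mdl_N2"}),
            conditions_b=GeneticConditions(over_expressed={"mdl_N1"}))
        assert ov.node_glyph["N2"] is Glyph.KNOCKOUT_CROSS
        assert ov.node_glyph["N1"] is Glyph.UP_ARROW


class TestEfmOverlay:
    def test_zero_flux_reactions_and_orphans_hidden(self):
        layout = build_layout({
            "R1": (False, ["A"], ["B"]),
            "R2": (False, ["B"], ["C"]),
            "R3": (False, ["C"], ["D"]),
            "R4": (False, ["D"], ["E"]),
            "R5": (False, ["E"], ["F"]),
        })
        mapping = mapping_for(layout)
        efm = FluxDistribution({"mdl_R1": 1.0, "mdl_R2": 1.0,
                                "mdl_R3": 1.0, "mdl_R4": 0.0})
        ov = efm_overlay(layout, mapping, efm)
        filt = next(f for f in ov.filters if f.name == "hide-zero-flux")
        # zero-set scan oracle: R4 (explicit 0) and R5 (absent)
        assert {"R4", "R5"} <= filt.hidden_node_ids
        assert "F" in filt.hidden_node_ids  # orphaned metabolite
        assert "D" not in filt.hidden_node_ids  # still touched by R3
        assert ov.node_glyph == {} and ov.edge_color == {}

    def test_all_zero_mode_hides_every_reaction(self):
        layout = star_layout(3)
        ov = efm_overlay(layout, mapping_for(layout), FluxDistribution({}))
        filt = ov.filters[-1]
        assert set(layout.reaction_nodes) <= filt.hidden_node_ids

    def test_single_reaction_mode_gets_max_width(self):
        layout = star_layout(2)
        style = StyleConfig()
        ov = efm_overlay(layout, mapping_for(layout),
                         FluxDistribution({"mdl_N1": 1.0}), style)
        widths = {e.reaction_id: w for e, w in ov.edge_width.items()}
        assert widths["N1"] == style.max_width
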