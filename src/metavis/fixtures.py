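"""Programmatic toy fixtures with known ground truth.

:func:`make_toy_scenario` builds, from a seed, a connected toy metabolic
model (a reaction chain with random branches, random reversibility and
optional ATP/ADP currency pairs), the corresponding layout, a complete
identifier mapping, a steady-state-like wild-type flux vector (nonzero
along one route, conserving mass at every internal metabolite of that
route), a mutant vector with the tail of that route rerouted, and the
knockout conditions implied by the reroute.  The scenario's ``truth``
record holds entity counts tracked independently during construction, so
tests can compare them against what the layout machinery actually built.

:func:`case_study_knockouts` returns the two published four-reaction
knockout sets (succinate production on iJR904, glycine production on
iAF1260); :func:`case_study_scenario` embeds either set in a small layout
built from simplified versions of the printed reaction equations, fully
mapped, for overlay tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fdl import (ModelDigest, ModelMetabolite, ModelReaction,
                  generate_pathway_layout)
from .layout import MetabolicLayout
from .mapping import (FluxDistribution, GeneticConditions, ModelMapping,
                      build_mapping, write_conditions_tsv, write_flux_tsv)

#: published knockout sets: succinate production (iJR904 model) and
#: glycine production (iAF1260 model)
SUCCINATE_KNOCKOUTS = frozenset({"R_GHMT2", "R_THD2", "R_SUCD1i", "R_TKT1"})
GLYCINE_KNOCKOUTS = frozenset({"R_ICL", "R_GLYCL", "R_PPC", "R_GART"})

_WILD_FLUX = 10.0


@dataclass
class ScenarioTruth:
    nodes: int = 0
    edges: int = 0
    currency_replicas: int = 0
    nonzero_wild_fluxes: int = 0


@dataclass
class ToyScenario:
    model: ModelDigest
    layout: MetabolicLayout
    mapping: ModelMapping
    wild_flux: FluxDistribution
    mutant_flux: FluxDistribution
    conditions: GeneticConditions
    truth: ScenarioTruth = field(default_factory=ScenarioTruth)


def make_toy_scenario(n_reactions: int, branching: float = 0.3,
                      currency_rate: float = 0.3,
                      seed: int = 0) -> ToyScenario:
    """Deterministically generate a toy scenario; see the module docstring.

    ``branching`` is the probability that a reaction starts a side branch
    from an already-produced metabolite instead of extending the main
    chain; ``currency_rate`` the probability that a reaction additionally
    converts ATP to ADP (rendered as per-reaction currency replicas).
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if not 0.0 <= branching <= 1.0:
        raise ValueError("branching must be within [0, 1]")
    if not 0.0 <= currency_rate <= 1.0:
        raise ValueError("currency_rate must be within [0, 1]")
    rng = np.random.default_rng(seed)

    model = ModelDigest(name=f"toy{n_reactions}s{seed}")
    model.metabolites["M_met0_c"] = ModelMetabolite(
        "M_met0_c", "metabolite 0", "c")
    chain: list[str] = []        # reaction ids of the main chain, in order
    branches: list[tuple[str, int]] = []  # (reaction id, chain position)
    chain_mets = ["M_met0_c"]    # metabolite ids along the chain
    n_currency = 0
    n_met = 1

    def new_metabolite() -> str:
        nonlocal n_met
        met_id = f"M_met{n_met}_c"
        model.metabolites[met_id] = ModelMetabolite(
            met_id, f"metabolite {n_met}", "c")
        n_met += 1
        return met_id

    for j in range(1, n_reactions + 1):
        rid = f"R_rxn{j}"
        is_branch = j > 1 and rng.random() < branching
        if is_branch:
            source_pos = int(rng.integers(0, len(chain_mets)))
            source = chain_mets[source_pos]
        else:
            source_pos = len(chain_mets) - 1
            source = chain_mets[-1]
        product = new_metabolite()
        reaction = ModelReaction(
            id=rid, name=f"reaction {j}",
            reversible=bool(rng.random() < 0.3),
            substrates=[(source, 1.0)], products=[(product, 1.0)])
        if rng.random() < currency_rate:
            _ensure_currency_pair(model)
            reaction.substrates.append(("M_atp_c", 1.0))
            reaction.products.append(("M_adp_c", 1.0))
            n_currency += 2
        model.reactions[rid] = reaction
        if is_branch:
            branches.append((rid, source_pos))
        else:
            chain.append(rid)
            chain_mets.append(product)

    model.pathways = {"main chain": list(chain)}
    if branches:
        model.pathways["branches"] = [rid for rid, _ in branches]

    # wild type: full flux down the main chain, branches silent
    wild = {rid: 0.0 for rid in model.reactions}
    for rid in chain:
        wild[rid] = _WILD_FLUX
    # mutant: reroute the chain tail through the deepest-rooted branch,
    # or truncate the chain when no branch exists
    mutant = dict(wild)
    # only branches rooted strictly before the chain tip divert anything
    diverting = [b for b in branches if b[1] < len(chain)]
    if diverting:
        branch_id, source_pos = max(diverting, key=lambda b: (b[1], b[0]))
        rerouted = chain[source_pos:]
        for rid in rerouted:
            mutant[rid] = 0.0
        mutant[branch_id] = _WILD_FLUX
    else:
        rerouted = chain[-1:]
        mutant[chain[-1]] = 0.0
    conditions = GeneticConditions(knockouts=set(rerouted))

    # explicit currency list and an unreachable degree threshold keep the
    # generator's bookkeeping (truth counts) exact
    layout = generate_pathway_layout(
        model, list(model.reactions),
        currency_ids=("M_atp_c", "M_adp_c"),
        currency_degree_threshold=10**9)
    _assign_positions(layout, rng)

    mapping = build_mapping(layout, model.reactions, model.metabolites)

    truth = ScenarioTruth(
        nodes=n_reactions + n_met + n_currency,
        edges=sum(len(r.substrates) + len(r.products)
                  for r in model.reactions.values()),
        currency_replicas=n_currency,
        nonzero_wild_fluxes=len(chain))
    return ToyScenario(model, layout, mapping,
                       FluxDistribution(wild), FluxDistribution(mutant),
                       conditions, truth)


def _ensure_currency_pair(model: ModelDigest) -> None:
    if "M_atp_c" not in model.metabolites:
        model.metabolites["M_atp_c"] = ModelMetabolite("M_atp_c", "ATP", "c")
        model.metabolites["M_adp_c"] = ModelMetabolite("M_adp_c", "ADP", "c")


def _assign_positions(layout: MetabolicLayout, rng: np.random.Generator,
                      fix_fraction: float = 0.5) -> None:
    """Deterministic scattered coordinates for every node (round-trip tests
    need positioned, partially fixed layouts without running the embedder)."""
    for node_id in sorted(layout.node_ids()):
        node = (layout.metabolite_nodes.get(node_id)
                or layout.reaction_nodes.get(node_id))
        if node is None:
            continue
        node.position = (float(np.round(rng.uniform(0, 800), 3)),
                         float(np.round(rng.uniform(0, 600), 3)))
        node.fixed = bool(rng.random() < fix_fraction)


def case_study_knockouts() -> tuple[GeneticConditions, GeneticConditions]:
    """The two published knockout sets as genetic conditions:
    (succinate case, glycine case)."""
    return (GeneticConditions(knockouts=set(SUCCINATE_KNOCKOUTS)),
            GeneticConditions(knockouts=set(GLYCINE_KNOCKOUTS)))


# simplified stoichiometries of the published knockout reactions (protons
# and water trimmed where inessential); enough to embed each knockout set
# in a small, fully mapped layout
_CASE_REACTIONS = {
    "succinate": [
        ("R_GHMT2", True,
         ["M_ser_L_c", "M_thf_c"], ["M_gly_c", "M_mlthf_c", "M_h2o_c"]),
        ("R_THD2", False,
         ["M_nadph_c", "M_nad_c"], ["M_nadp_c", "M_nadh_c"]),
        ("R_SUCD1i", False,
         ["M_fad_c", "M_succ_c"], ["M_fadh2_c", "M_fum_c"]),
        ("R_TKT1", True,
         ["M_e4p_c", "M_xu5p_D_c"], ["M_f6p_c", "M_g3p_c"]),
        # context reactions so the knockouts sit in a connected pathway
        ("R_FUM", True, ["M_fum_c"], ["M_mal_L_c"]),
        ("R_SUCOAS", True, ["M_succoa_c"], ["M_succ_c"]),
    ],
    "glycine": [
        ("R_ICL", False, ["M_icit_c"], ["M_succ_c", "M_glx_c"]),
        ("R_GLYCL", False,
         ["M_gly_c", "M_nad_c", "M_thf_c"],
         ["M_nh4_c", "M_mlthf_c", "M_nadh_c", "M_co2_c"]),
        ("R_PPC", True, ["M_oaa_c", "M_pi_c"], ["M_pep_c", "M_hco3_c"]),
        ("R_GART", True,
         ["M_gar_c", "M_for_c", "M_atp_c"],
         ["M_fgam_c", "M_adp_c", "M_pi_c"]),
        ("R_MALS", False, ["M_glx_c", "M_accoa_c"], ["M_mal_L_c"]),
        ("R_GLYt", True, ["M_gly_e"], ["M_gly_c"]),
    ],
}


def case_study_scenario(case: str) -> tuple[MetabolicLayout, ModelMapping,
                                            GeneticConditions]:
    """A small fully mapped layout around one published knockout set.

    ``case`` is ``"succinate"`` or ``"glycine"``; returns (layout, mapping,
    conditions) ready for :func:`metavis.overlay.genetic_overlay`.
    """
    try:
        rows = _CASE_REACTIONS[case]
    except KeyError:
        raise ValueError(f"unknown case {case!r}; expected 'succinate' "
                         "or 'glycine'") from None
    model = ModelDigest(name=f"{case} case")
    for rid, reversible, subs, prods in rows:
        for met in subs + prods:
            model.metabolites.setdefault(
                met, ModelMetabolite(met, met[2:].rsplit("_", 1)[0],
                                     met.rsplit("_", 1)[-1]))
        model.reactions[rid] = ModelReaction(
            id=rid, name=rid[2:], reversible=reversible,
            substrates=[(m, 1.0) for m in subs],
            products=[(m, 1.0) for m in prods])
    layout = generate_pathway_layout(model, list(model.reactions))
    mapping = build_mapping(layout, model.reactions, model.metabolites)
    succinate, glycine = case_study_knockouts()
    conditions = succinate if case == "succinate" else glycine
    return layout, mapping, conditions


def write_scenario(scenario: ToyScenario, directory: str | Path) -> list[Path]:
    """Write a scenario to disk as SBML + XGMML + TSV files; returns the
    paths written."""
    from .io import write_sbml_model, write_xgmml
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    path = directory / "model.xml"
    with open(path, "w", encoding="utf-8") as fh:
        write_sbml_model(scenario.model, fh)
    written.append(path)

    path = directory / "layout.xgmml"
    with open(path, "wb") as fh:
        write_xgmml(scenario.layout, fh)
    written.append(path)

    for name, flux in (("wild.tsv", scenario.wild_flux),
                       ("mutant.tsv", scenario.mutant_flux)):
        path = directory / name
        with open(path, "w", encoding="utf-8") as fh:
            write_flux_tsv(flux, fh)
        written.append(path)

    path = directory / "conditions.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        write_conditions_tsv(scenario.conditions, fh)
    written.append(path)
    return written
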