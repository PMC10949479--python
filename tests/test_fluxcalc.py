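"""FBA / pFBA / FVA / ratio constraints / blocked reactions / yields."""

import numpy as np
import pytest

from bifidoflux import fluxcalc
from bifidoflux.netcore import (
    MediumSpec,
    Metabolite,
    MetabolicModel,
    RatioConstraint,
    Reaction,
    apply_medium,
    build_stoich_matrix,
)
from bifidoflux.synthetic_data import default_medium


def _chain_model(parallel=False):
    """EX_a (uptake <=10) -> a_c -> b_c -> EX_b, optionally two a->b paths."""
    mets = [Metabolite("a_e", compartment="e"), Metabolite("a_c"),
            Metabolite("b_c"), Metabolite("b_e", compartment="e")]
    rxns = [Reaction("EX_a", {"a_e": -1}, -10, 1000),
            Reaction("At", {"a_e": -1, "a_c": 1}, 0, 1000),
            Reaction("AB", {"a_c": -1, "b_c": 1}, 0, 1000),
            Reaction("Bt", {"b_c": -1, "b_e": 1}, 0, 1000),
            Reaction("EX_b", {"b_e": -1}, 0, 1000)]
    if parallel:
        mets.append(Metabolite("x_c"))
        rxns += [Reaction("AX", {"a_c": -1, "x_c": 1}, 0, 1000),
                 Reaction("XB", {"x_c": -1, "b_c": 1}, 0, 1000)]
    return MetabolicModel(id="chain", metabolites=mets, reactions=rxns,
                          objective_reaction_id="EX_b")


def test_fba_bound_limited_chain():
    sol = fluxcalc.fba(_chain_model(), "EX_b")
    assert sol.optimal and sol.mu == pytest.approx(10.0)
    S = build_stoich_matrix(_chain_model())
    v = np.array([sol.fluxes[r] for r in _chain_model().reaction_ids()])
    assert np.max(np.abs(S @ v)) <= 1e-6


def test_fba_nothing_to_eat(model):
    """All uptakes closed (the model's raw bounds) -> zero growth."""
    sol = fluxcalc.fba(model)
    assert sol.optimal and sol.mu == pytest.approx(0.0, abs=1e-9)


def test_fba_infeasible_reported_as_status():
    bad = _chain_model()
    bad.reaction("AB").lower_bound = 5.0  # force flux with uptake closed
    bad.reaction("AB").upper_bound = 5.0
    bad.reaction("EX_a").lower_bound = 0.0
    sol = fluxcalc.fba(bad, "EX_b")
    assert sol.status == "infeasible" and sol.mu is None


def test_pfba_prefers_shorter_of_two_optimal_routes():
    """A 2-step and a 3-step equivalent route both reach the optimum; the
    parsimonious solution leaves the longer route idle."""
    model = _chain_model(parallel=True)
    model.reactions.append(
        Reaction("XY", {"x_c": -1, "b_c": 1}, 0, 1000))  # unused duplicate
    model.reindex()
    sol = fluxcalc.pfba(model, "EX_b")
    assert sol.mu == pytest.approx(10.0)
    assert sol.fluxes["AB"] == pytest.approx(10.0, abs=1e-6)
    assert abs(sol.fluxes["AX"]) <= 1e-6


def test_pfba_equals_fba_on_single_path():
    model = _chain_model()
    fba_sol = fluxcalc.fba(model, "EX_b")
    pfba_sol = fluxcalc.pfba(model, "EX_b")
    for rid in model.reaction_ids():
        assert pfba_sol.fluxes[rid] == pytest.approx(fba_sol.fluxes[rid],
                                                     abs=1e-6)


def test_fva_parallel_paths_full_range():
    """Two equivalent routes: at fraction 1 each route ranges [0, total]."""
    model = _chain_model(parallel=True)
    ranges = fluxcalc.fva(model, "EX_b", fraction=1.0)
    assert ranges.minimum("AB") == pytest.approx(0.0, abs=1e-6)
    assert ranges.maximum("AB") == pytest.approx(10.0, abs=1e-6)
    assert ranges.minimum("EX_b") == pytest.approx(10.0, abs=1e-6)


def test_fva_single_chain_zero_width():
    ranges = fluxcalc.fva(_chain_model(), "EX_b", fraction=1.0)
    widths = ranges.ranges["max"] - ranges.ranges["min"]
    assert (widths.abs() <= 1e-6).all()


def test_fva_relaxing_fraction_never_shrinks_ranges(bounded_models):
    tight = fluxcalc.fva(bounded_models["lactose"], fraction=1.0)
    loose = fluxcalc.fva(bounded_models["lactose"], fraction=0.9)
    assert (loose.ranges["min"] <= tight.ranges["min"] + 1e-6).all()
    assert (loose.ranges["max"] >= tight.ranges["max"] - 1e-6).all()


def test_fva_contains_pfba_flux(bounded_models):
    bounded = bounded_models["3FL"]
    sol = fluxcalc.pfba(bounded)
    ranges = fluxcalc.fva(bounded, fraction=0.99)
    # compare against pFBA at the same retained fraction of the optimum
    for rid in bounded.reaction_ids():
        if sol.fluxes[rid] >= 0.99 * ranges.ranges.loc[rid, "min"] - 1e-6:
            assert sol.fluxes[rid] <= ranges.ranges.loc[rid, "max"] + 1e-6


def test_ratio_constraint_enforced(bounded_models):
    sol = fluxcalc.pfba(bounded_models["lactose"])
    assert sol.fluxes["EX_ac_e"] == pytest.approx(
        1.75 * sol.fluxes["EX_lac__L_e"], rel=1e-6)


def test_ratio_constraint_feasible_when_both_zero():
    model = _chain_model()
    model = fluxcalc.add_ratio_constraint(
        model, RatioConstraint("AB", "Bt", 2.0))
    model.reaction("EX_a").lower_bound = 0.0   # nothing to eat
    sol = fluxcalc.fba(model, "EX_b")
    assert sol.optimal and sol.mu == pytest.approx(0.0, abs=1e-9)


def test_ratio_constraint_missing_reaction():
    with pytest.raises(KeyError):
        fluxcalc.add_ratio_constraint(
            _chain_model(), RatioConstraint("AB", "nope", 1.0))


def test_ratio_constraint_never_beats_unconstrained(model):
    """The imposed ratio can only lower the optimal growth rate."""
    bounded = apply_medium(model, default_medium("lactose"))
    mu_free = fluxcalc.fba(bounded).mu
    for ratio in (1.75, 2.0, 2.5):
        constrained = fluxcalc.add_ratio_constraint(
            bounded, RatioConstraint("EX_ac_e", "EX_lac__L_e", ratio))
        assert fluxcalc.fba(constrained).mu <= mu_free + 1e-6


def test_blocked_reactions_dead_end():
    model = _chain_model()
    model.metabolites.append(Metabolite("dead_c"))
    model.reactions.append(Reaction("DEAD", {"a_c": -1, "dead_c": 1}))
    model.reindex()
    blocked = fluxcalc.blocked_reactions(model)
    assert blocked == {"DEAD"}


def test_blocked_reactions_after_branch_removal(model):
    """Removing the sialidase blocks the whole sialic-acid branch."""
    bounded = apply_medium(model, default_medium("6SL"))
    assert "NANA" not in fluxcalc.blocked_reactions(bounded)
    cut = bounded.copy()
    cut.reaction("SIAL").upper_bound = 0.0
    blocked = fluxcalc.blocked_reactions(cut)
    assert {"NANA", "NANK", "NANE"} <= blocked


def test_consistency_check_flags_expressed_but_blocked(model):
    """Gap report on the open reconstruction: everything connected is clean;
    stranding the fucose branch flags its expressed reactions."""
    rich = model.copy()
    for rxn in rich.exchanges():     # all substrates available
        rxn.lower_bound = -10.0
    all_genes = set(rich.genes)
    flagged = fluxcalc.consistency_check(rich, all_genes)
    assert [r for r in flagged if r != "SUCS"] == []  # stub is bounds-disabled
    cut = rich.copy()
    cut.reaction("12PPDt").upper_bound = 0.0   # strand the expressed branch
    flagged = fluxcalc.consistency_check(cut, all_genes)
    assert "LCARS" in flagged


def test_yields_definitions(bounded_models, media):
    bounded = bounded_models["3FL"]
    sol = fluxcalc.pfba(bounded)
    report = fluxcalc.compute_yields(sol, bounded, media["3FL"])
    uptake = abs(sol.fluxes["EX_fl3_e"])
    assert report.biomass_yield == pytest.approx(
        sol.mu / (uptake * 488.44 / 1000.0))
    # 1,2-PD yield positive on the fucosylated substrate, succinate absent
    assert report.metabolite_yields["12ppd__R_e"] > 0
    assert report.metabolite_yields.get("succ_e", 0.0) == 0.0


def test_yields_scale_invariance(model, media):
    """Doubling the uptake bound doubles mu and leaves yields unchanged."""
    medium = default_medium("lactose")
    base = apply_medium(model, medium)
    sol1 = fluxcalc.fba(base)
    doubled = default_medium("lactose")
    doubled.base_uptake_bound *= 2
    sol2 = fluxcalc.fba(apply_medium(model, doubled))
    assert sol2.mu == pytest.approx(2 * sol1.mu, rel=1e-6)
    y1 = fluxcalc.compute_yields(sol1, base, medium)
    y2 = fluxcalc.compute_yields(sol2, base, doubled)
    assert y2.biomass_yield == pytest.approx(y1.biomass_yield, rel=1e-6)


def test_mass_balance_on_fixture_solutions(bounded_models):
    for condition, bounded in bounded_models.items():
        sol = fluxcalc.pfba(bounded)
        S = build_stoich_matrix(bounded)
        v = np.array([sol.fluxes[r] for r in bounded.reaction_ids()])
        assert np.max(np.abs(S @ v)) <= 1e-6, condition
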