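"""Expression thresholding and GIMME context-model extraction."""

import pytest

from bifidoflux import fluxcalc, gimme
from bifidoflux.netcore import (
    Metabolite,
    MetabolicModel,
    Reaction,
    parse_gpr,
)
from bifidoflux.synthetic_data import CONDITIONS


def test_threshold_percentile_interpolation():
    profile = gimme.ExpressionProfile("x", {f"g{i}": float(i)
                                            for i in range(1, 11)})
    assert gimme.expression_threshold(profile, 0) == 1.0
    assert gimme.expression_threshold(profile, 100) == 10.0
    four = gimme.ExpressionProfile("x", {"a": 10, "b": 20, "c": 30, "d": 40})
    assert gimme.expression_threshold(four, 30) == pytest.approx(19.0)


def test_threshold_rejects_empty_profile():
    with pytest.raises(ValueError):
        gimme.expression_threshold(gimme.ExpressionProfile("x", {}), 30)


def test_reaction_expression_or_and_undefined(model, profiles):
    rxn_expr = gimme.reaction_expression(model, profiles["lactose"])
    values = profiles["lactose"].values
    # OR -> highest gene (beta-galactosidase isozymes)
    assert rxn_expr["LACZ"] == pytest.approx(
        max(values["Blon_9010"], values["Blon_9011"]))
    # AND -> lowest gene (ABC transporter complex)
    assert rxn_expr["FL3abc"] == pytest.approx(
        min(values["Blon_9003"], values["Blon_9004"]))
    # exchanges have no gene association -> undefined
    assert rxn_expr["EX_lcts_e"] is None


def _two_path_model():
    """Two equivalent routes a->b; one is transcriptionally silent."""
    mets = [Metabolite("a_e", compartment="e"), Metabolite("a_c"),
            Metabolite("b_c"), Metabolite("b_e", compartment="e")]
    rxns = [Reaction("EX_a", {"a_e": -1}, -10, 1000),
            Reaction("At", {"a_e": -1, "a_c": 1}, 0, 1000),
            Reaction("HI", {"a_c": -1, "b_c": 1}, 0, 1000,
                     gpr=parse_gpr("gHI")),
            Reaction("LO", {"a_c": -1, "b_c": 1}, 0, 1000,
                     gpr=parse_gpr("gLO")),
            Reaction("Bt", {"b_c": -1, "b_e": 1}, 0, 1000),
            Reaction("EX_b", {"b_e": -1}, 0, 1000)]
    return MetabolicModel(id="twopath", metabolites=mets, reactions=rxns,
                          genes=["gHI", "gLO"],
                          objective_reaction_id="EX_b")


def test_gimme_deactivates_silent_parallel_path():
    model = _two_path_model()
    rxn_expr = {"HI": 100.0, "LO": 1.0}
    ctx = gimme.gimme_extract(model, rxn_expr, threshold=10.0,
                              biomass_fraction=1.0)
    assert ctx.deactivated_reactions == {"LO"}
    assert ctx.solution.mu == pytest.approx(10.0, abs=1e-6)
    assert ctx.inconsistency_score == pytest.approx(0.0, abs=1e-6)


def test_gimme_keeps_essential_low_expression_route():
    """A below-threshold reaction that is the sole route to biomass is
    retained (growth stays feasible) and scores a positive inconsistency."""
    model = _two_path_model()
    model.reactions = [r for r in model.reactions if r.id != "HI"]
    model.reindex()
    rxn_expr = {"LO": 1.0}
    ctx = gimme.gimme_extract(model, rxn_expr, threshold=10.0,
                              biomass_fraction=0.9)
    assert "LO" not in ctx.deactivated_reactions
    assert ctx.inconsistency_score > 0
    assert ctx.solution.mu >= 0.9 * 10.0 - 1e-6


def test_gimme_all_above_threshold_is_identity(model, bounded_models):
    bounded = bounded_models["lactose"]
    rxn_expr = {r.id: 100.0 for r in bounded.reactions}
    ctx = gimme.gimme_extract(bounded, rxn_expr, threshold=10.0)
    assert ctx.deactivated_reactions == set()
    assert ctx.inconsistency_score == pytest.approx(0.0, abs=1e-6)


def test_gimme_growth_preservation_on_fixture(bounded_models, profiles):
    for condition in CONDITIONS:
        bounded = bounded_models[condition]
        mu_star = fluxcalc.fba(bounded).mu
        profile = profiles[condition]
        rxn_expr = gimme.reaction_expression(bounded, profile)
        threshold = gimme.expression_threshold(profile, 30)
        ctx = gimme.gimme_extract(bounded, rxn_expr, threshold,
                                  biomass_fraction=0.9, condition=condition)
        assert ctx.solution.mu >= 0.9 * mu_star - 1e-6
        # deactivation soundness: re-solving never uses deactivated reactions
        resolved = fluxcalc.pfba(ctx.model)
        for rid in ctx.deactivated_reactions:
            assert abs(resolved.fluxes[rid]) <= 1e-9


def test_gimme_lactose_deactivates_hmo_branches(bounded_models, profiles):
    bounded = bounded_models["lactose"]
    profile = profiles["lactose"]
    rxn_expr = gimme.reaction_expression(bounded, profile)
    threshold = gimme.expression_threshold(profile, 30)
    ctx = gimme.gimme_extract(bounded, rxn_expr, threshold,
                              condition="lactose")
    # fucose and sialic-acid feeder enzymes are transcriptionally silent on
    # lactose and carry no flux -> deactivated
    assert {"AFUC", "SIAL", "NANA"} <= ctx.deactivated_reactions


def test_threshold_monotonicity_sweep(bounded_models, profiles):
    """Below-threshold sets and inconsistency grow with the percentile."""
    bounded = bounded_models["3FL"]
    profile = profiles["3FL"]
    rxn_expr = gimme.reaction_expression(bounded, profile)
    previous_below: set = set()
    previous_score = -1.0
    for percentile in (10, 30, 50, 70):
        threshold = gimme.expression_threshold(profile, percentile)
        below = {rid for rid, x in rxn_expr.items()
                 if x is not None and x < threshold}
        assert previous_below <= below
        ctx = gimme.gimme_extract(bounded, rxn_expr, threshold)
        assert ctx.inconsistency_score >= previous_score - 1e-9
        previous_below = below
        previous_score = ctx.inconsistency_score


def test_context_report_bookkeeping(bounded_models, profiles, media):
    contexts = []
    for condition in CONDITIONS:
        bounded = bounded_models[condition]
        profile = profiles[condition]
        rxn_expr = gimme.reaction_expression(bounded, profile)
        threshold = gimme.expression_threshold(profile, 30)
        contexts.append(gimme.gimme_extract(bounded, rxn_expr, threshold,
                                            condition=condition))
    report = gimme.context_report(contexts, media=media)
    assert len(report) == 4
    for ctx, (_, row) in zip(contexts, report.iterrows()):
        assert row["n_deactivated"] == len(ctx.deactivated_reactions)
    # context-model biomass yields stay within 10% of the generic model's
    for ctx, (_, row) in zip(contexts, report.iterrows()):
        base = bounded_models[ctx.condition]
        mu_star = fluxcalc.fba(base).mu
        generic_yield = mu_star / (media[ctx.condition].uptake_bound
                                   * media[ctx.condition].molecular_weight
                                   / 1000.0)
        assert abs(row["biomass_yield"] - generic_yield) <= \
            0.10 * generic_yield


def test_expression_tsv_roundtrip(profiles, tmp_path):
    path = tmp_path / "expr.tsv"
    gimme.write_expression_tsv(list(profiles.values()), path)
    back = {p.condition: p for p in gimme.read_expression_tsv(path)}
    for condition, profile in profiles.items():
        assert back[condition].values.keys() == profile.values.keys()
        for gene, value in profile.values.items():
            assert back[condition].values[gene] == pytest.approx(value)
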