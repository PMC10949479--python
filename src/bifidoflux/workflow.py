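"""Per-condition pipeline orchestration.

Runs medium construction -> FBA/pFBA/FVA -> yields -> GIMME extraction ->
gene essentiality -> flux coupling network for each condition, writes the
report bundle (TSV tables, GraphML networks, Escher-style flux JSON), and
aggregates cross-condition comparisons (context report, essential-gene
intersection, consensus network with Dn rewiring scores).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import couplenet, essentiality, evalmetrics, fluxcalc, gimme, modelio
from .netcore import MediumSpec, MetabolicModel, RatioConstraint, apply_medium
from .synthetic_data import (
    CONDITIONS,
    DEFAULT_GROWTH_DESIGN,
    END_PRODUCT_EXCHANGES,
    FixtureOptions,
    build_bifid_fixture,
    build_expression_fixture,
    build_growth_table,
    default_medium,
)

log = logging.getLogger("bifidoflux")

__all__ = ["RunConfig", "run_condition", "run_all", "make_fixtures",
           "predict_growth", "evaluate_growth"]

#: acetate:lactate = 3.5:2, the ratio adopted for all constrained analyses
DEFAULT_RATIO = 1.75


@dataclass
class RunConfig:
    model_path: str | Path | None = None
    expression_path: str | Path | None = None
    phenotype_path: str | Path | None = None
    output_dir: str | Path = "results"
    conditions: tuple[str, ...] = CONDITIONS
    ratio_value: float | None = DEFAULT_RATIO
    fva_fraction: float = 0.99
    gimme_percentile: float = 30.0
    gimme_biomass_fraction: float = 0.9
    seed: int = 2024

    def load_model(self) -> MetabolicModel:
        if self.model_path is None:
            return build_bifid_fixture(FixtureOptions(random_seed=self.seed))
        return modelio.read_model(self.model_path, "json")

    def load_profiles(self) -> dict[str, gimme.ExpressionProfile]:
        if self.expression_path is None:
            model = self.load_model()
            opts = FixtureOptions(random_seed=self.seed)
            return {c: build_expression_fixture(model, c, opts)
                    for c in self.conditions}
        return {p.condition: p
                for p in gimme.read_expression_tsv(self.expression_path)}


def _constrained(model: MetabolicModel, ratio: float | None
                 ) -> MetabolicModel:
    if ratio is None:
        return model
    return fluxcalc.add_ratio_constraint(
        model, RatioConstraint("EX_ac_e", "EX_lac__L_e", ratio))


def run_condition(config: RunConfig, condition: str,
                  model: MetabolicModel | None = None,
                  profile: gimme.ExpressionProfile | None = None) -> dict:
    """Run the full pipeline for one condition; write the report bundle."""
    t0 = time.time()
    model = model if model is not None else config.load_model()
    profile = profile if profile is not None else \
        config.load_profiles()[condition]
    outdir = Path(config.output_dir) / condition
    outdir.mkdir(parents=True, exist_ok=True)

    medium = default_medium(condition)
    bounded = _constrained(apply_medium(model, medium), config.ratio_value)

    solution = fluxcalc.pfba(bounded)
    log.info("stage=pfba condition=%s status=%s elapsed=%.2fs",
             condition, solution.status, time.time() - t0)
    if not solution.optimal:
        raise fluxcalc.SolverError(
            f"pFBA {solution.status} in condition {condition!r}")
    flux_range = fluxcalc.fva(bounded, fraction=config.fva_fraction)
    fluxcalc.write_flux_tsv(solution, outdir / "fluxes.tsv", flux_range)
    fluxcalc.write_escher_json(solution, outdir / "fluxes.escher.json")

    yields = fluxcalc.compute_yields(
        solution, bounded, medium, product_exchanges=END_PRODUCT_EXCHANGES)
    yrows = [{"quantity": "biomass_yield_gdcw_per_g",
              "value": yields.biomass_yield}]
    yrows += [{"quantity": f"yield_g_per_gdcw_{met}", "value": val}
              for met, val in sorted(yields.metabolite_yields.items())]
    pd.DataFrame(yrows).to_csv(outdir / "yields.tsv", sep="\t", index=False,
                               float_format="%.10g")

    rxn_expr = gimme.reaction_expression(bounded, profile)
    threshold = gimme.expression_threshold(profile, config.gimme_percentile)
    context = gimme.gimme_extract(
        bounded, rxn_expr, threshold,
        biomass_fraction=config.gimme_biomass_fraction, condition=condition)
    log.info("stage=gimme condition=%s deactivated=%d elapsed=%.2fs",
             condition, len(context.deactivated_reactions), time.time() - t0)
    pd.DataFrame(sorted(context.deactivated_reactions),
                 columns=["deactivated_reaction"]).to_csv(
        outdir / "deactivated.tsv", sep="\t", index=False)

    scan = essentiality.single_gene_deletions({condition: context.model})
    classified = essentiality.classify_essentiality(scan)
    classified.to_csv(outdir / "essentiality.tsv", sep="\t", index=False,
                      float_format="%.10g")

    coupling = couplenet.fca(context.model)
    network = couplenet.build_coupled_network(coupling,
                                              END_PRODUCT_EXCHANGES)
    metrics = couplenet.topology_metrics(network)
    couplenet.write_graphml(network, outdir / "coupled_network.graphml",
                            context.model)
    log.info("stage=fca condition=%s nodes=%d edges=%d elapsed=%.2fs",
             condition, metrics["n_nodes"], metrics["n_edges"],
             time.time() - t0)
    pd.DataFrame([{
        "condition": condition,
        "n_nodes": metrics["n_nodes"],
        "n_edges": metrics["n_edges"],
        "clustering_coefficient": metrics["clustering_coefficient"],
        "power_law_alpha": metrics["power_law_alpha"],
    }]).to_csv(outdir / "topology.tsv", sep="\t", index=False,
               float_format="%.6g")

    return {
        "condition": condition,
        "medium": medium,
        "solution": solution,
        "flux_range": flux_range,
        "yields": yields,
        "context": context,
        "essentiality": classified,
        "coupling": coupling,
        "network": network,
        "topology": metrics,
    }


def run_all(config: RunConfig) -> dict:
    """Run every condition and the cross-condition comparisons."""
    if len(config.conditions) < 2:
        raise ValueError("run_all needs at least two conditions")
    model = config.load_model()
    profiles = config.load_profiles()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundles = {c: run_condition(config, c, model=model, profile=profiles[c])
               for c in config.conditions}

    contexts = [bundles[c]["context"] for c in config.conditions]
    media = {c: bundles[c]["medium"] for c in config.conditions}
    report = gimme.context_report(contexts, media=media,
                                  product_exchanges=END_PRODUCT_EXCHANGES)
    report.to_csv(outdir / "context_report.tsv", sep="\t", index=False,
                  float_format="%.10g")

    classified = pd.concat([bundles[c]["essentiality"]
                            for c in config.conditions], ignore_index=True)
    common = essentiality.essential_intersection(classified)
    pd.DataFrame(sorted(common), columns=["gene"]).to_csv(
        outdir / "essential_common.tsv", sep="\t", index=False)

    networks = [bundles[c]["network"] for c in config.conditions]
    scores, consensus = couplenet.dn_rewiring(networks,
                                              labels=list(config.conditions))
    couplenet.write_graphml(consensus, outdir / "consensus_network.graphml",
                            model)
    pd.DataFrame([{"node": s.node, "dn_score": s.dn_score,
                   "n_networks": sum(s.presence)} for s in scores]).to_csv(
        outdir / "dn_scores.tsv", sep="\t", index=False,
        float_format="%.10g")
    return {"bundles": bundles, "context_report": report,
            "essential_common": common, "dn_scores": scores,
            "consensus": consensus}


# --------------------------------------------------------------------------
# Growth evaluation


def predict_growth(model: MetabolicModel,
                   media: dict[str, MediumSpec | None],
                   ratio: float | None = None) -> dict[str, float]:
    """Maximum growth rate per substrate; 0 when the substrate is absent."""
    predictions = {}
    for substrate, medium in media.items():
        if medium is None or not model.has_reaction(medium.carbon_source_id):
            predictions[substrate] = 0.0
            continue
        bounded = _constrained(apply_medium(model, medium), ratio)
        sol = fluxcalc.fba(bounded)
        predictions[substrate] = sol.mu if (sol.optimal and sol.mu) else 0.0
    return predictions


def evaluate_growth(model: MetabolicModel, table: pd.DataFrame,
                    media: dict, ratio: float | None = None) -> dict:
    """Confusion counts and F/MCC/RMSE against a phenotype table."""
    observations = [
        evalmetrics.GrowthObservation(
            substrate=row["substrate"],
            observed_growth=bool(row["observed_growth"]),
            observed_rate=None if pd.isna(row["observed_rate"])
            else float(row["observed_rate"]),
        )
        for _, row in table.iterrows()
    ]
    predictions = predict_growth(model, media, ratio=ratio)
    counts = evalmetrics.compare_growth(predictions, observations)
    observed_rates = {o.substrate: o.observed_rate for o in observations
                      if o.observed_rate is not None}
    rmse = (evalmetrics.rmse_growth(predictions, observed_rates)
            if observed_rates else None)
    return {
        "confusion": counts,
        "f_score": evalmetrics.f_score(counts),
        "mcc": evalmetrics.mcc(counts),
        "rmse": rmse,
        "predictions": predictions,
    }


# --------------------------------------------------------------------------
# Fixture workspace


def make_fixtures(output_dir, seed: int = 2024) -> dict:
    """Write a complete test workspace: model JSON, expression and
    phenotype TSVs."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    opts = FixtureOptions(random_seed=seed)
    model = build_bifid_fixture(opts)
    modelio.write_model(model, outdir / "model.json", "json")
    profiles = [build_expression_fixture(model, c, opts) for c in CONDITIONS]
    gimme.write_expression_tsv(profiles, outdir / "expression.tsv")
    table, media = build_growth_table(opts=opts)
    table.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    return {"model": model, "profiles": profiles, "table": table,
            "media": media}
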