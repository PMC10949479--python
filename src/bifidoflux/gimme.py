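"""Transcriptomics integration via the GIMME algorithm.

Maps gene expression onto reactions through GPR rules (AND -> lowest
expressed gene, OR -> highest), thresholds the per-gene distribution at a
percentile (default the 30th), and extracts a context-specific model by
minimizing flux through below-threshold reactions while preserving a
fraction of the optimal biomass flux:

    min   sum_i  (t - x_i) * |v_i|      over reactions with x_i < t
    s.t.  S v = 0,  lb <= v <= ub,  mu >= f * mu*

Reactions below threshold that carry zero flux in the optimum are
deactivated (bounds set to 0) in the returned context model; below-threshold
reactions that must carry flux to sustain growth are retained, so every
context model still grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fluxcalc
from .fluxcalc import SOLVER_TOL, ZERO_TOL, FluxSolution, SolverError, fba
from .netcore import MetabolicModel, gpr_expression

__all__ = [
    "ExpressionProfile",
    "ContextModel",
    "reaction_expression",
    "expression_threshold",
    "gimme_extract",
    "context_report",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionProfile:
    """Normalized counts per gene for one growth condition."""

    condition: str
    values: dict[str, float]

    def __post_init__(self):
        bad = {g: v for g, v in self.values.items() if v < 0}
        if bad:
            raise ValueError(f"negative expression values: {bad}")


@dataclass
class ContextModel:
    base_model_id: str
    condition: str
    threshold_value: float
    deactivated_reactions: set[str]
    inconsistency_score: float
    solution: FluxSolution
    model: MetabolicModel


def reaction_expression(model: MetabolicModel, profile: ExpressionProfile
                        ) -> dict[str, float | None]:
    """Per-reaction expression via GPR min/max recursion.

    Reactions without a gene association map to None and are never
    penalized or deactivated downstream.
    """
    return {r.id: gpr_expression(r.gpr, profile.values)
            for r in model.reactions}


def expression_threshold(profile: ExpressionProfile,
                         percentile: float = 30.0) -> float:
    """Percentile of the per-gene expression distribution.

    Linear interpolation between order statistics; percentile 0 is the
    minimum, 100 the maximum.
    """
    if not profile.values:
        raise ValueError("empty expression profile")
    if not (0 <= percentile <= 100):
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(list(profile.values.values()), percentile))


def gimme_extract(model: MetabolicModel,
                  rxn_expr: dict[str, float | None],
                  threshold: float,
                  biomass_fraction: float = 0.9,
                  condition: str = "") -> ContextModel:
    """Extract a context-specific model by penalized flux minimization."""
    if not (0 < biomass_fraction <= 1):
        raise ValueError("biomass_fraction must be in (0, 1]")
    objective = model.objective_reaction_id
    base = fba(model, objective)
    if not base.optimal or base.mu is None or base.mu <= ZERO_TOL:
        raise SolverError(
            "GIMME requires a growing base model "
            f"(status {base.status}, mu {base.mu})"
        )
    mu_star = base.mu
    n = len(model.reactions)
    rxn_ids = model.reaction_ids()
    weights = np.zeros(n)
    for j, rid in enumerate(rxn_ids):
        x = rxn_expr.get(rid)
        if x is not None and x < threshold:
            weights[j] = threshold - x
    A_split, bounds = fluxcalc._split_system(model)
    b_eq = np.zeros(A_split.shape[0])
    j_obj = rxn_ids.index(objective)
    A_ub = np.zeros((1, 2 * n))
    A_ub[0, j_obj] = -1.0
    A_ub[0, n + j_obj] = 1.0
    target = biomass_fraction * mu_star
    b_ub = np.array([-(target - SOLVER_TOL * max(1.0, abs(target)))])
    c = np.concatenate([weights, weights])
    status, res = fluxcalc._solve(c, A_split, b_eq, bounds,
                                  A_ub=A_ub, b_ub=b_ub)
    if status != "optimal":
        raise SolverError(
            f"GIMME LP {status}; try a lower biomass_fraction than "
            f"{biomass_fraction}"
        )
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: float(x) for rid, x in zip(rxn_ids, v)}
    solution = FluxSolution(status="optimal", mu=float(v[j_obj]),
                            fluxes=fluxes, objective_id=objective)
    deactivated = {
        rid for j, rid in enumerate(rxn_ids)
        if weights[j] > 0 and abs(v[j]) <= ZERO_TOL
    }
    context = model.copy()
    for rxn in context.reactions:
        if rxn.id in deactivated:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return ContextModel(
        base_model_id=model.id,
        condition=condition,
        threshold_value=threshold,
        deactivated_reactions=deactivated,
        inconsistency_score=float(res.fun),
        solution=solution,
        model=context,
    )


def context_report(context_models: list[ContextModel],
                   media: dict | None = None,
                   product_exchanges: list[str] | None = None
                   ) -> pd.DataFrame:
    """Per-condition summary of the context-specific models.

    Reports deactivated-reaction counts, inconsistency scores, and the
    context model's own optimal growth; when per-condition media are given
    the biomass and end-product yields (from a pFBA solution) are added.
    """
    if not context_models:
        raise ValueError("need at least one context model")
    rows = []
    for ctx in context_models:
        row = {
            "condition": ctx.condition,
            "threshold": ctx.threshold_value,
            "n_deactivated": len(ctx.deactivated_reactions),
            "inconsistency": ctx.inconsistency_score,
            "mu_gimme": ctx.solution.mu,
        }
        sol = fluxcalc.pfba(ctx.model)
        row["mu_context"] = sol.mu
        if media is not None and ctx.condition in media and sol.optimal:
            report = fluxcalc.compute_yields(
                sol, ctx.model, media[ctx.condition],
                product_exchanges=product_exchanges)
            row["biomass_yield"] = report.biomass_yield
            for met, value in sorted(report.metabolite_yields.items()):
                row[f"yield_{met}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# TSV I/O


def read_expression_tsv(path) -> list[ExpressionProfile]:
    """Expression matrix TSV (rows genes, columns conditions) -> profiles."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return [ExpressionProfile(condition=str(col),
                              values=frame[col].dropna().to_dict())
            for col in frame.columns]


def write_expression_tsv(profiles: list[ExpressionProfile], path) -> None:
    frame = pd.DataFrame({p.condition: pd.Series(p.values)
                          for p in profiles})
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.10g")
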