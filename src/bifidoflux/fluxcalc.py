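"""Linear-programming engines for constraint-based simulation.

Implements flux balance analysis (FBA), parsimonious FBA (pFBA), flux
variability analysis (FVA), end-product ratio constraints, blocked-reaction
detection, expression/flux consistency checks, and yield calculations, all
on top of scipy's HiGHS solver.

The steady-state problem is

    max  c·v
    s.t. S·v = 0          (mass balance)
         v_num - r·v_den = 0   for each ratio constraint
         lb <= v <= ub

with fluxes in mmol·gDCW⁻¹·h⁻¹ and the biomass objective in h⁻¹.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .netcore import (
    MediumSpec,
    MetabolicModel,
    RatioConstraint,
    build_stoich_matrix,
    formula_weight,
    gpr_active,
)

__all__ = [
    "FluxSolution",
    "FluxRange",
    "YieldReport",
    "SolverError",
    "fba",
    "pfba",
    "fva",
    "add_ratio_constraint",
    "blocked_reactions",
    "consistency_check",
    "compute_yields",
    "write_flux_tsv",
    "write_escher_json",
]

#: solver-level feasibility/optimality tolerance
SOLVER_TOL = 1e-9
#: downstream zero test, one order of magnitude looser than the solver
ZERO_TOL = 1e-6


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasible/unbounded."""


@dataclass
class FluxSolution:
    status: str                      # "optimal" | "infeasible" | "unbounded"
    mu: float | None                 # objective value (None unless optimal)
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_id: str = ""
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FluxRange:
    """Per-reaction flux min/max at a fixed fraction of the optimum."""

    ranges: pd.DataFrame             # index: reaction id; columns: min, max
    optimality_fraction: float
    objective_value: float

    def minimum(self, rxn_id: str) -> float:
        return float(self.ranges.loc[rxn_id, "min"])

    def maximum(self, rxn_id: str) -> float:
        return float(self.ranges.loc[rxn_id, "max"])


@dataclass
class YieldReport:
    biomass_yield: float | None          # gDCW per g substrate
    metabolite_yields: dict[str, float]  # g per gDCW
    substrate_exchange: str
    flagged: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# LP assembly


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded",
           4: "numerical trouble"}


def _equalities(model: MetabolicModel):
    """Mass-balance rows plus one homogeneous row per ratio constraint."""
    S = build_stoich_matrix(model)
    if not model.ratio_constraints:
        return S
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    extra = np.zeros((len(model.ratio_constraints), S.shape[1]))
    for k, rc in enumerate(model.ratio_constraints):
        extra[k, rxn_index[rc.numerator_reaction]] = 1.0
        extra[k, rxn_index[rc.denominator_reaction]] = -rc.ratio
    return np.vstack([S, extra])


def _solve(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    status = _STATUS.get(res.status, "unknown")
    if status not in ("optimal", "infeasible", "unbounded"):
        raise SolverError(f"LP solver failure: {res.message}")
    return status, res


def fba(model: MetabolicModel, objective: str | None = None,
        direction: str = "max") -> FluxSolution:
    """Flux balance analysis: optimize one reaction's flux at steady state."""
    objective = objective or model.objective_reaction_id
    if not model.has_reaction(objective):
        raise KeyError(f"objective reaction {objective!r} not in model")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    n = len(model.reactions)
    A_eq = _equalities(model)
    b_eq = np.zeros(A_eq.shape[0])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    sign = -1.0 if direction == "max" else 1.0
    j_obj = model.reaction_ids().index(objective)
    c = np.zeros(n)
    c[j_obj] = sign
    status, res = _solve(c, A_eq, b_eq, bounds)
    if status != "optimal":
        return FluxSolution(status=status, mu=None, objective_id=objective,
                            message=res.message)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxSolution(status="optimal", mu=float(res.x[j_obj]),
                        fluxes=fluxes, objective_id=objective)


def _split_system(model: MetabolicModel):
    """Split v = v+ - v- (both >= 0) for L1-norm objectives.

    Returns (A_eq over 2n split vars, bounds, mapping back).  Column j is
    the forward half of reaction j, column n+j the reverse half.
    """
    A = _equalities(model)
    n = A.shape[1]
    A_split = np.hstack([A, -A])
    bounds = []
    for r in model.reactions:
        bounds.append((max(0.0, r.lower_bound), max(0.0, r.upper_bound)))
    for r in model.reactions:
        bounds.append((max(0.0, -r.upper_bound), max(0.0, -r.lower_bound)))
    return A_split, bounds


def pfba(model: MetabolicModel, objective: str | None = None) -> FluxSolution:
    """Parsimonious FBA: fix the FBA optimum, minimize total |flux|.

    Stage 1 is a plain FBA maximization; stage 2 fixes the objective at its
    optimum (with a 1e-9 slack to avoid floating-point infeasibility) and
    minimizes the sum of absolute fluxes over reversibles split into
    nonnegative halves, suppressing futile cycles.
    """
    objective = objective or model.objective_reaction_id
    stage1 = fba(model, objective, "max")
    if not stage1.optimal:
        return stage1
    mu_star = stage1.mu
    n = len(model.reactions)
    j_obj = model.reaction_ids().index(objective)
    A_split, bounds = _split_system(model)
    b_eq = np.zeros(A_split.shape[0])
    # objective >= mu* - slack as an upper-bound row on -(v+ - v-)_obj
    A_ub = np.zeros((1, 2 * n))
    A_ub[0, j_obj] = -1.0
    A_ub[0, n + j_obj] = 1.0
    b_ub = np.array([-(mu_star - SOLVER_TOL)])
    c = np.ones(2 * n)
    status, res = _solve(c, A_split, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
    if status != "optimal":
        raise SolverError(
            "pFBA stage 2 infeasible at the fixed optimum; "
            "tolerance misconfiguration suspected"
        )
    v = res.x[:n] - res.x[n:]
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    return FluxSolution(status="optimal", mu=float(v[j_obj]),
                        fluxes=fluxes, objective_id=objective)


def fva(model: MetabolicModel, objective: str | None = None,
        fraction: float = 0.99,
        reactions: list[str] | None = None) -> FluxRange:
    """Flux variability analysis at a fraction of the FBA optimum."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    objective = objective or model.objective_reaction_id
    stage1 = fba(model, objective, "max")
    if not stage1.optimal:
        raise SolverError(f"FVA base problem {stage1.status}")
    mu_star = stage1.mu
    n = len(model.reactions)
    rxn_ids = model.reaction_ids()
    j_obj = rxn_ids.index(objective)
    A_eq = _equalities(model)
    b_eq = np.zeros(A_eq.shape[0])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    # c·v >= fraction*mu* (minus slack) as -v_obj <= -target
    target = fraction * mu_star - SOLVER_TOL * max(1.0, abs(mu_star))
    A_ub = np.zeros((1, n))
    A_ub[0, j_obj] = -1.0
    b_ub = np.array([-target])
    wanted = reactions if reactions is not None else rxn_ids
    rows = {}
    c = np.zeros(n)
    for rid in wanted:
        j = rxn_ids.index(rid)
        c[:] = 0.0
        c[j] = 1.0
        lo_status, lo = _solve(c, A_eq, b_eq, bounds, A_ub, b_ub)
        c[j] = -1.0
        hi_status, hi = _solve(c, A_eq, b_eq, bounds, A_ub, b_ub)
        vmin = float(lo.x[j]) if lo_status == "optimal" else -math.inf
        vmax = float(hi.x[j]) if hi_status == "optimal" else math.inf
        rows[rid] = (min(vmin, vmax), max(vmin, vmax))
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["min", "max"])
    return FluxRange(ranges=frame, optimality_fraction=fraction,
                     objective_value=mu_star)


def add_ratio_constraint(model: MetabolicModel,
                         rc: RatioConstraint) -> MetabolicModel:
    """Copy of the model with v_num - ratio*v_den = 0 appended."""
    for rid in (rc.numerator_reaction, rc.denominator_reaction):
        if not model.has_reaction(rid):
            raise KeyError(f"ratio constraint reaction {rid!r} not in model")
    out = model.copy()
    out.ratio_constraints.append(rc)
    return out


def blocked_reactions(model: MetabolicModel,
                      tol: float = ZERO_TOL) -> set[str]:
    """Reactions that cannot carry flux under the model's own bounds.

    A reaction is blocked when its unconstrained-objective FVA range is
    [0, 0] within tolerance.
    """
    n = len(model.reactions)
    A_eq = _equalities(model)
    b_eq = np.zeros(A_eq.shape[0])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    blocked = set()
    c = np.zeros(n)
    for j, rxn in enumerate(model.reactions):
        c[:] = 0.0
        c[j] = -1.0
        status, res = _solve(c, A_eq, b_eq, bounds)
        vmax = float(res.x[j]) if status == "optimal" else math.inf
        if abs(vmax) > tol:
            continue
        c[j] = 1.0
        status, res = _solve(c, A_eq, b_eq, bounds)
        vmin = float(res.x[j]) if status == "optimal" else -math.inf
        if abs(vmin) <= tol:
            blocked.add(rxn.id)
    return blocked


def consistency_check(model: MetabolicModel, expressed_genes: set[str],
                      biomass_fraction: float = 0.0,
                      tol: float = ZERO_TOL) -> list[str]:
    """Expressed-but-blocked reactions: gap report for a reconstruction.

    Lists reactions whose GPR is satisfied by the expressed gene set but
    which cannot carry flux while biomass stays at or above
    ``biomass_fraction`` of its optimum.  Genes outside the model are
    ignored with a warning.
    """
    import warnings

    extra = expressed_genes - set(model.genes)
    if extra:
        warnings.warn(
            f"{len(extra)} expressed genes not in model: {sorted(extra)[:5]}..."
        )
    deleted = set(model.genes) - expressed_genes
    candidates = [
        r for r in model.reactions
        if not r.gpr.is_empty and gpr_active(r.gpr, deleted)
    ]
    n = len(model.reactions)
    rxn_ids = model.reaction_ids()
    A_eq = _equalities(model)
    b_eq = np.zeros(A_eq.shape[0])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    A_ub = b_ub = None
    if biomass_fraction > 0 and model.objective_reaction_id:
        base = fba(model)
        if not base.optimal or base.mu is None:
            raise SolverError("consistency check: base FBA not optimal")
        j_obj = rxn_ids.index(model.objective_reaction_id)
        A_ub = np.zeros((1, n))
        A_ub[0, j_obj] = -1.0
        b_ub = np.array([-(biomass_fraction * base.mu - SOLVER_TOL)])
    inconsistent = []
    c = np.zeros(n)
    for rxn in candidates:
        j = rxn_ids.index(rxn.id)
        c[:] = 0.0
        c[j] = -1.0
        status, res = _solve(c, A_eq, b_eq, bounds, A_ub, b_ub)
        vmax = float(res.x[j]) if status == "optimal" else math.inf
        if abs(vmax) > tol:
            continue
        c[j] = 1.0
        status, res = _solve(c, A_eq, b_eq, bounds, A_ub, b_ub)
        vmin = float(res.x[j]) if status == "optimal" else -math.inf
        if abs(vmin) <= tol:
            inconsistent.append(rxn.id)
    return inconsistent


# --------------------------------------------------------------------------
# Yields


def compute_yields(solution: FluxSolution, model: MetabolicModel,
                   medium: MediumSpec,
                   product_exchanges: list[str] | None = None) -> YieldReport:
    """Biomass and end-product yields from an optimal flux solution.

    biomass_yield = mu / (|uptake| * MW_substrate / 1000)   [gDCW / g]
    metabolite yield = (export flux * MW / 1000) / mu        [g / gDCW]

    Molecular weights of products are derived from metabolite formulas.
    """
    if not solution.optimal or solution.mu is None:
        raise ValueError("yields require an optimal solution")
    flagged: list[str] = []
    uptake = solution.fluxes.get(medium.carbon_source_id, 0.0)
    mu = solution.mu
    if abs(uptake) <= ZERO_TOL:
        flagged.append("no substrate uptake; biomass yield undefined")
        biomass_yield = None
    else:
        biomass_yield = mu / (abs(uptake) * medium.molecular_weight / 1000.0)
    if product_exchanges is None:
        product_exchanges = [
            r.id for r in model.exchanges()
            if solution.fluxes.get(r.id, 0.0) > ZERO_TOL
            and r.id != medium.carbon_source_id
        ]
    met_yields: dict[str, float] = {}
    for ex_id in product_exchanges:
        rxn = model.reaction(ex_id)
        met = model.metabolite(next(iter(rxn.stoichiometry)))
        export = max(0.0, solution.fluxes.get(ex_id, 0.0))
        if mu <= ZERO_TOL:
            flagged.append(f"{ex_id}: mu = 0, metabolite yield undefined")
            continue
        mw = formula_weight(met.formula) if met.formula else float("nan")
        met_yields[met.id] = export * mw / 1000.0 / mu
    return YieldReport(biomass_yield=biomass_yield,
                       metabolite_yields=met_yields,
                       substrate_exchange=medium.carbon_source_id,
                       flagged=flagged)


# --------------------------------------------------------------------------
# Exports


def write_flux_tsv(solution: FluxSolution, path,
                   flux_range: FluxRange | None = None) -> None:
    """Flux table as TSV: reaction id, flux, and FVA min/max if given."""
    frame = pd.DataFrame(
        {"flux": pd.Series(solution.fluxes)}
    )
    frame.index.name = "reaction"
    if flux_range is not None:
        frame = frame.join(flux_range.ranges)
    frame.to_csv(path, sep="\t", float_format="%.10g")


def write_escher_json(solution: FluxSolution, path) -> None:
    """Escher-compatible flat flux map {reaction_id: flux}."""
    with open(path, "w") as handle:
        json.dump({k: round(v, 10) for k, v in sorted(solution.fluxes.items())},
                  handle, indent=1, sort_keys=True)
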