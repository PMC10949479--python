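"""Single-gene deletion scans and essentiality classification.

A gene is knocked out by zeroing the bounds of every reaction whose GPR
rule evaluates false without it; growth is then re-solved by plain FBA
(classification depends only on the optimum).  A gene is essential when
the knockout growth ratio mu_ko / mu_wt falls to zero within tolerance,
and causes "reduced growth" when the ratio drops by more than the
reduction tolerance without reaching zero.
"""

from __future__ import annotations

import pandas as pd

from .fluxcalc import ZERO_TOL, SolverError, fba
from .netcore import MetabolicModel, gpr_active

__all__ = [
    "single_gene_deletions",
    "classify_essentiality",
    "essential_intersection",
]


def _knockout(model: MetabolicModel, gene: str) -> tuple[MetabolicModel, set]:
    disabled = {
        r.id for r in model.reactions
        if not r.gpr.is_empty and not gpr_active(r.gpr, {gene})
    }
    if not disabled:
        return model, disabled
    ko = model.copy()
    for rxn in ko.reactions:
        if rxn.id in disabled:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return ko, disabled


def single_gene_deletions(conditions: dict[str, MetabolicModel],
                          genes: list[str] | None = None) -> pd.DataFrame:
    """Scan all single-gene knockouts in each bounded condition model.

    Returns a DataFrame with one row per (gene, condition): the knockout
    growth ratio and the set of reactions the deletion disables.  Raises if
    any wild type fails to grow.
    """
    rows = []
    for condition, model in conditions.items():
        wt = fba(model)
        if not wt.optimal or wt.mu is None or wt.mu <= ZERO_TOL:
            raise SolverError(
                f"wild type does not grow in condition {condition!r} "
                f"(status {wt.status})"
            )
        scan_genes = genes if genes is not None else model.genes
        for gene in scan_genes:
            ko, disabled = _knockout(model, gene)
            if not disabled:
                mu_ko = wt.mu
            else:
                sol = fba(ko)
                mu_ko = sol.mu if (sol.optimal and sol.mu is not None) else 0.0
            ratio = max(0.0, mu_ko / wt.mu)
            rows.append({
                "gene": gene,
                "condition": condition,
                "mu_wt": wt.mu,
                "mu_ko": mu_ko,
                "growth_ratio": ratio,
                "n_disabled": len(disabled),
                "disabled_reactions": ";".join(sorted(disabled)),
            })
    return pd.DataFrame(rows)


def classify_essentiality(results: pd.DataFrame,
                          zero_tol: float = 1e-6,
                          reduction_tol: float = 0.05) -> pd.DataFrame:
    """Attach essentiality classes to a deletion scan.

    essential       growth_ratio <= zero_tol
    reduced_growth  zero_tol < growth_ratio < 1 - reduction_tol
    no_effect       otherwise
    """
    out = results.copy()

    def classify(ratio: float) -> str:
        if ratio <= zero_tol:
            return "essential"
        if ratio < 1.0 - reduction_tol:
            return "reduced_growth"
        return "no_effect"

    out["class"] = out["growth_ratio"].map(classify)
    return out


def essential_intersection(classified: pd.DataFrame) -> set[str]:
    """Genes essential in every condition ("common to all carbon sources")."""
    per_condition = [
        set(sub.loc[sub["class"] == "essential", "gene"])
        for _, sub in classified.groupby("condition")
    ]
    if not per_condition:
        return set()
    common = per_condition[0]
    for s in per_condition[1:]:
        common &= s
    return common


def summary_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per class and condition."""
    counts = (classified.groupby(["condition", "class"])["gene"]
              .count().rename("count").reset_index())
    totals = counts.groupby("condition")["count"].transform("sum")
    counts["percent"] = 100.0 * counts["count"] / totals
    return counts
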