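"""Model serialization: JSON dialect, tabular reaction list, SBML L3+FBC.

The JSON dialect is the package's native schema:

    {"id": ..., "objective": <reaction id>, "gam": <float>,
     "metabolites": [{"id", "name", "compartment", "formula"}, ...],
     "reactions":   [{"id", "name", "metabolites": {met: coeff},
                      "lower_bound", "upper_bound",
                      "gene_reaction_rule", "subsystem"}, ...],
     "genes": [...]}

The tabular format is a TSV with columns id / equation / lb / ub / gpr /
subsystem, using "a A + b B -> c C" (or "<->" for reversible) equations.
SBML Level 3 with the FBC package is read and written through cobrapy's
libsbml bindings; conversion between the two object models is lossless for
ids, bounds, stoichiometry and GPR logic.
"""

from __future__ import annotations

import json
import re

from .netcore import (
    EMPTY_GPR,
    Metabolite,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    parse_gpr,
)

__all__ = ["read_model", "write_model", "SchemaError"]

FORMATS = ("json", "sbml", "tabular")


class SchemaError(ValueError):
    """Input file does not conform to the documented schema."""


def read_model(path, format: str = "json") -> MetabolicModel:
    if format == "json":
        return _read_json(path)
    if format == "sbml":
        return _read_sbml(path)
    if format == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")


def write_model(model: MetabolicModel, path, format: str = "json") -> None:
    if format == "json":
        _write_json(model, path)
    elif format == "sbml":
        _write_sbml(model, path)
    elif format == "tabular":
        _write_tabular(model, path)
    else:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")


# --------------------------------------------------------------------------
# JSON dialect


def _read_json(path) -> MetabolicModel:
    with open(path) as handle:
        doc = json.load(handle)
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise SchemaError(f"missing required field {key!r}")
    mets = []
    for entry in doc["metabolites"]:
        if "id" not in entry:
            raise SchemaError("metabolite entry missing field 'id'")
        mets.append(Metabolite(
            id=entry["id"], name=entry.get("name", ""),
            formula=entry.get("formula", ""),
            compartment=entry.get("compartment", "c"),
        ))
    rxns = []
    for entry in doc["reactions"]:
        for key in ("id", "metabolites", "lower_bound", "upper_bound"):
            if key not in entry:
                raise SchemaError(
                    f"reaction entry missing field {key!r} "
                    f"(reaction {entry.get('id', '?')!r})"
                )
        try:
            rxn = Reaction(
                id=entry["id"],
                stoichiometry={k: float(v)
                               for k, v in entry["metabolites"].items()},
                lower_bound=float(entry["lower_bound"]),
                upper_bound=float(entry["upper_bound"]),
                name=entry.get("name", ""),
                gpr=parse_gpr(entry.get("gene_reaction_rule", "")),
                subsystem=entry.get("subsystem", ""),
            )
        except ModelValidationError as err:
            raise SchemaError(str(err)) from err
        rxns.append(rxn)
    genes = doc.get("genes")
    if genes is None:
        genes = sorted({g for r in rxns for g in r.gpr.genes()})
    model = MetabolicModel(
        id=doc.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        genes=list(genes),
        objective_reaction_id=doc.get("objective", ""),
        gam=float(doc.get("gam", 40.0)),
    )
    model.validate()
    return model


def _write_json(model: MetabolicModel, path) -> None:
    doc = {
        "id": model.id,
        "objective": model.objective_reaction_id,
        "gam": model.gam,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "formula": m.formula}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "name": r.name,
             "metabolites": dict(r.stoichiometry),
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "gene_reaction_rule": r.gpr.to_string(),
             "subsystem": r.subsystem}
            for r in model.reactions
        ],
        "genes": list(model.genes),
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1, sort_keys=False)


# --------------------------------------------------------------------------
# Tabular reaction list

_ARROWS = ("<->", "<=>", "->", "=>")
_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(text: str, sign: float, stoich: dict) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split(" + "):
        match = _TERM.match(term.strip())
        if match is None:
            raise SchemaError(f"cannot parse equation term {term!r}")
        coeff = float(match.group(1) or 1.0)
        met = match.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coeff
        if stoich[met] == 0:
            del stoich[met]


def _parse_equation(text: str) -> tuple[dict, bool]:
    for arrow in _ARROWS:
        if arrow in text:
            left, right = text.split(arrow, 1)
            reversible = arrow in ("<->", "<=>")
            stoich: dict = {}
            _parse_side(left, -1.0, stoich)
            _parse_side(right, +1.0, stoich)
            return stoich, reversible
    raise SchemaError(f"no reaction arrow in equation {text!r}")


def _format_equation(rxn: Reaction) -> str:
    def side(items):
        parts = []
        for met, coeff in items:
            coeff = abs(coeff)
            parts.append(met if coeff == 1 else f"{coeff:g} {met}")
        return " + ".join(parts)

    subs = sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<->" if rxn.lower_bound < 0 else "->"
    return f"{side(subs)} {arrow} {side(prods)}"


def _read_tabular(path) -> MetabolicModel:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "equation", "lb", "ub"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"missing required columns {sorted(missing)}")
    rxns, met_ids = [], {}
    for _, row in frame.iterrows():
        stoich, _ = _parse_equation(row["equation"])
        try:
            rxn = Reaction(
                id=row["id"], stoichiometry=stoich,
                lower_bound=float(row["lb"]), upper_bound=float(row["ub"]),
                gpr=parse_gpr(row.get("gpr", "")),
                subsystem=row.get("subsystem", ""),
            )
        except ModelValidationError as err:
            raise SchemaError(str(err)) from err
        rxns.append(rxn)
        for met in stoich:
            met_ids.setdefault(met, None)
    # compartment from the conventional _c/_e id suffix
    mets = [Metabolite(mid, compartment="e" if mid.endswith("_e") else "c")
            for mid in met_ids]
    genes = sorted({g for r in rxns for g in r.gpr.genes()})
    model = MetabolicModel(id="tabular_model", metabolites=mets,
                           reactions=rxns, genes=genes)
    model.validate()
    return model


def _write_tabular(model: MetabolicModel, path) -> None:
    import pandas as pd

    rows = [{
        "id": r.id,
        "equation": _format_equation(r),
        "lb": r.lower_bound,
        "ub": r.upper_bound,
        "gpr": r.gpr.to_string(),
        "subsystem": r.subsystem,
    } for r in model.reactions]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# SBML Level 3 + FBC (through cobrapy / libsbml)


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (used for SBML I/O and cross-checks)."""
    import cobra

    out = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        met = cobra.Metabolite(m.id, name=m.name, formula=m.formula or None,
                               compartment=m.compartment)
        mets[m.id] = met
    for r in model.reactions:
        rxn = cobra.Reaction(r.id, name=r.name,
                             lower_bound=r.lower_bound,
                             upper_bound=r.upper_bound)
        rxn.subsystem = r.subsystem
        out.add_reactions([rxn])
        rxn.add_metabolites({mets[mid]: coeff
                             for mid, coeff in r.stoichiometry.items()})
        rule = r.gpr.to_string()
        if rule:
            rxn.gene_reaction_rule = rule
    if model.objective_reaction_id:
        out.objective = model.objective_reaction_id
    return out


def from_cobra(cmodel) -> MetabolicModel:
    mets = [Metabolite(m.id, name=m.name or "", formula=m.formula or "",
                       compartment=m.compartment or "c")
            for m in cmodel.metabolites]
    rxns = []
    for r in cmodel.reactions:
        rxns.append(Reaction(
            id=r.id,
            stoichiometry={m.id: coeff for m, coeff in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            name=r.name or "",
            gpr=parse_gpr(r.gene_reaction_rule or ""),
            subsystem=r.subsystem or "",
        ))
    objective = ""
    for r in cmodel.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    genes = sorted({g for r in rxns for g in r.gpr.genes()})
    model = MetabolicModel(id=cmodel.id or "model", metabolites=mets,
                           reactions=rxns, genes=genes,
                           objective_reaction_id=objective)
    model.validate()
    return model


def _write_sbml(model: MetabolicModel, path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def _read_sbml(path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    return from_cobra(read_sbml_model(str(path)))
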