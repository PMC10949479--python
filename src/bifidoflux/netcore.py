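"""Core data model for genome-scale metabolic networks.

Defines metabolites, reactions with gene-protein-reaction (GPR) boolean
rules, the model container with its stoichiometric matrix, and in silico
medium construction.  Conventions follow the dominant genome-scale model
dialect (BiGG/AGORA): two compartments (cytosol ``c`` and extracellular
``e``), exchange reactions written ``met_e -->`` so that uptake is a
negative flux bounded below by minus the uptake rate, and fluxes in
mmol·gDCW⁻¹·h⁻¹.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Metabolite",
    "GPRTree",
    "Reaction",
    "MetabolicModel",
    "MediumSpec",
    "RatioConstraint",
    "GPRParseError",
    "ModelValidationError",
    "parse_gpr",
    "gpr_active",
    "gpr_expression",
    "build_stoich_matrix",
    "apply_medium",
    "formula_weight",
    "carbon_count",
]

COMPARTMENTS = ("c", "e")

# monoisotopic-free average atomic masses, g/mol, for the elements that
# occur in the fixture formulas
_ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007,
    "P": 30.974, "S": 32.06,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class GPRParseError(ValueError):
    """Malformed gene-protein-reaction rule string."""


class ModelValidationError(ValueError):
    """Model violates a structural invariant."""


def formula_weight(formula: str) -> float:
    """Molecular weight in g/mol from a Hill-style formula string."""
    if not formula:
        raise ValueError("empty formula")
    pos, weight = 0, 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, count = match.group(1), int(match.group(2) or 1)
        if element not in _ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        weight += _ATOMIC_MASS[element] * count
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return weight


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a formula string (0 if none or empty)."""
    if not formula:
        return 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.group(1) == "C":
            return int(match.group(2) or 1)
    return 0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    compartment: str = "c"

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment must be one of "
                f"{COMPARTMENTS}, got {self.compartment!r}"
            )


# --------------------------------------------------------------------------
# GPR boolean trees


@dataclass(frozen=True)
class GPRTree:
    """Boolean gene association: AND/OR tree over gene-id leaves.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``, ``"empty"``.
    An empty tree means the reaction has no gene association.
    """

    kind: str
    children: tuple["GPRTree", ...] = ()
    gene: str = ""

    def __post_init__(self):
        if self.kind not in ("gene", "and", "or", "empty"):
            raise ValueError(f"bad GPR node kind {self.kind!r}")
        if self.kind in ("and", "or") and len(self.children) < 2:
            raise ValueError(f"{self.kind} node needs >=2 children")
        if self.kind in ("gene", "empty") and self.children:
            raise ValueError("leaf/empty nodes take no children")
        if self.kind == "gene" and not self.gene:
            raise ValueError("gene leaf needs a gene id")

    @property
    def is_empty(self) -> bool:
        return self.kind == "empty"

    def genes(self) -> set[str]:
        if self.kind == "gene":
            return {self.gene}
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def to_string(self) -> str:
        if self.kind == "empty":
            return ""
        if self.kind == "gene":
            return self.gene
        sep = f" {self.kind} "
        parts = []
        for child in self.children:
            text = child.to_string()
            if child.kind in ("and", "or") and child.kind != self.kind:
                text = f"({text})"
            elif child.kind == self.kind:
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)


EMPTY_GPR = GPRTree("empty")

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GPRTree:
    """Parse a GPR rule string ("g1 and (g2 or g3)") into a tree.

    Keywords ``and``/``or`` are case-insensitive; every other token is an
    opaque gene id.  ``or`` binds loosest, as in Python.  An empty or
    whitespace-only string yields the empty tree (no gene association).
    """
    tokens = _GPR_TOKEN.findall(text or "")
    if not tokens:
        return EMPTY_GPR
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def error(message):
        raise GPRParseError(f"{message} at token {pos} in GPR {text!r}")

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GPRTree("or", tuple(terms))

    def parse_and():
        nonlocal pos
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            factors.append(parse_atom())
        if len(factors) == 1:
            return factors[0]
        return GPRTree("and", tuple(factors))

    def parse_atom():
        nonlocal pos
        token = peek()
        if token is None:
            error("unexpected end of rule")
        if token == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                error("expected ')'")
            pos += 1
            return inner
        if token == ")" or token.lower() in ("and", "or"):
            error(f"unexpected token {token!r}")
        pos += 1
        return GPRTree("gene", gene=token)

    tree = parse_or()
    if pos != len(tokens):
        error(f"trailing token {tokens[pos]!r}")
    return tree


def gpr_active(tree: GPRTree, deleted_genes: set[str] | frozenset[str]) -> bool:
    """Evaluate a GPR rule with the given genes knocked out.

    AND is conjunction, OR is disjunction; the empty tree is always active
    (a reaction without gene association is retained).
    """
    if tree.kind == "empty":
        return True
    if tree.kind == "gene":
        return tree.gene not in deleted_genes
    if tree.kind == "and":
        return all(gpr_active(c, deleted_genes) for c in tree.children)
    return any(gpr_active(c, deleted_genes) for c in tree.children)


def gpr_expression(tree: GPRTree, expression: dict[str, float]) -> float | None:
    """Reaction-level expression: AND -> min of children, OR -> max.

    Returns ``None`` (undefined) for the empty tree.  Genes missing from the
    map are treated as unmeasured, never as silent: they are skipped, and a
    node all of whose children are unmeasured is itself undefined.
    """
    if tree.kind == "empty":
        return None
    if tree.kind == "gene":
        return expression.get(tree.gene)
    values = [gpr_expression(c, expression) for c in tree.children]
    values = [v for v in values if v is not None]
    if not values:
        return None
    return min(values) if tree.kind == "and" else max(values)


# --------------------------------------------------------------------------
# Reactions and model


@dataclass
class Reaction:
    """A (possibly reversible) stoichiometric conversion with bounds and GPR.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  Bounds are in mmol·gDCW⁻¹·h⁻¹.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: GPRTree = EMPTY_GPR
    subsystem: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        for met, coeff in self.stoichiometry.items():
            if coeff == 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: zero coefficient for {met!r}"
                )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
            gpr=self.gpr,
            subsystem=self.subsystem,
        )


@dataclass(frozen=True)
class RatioConstraint:
    """Homogeneous coupling row v_num - ratio * v_den = 0.

    Used to pin the acetate:lactate secretion ratio (e.g. 1.5 for 3:2,
    1.75 for 3.5:2) onto the exchange fluxes of the two end products.
    """

    numerator_reaction: str
    denominator_reaction: str
    ratio: float

    def __post_init__(self):
        if not self.ratio > 0:
            raise ValueError("ratio must be positive")


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    objective_reaction_id: str = ""
    gam: float = 40.0
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)

    def __post_init__(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reindex(self) -> None:
        """Rebuild the id->position maps after in-place list edits."""
        self.__post_init__()

    def is_exchange(self, rxn: Reaction) -> bool:
        """Boundary reaction: touches exactly one extracellular metabolite."""
        if len(rxn.stoichiometry) != 1:
            return False
        met_id = next(iter(rxn.stoichiometry))
        met = self.metabolites[self._met_index[met_id]]
        return met.compartment == "e"

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if self.is_exchange(r)]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_reaction_id=self.objective_reaction_id,
            gam=self.gam,
            ratio_constraints=list(self.ratio_constraints),
        )

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        seen_mets = set()
        for met in self.metabolites:
            if met.id in seen_mets:
                raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
            seen_mets.add(met.id)
        seen_rxns = set()
        gene_set = set(self.genes)
        for rxn in self.reactions:
            if rxn.id in seen_rxns:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            seen_rxns.add(rxn.id)
            for met_id in rxn.stoichiometry:
                if met_id not in seen_mets:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite "
                        f"{met_id!r}"
                    )
            missing = rxn.gpr.genes() - gene_set
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: GPR genes {sorted(missing)} not in "
                    "model gene list"
                )
        if self.objective_reaction_id and \
                self.objective_reaction_id not in seen_rxns:
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction_id!r} not found"
            )
        for rc in self.ratio_constraints:
            for rid in (rc.numerator_reaction, rc.denominator_reaction):
                if rid not in seen_rxns:
                    raise ModelValidationError(
                        f"ratio constraint references unknown reaction {rid!r}"
                    )


def build_stoich_matrix(model: MetabolicModel):
    """Dense stoichiometric matrix S (metabolites x reactions).

    Row order follows ``model.metabolites``, column order
    ``model.reactions``; entry (i, j) is the coefficient of metabolite i in
    reaction j.
    """
    import numpy as np

    n_met = len(model.metabolites)
    n_rxn = len(model.reactions)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((n_met, n_rxn))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in met_index:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite "
                    f"{met_id!r}"
                )
            S[met_index[met_id], j] = coeff
    return S


# --------------------------------------------------------------------------
# In silico medium


@dataclass
class MediumSpec:
    """One growth condition: a single carbon source at a given wt/vol.

    Equal wt/vol media are made mole-comparable by scaling the uptake bound
    with the molecular-weight ratio to a reference substrate (lactose):
    uptake = base_uptake_bound * MW_reference / MW_substrate.
    """

    carbon_source_id: str          # exchange reaction id of the carbon source
    molecular_weight: float        # g/mol of the substrate
    reference_molecular_weight: float = 342.30   # lactose
    reference_substrate_id: str = "EX_lcts_e"
    wt_vol_fraction: float = 0.02
    base_uptake_bound: float = 10.0     # mmol·gDCW⁻¹·h⁻¹ for the reference
    non_carbon_allowances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.molecular_weight <= 0 or self.reference_molecular_weight <= 0:
            raise ValueError("molecular weights must be positive")

    @property
    def uptake_bound(self) -> float:
        """Mole-normalized uptake bound for the active carbon source."""
        return self.base_uptake_bound * (
            self.reference_molecular_weight / self.molecular_weight
        )


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a bounded copy of the model representing one medium.

    The active carbon source's exchange lower bound is opened to
    ``-uptake_bound``; every other carbon-containing exchange is closed to
    uptake (lower bound 0) unless it appears in ``non_carbon_allowances``,
    which maps exchange ids to (negative) lower bounds for medium components
    such as ammonium or CO2.
    """
    bounded = model.copy()
    if not bounded.has_reaction(medium.carbon_source_id):
        raise KeyError(
            f"carbon source exchange {medium.carbon_source_id!r} not in model"
        )
    for rxn in bounded.reactions:
        if not bounded.is_exchange(rxn):
            continue
        met = bounded.metabolite(next(iter(rxn.stoichiometry)))
        if rxn.id == medium.carbon_source_id:
            rxn.lower_bound = -medium.uptake_bound
        elif rxn.id in medium.non_carbon_allowances:
            rxn.lower_bound = medium.non_carbon_allowances[rxn.id]
        elif carbon_count(met.formula) > 0:
            rxn.lower_bound = 0.0  # alternative carbon sources closed
    return bounded
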