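"""Synthetic test universe: a bifid-shunt core model with HMO feeder pathways.

Builds a small (~60 reaction) genome-scale-style model of *Bifidobacterium*
central fermentation, faithful to the textbook stoichiometry of the
fructose-6-phosphate phosphoketolase pathway:

    2 glucose + 5 ADP + 5 Pi  ->  3 acetate + 2 lactate + 5 ATP

together with feeder pathways for lactose (beta-galactosidase + Leloir),
3'-fucosyllactose (alpha-fucosidase -> fucose -> 1,2-propanediol +
pyruvate), 6'-sialyllactose (sialidase -> sialic acid -> aminosugar
pathway), and lacto-N-neotetraose (beta-hexosaminidase -> galactose +
GlcNAc + lactose).  A pyruvate-formate-lyase / alcohol-dehydrogenase
branch regenerates NAD+ when pyruvate is drawn into biomass, and a lumped
succinate branch is present but flux-disabled by default.

Gene ids follow the Blon_ locus-tag pattern with fabricated 9xxx numbers:
they are synthetic placeholders, not real *B. infantis* loci.

The module also generates condition-specific expression profiles (with a
configurable fraction of "crossed" off-condition genes) and a designed
growth-phenotype table, so the whole pipeline is testable without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gimme import ExpressionProfile
from .netcore import (
    EMPTY_GPR,
    MediumSpec,
    Metabolite,
    MetabolicModel,
    Reaction,
    carbon_count,
    parse_gpr,
)

__all__ = [
    "FixtureOptions",
    "SUBSTRATE_EXCHANGES",
    "SUBSTRATE_MW",
    "CONDITIONS",
    "END_PRODUCT_EXCHANGES",
    "build_bifid_fixture",
    "default_medium",
    "build_expression_fixture",
    "build_growth_table",
    "carbon_imbalances",
]

#: the four study conditions
CONDITIONS = ("lactose", "3FL", "6SL", "LNnT")

#: substrate name -> exchange reaction id (None marks substrates the model
#: has no transporter/exchange for; used to design true/false negatives)
SUBSTRATE_EXCHANGES = {
    "lactose": "EX_lcts_e",
    "3FL": "EX_fl3_e",
    "6SL": "EX_sl6_e",
    "LNnT": "EX_lnnt_e",
    "glucose": "EX_glc__D_e",
    "pyruvate": "EX_pyr_e",
}

#: substrate molecular weights, g/mol
SUBSTRATE_MW = {
    "lactose": 342.30,
    "3FL": 488.44,
    "6SL": 633.55,
    "LNnT": 707.63,
    "glucose": 180.16,
    "pyruvate": 88.06,
    "fucose": 164.16,
    "ribose": 150.13,
    "sorbitol": 182.17,
    "2FL": 488.44,
    "raffinose": 504.42,
}

#: major end-product exchanges used to seed the coupling networks
END_PRODUCT_EXCHANGES = [
    "EX_lac__L_e", "EX_ac_e", "EX_succ_e", "EX_for_e", "EX_etoh_e",
    "EX_12ppd__R_e",
]


@dataclass
class FixtureOptions:
    gam: float = 40.0                 # mmol ATP per gDCW in biomass
    uptake_bound: float = 10.0        # reference (lactose) uptake bound
    include_fucose: bool = True
    include_neuac: bool = True
    include_glcnac: bool = True
    include_pfl_ethanol: bool = True
    include_succinate_stub: bool = True
    crossed_fraction: float = 0.15    # fraction of silent genes moderately on
    noise_sigma: float = 0.15         # lognormal sigma for expression noise
    random_seed: int = 2024


# --------------------------------------------------------------------------
# Model construction


def _mets() -> list[Metabolite]:
    cyt = {
        "glc__D_c": ("D-glucose", "C6H12O6"),
        "gal_c": ("D-galactose", "C6H12O6"),
        "lcts_c": ("lactose", "C12H22O11"),
        "fl3_c": ("3-fucosyllactose", "C18H32O15"),
        "sl6_c": ("6-sialyllactose", "C23H39NO19"),
        "lnnt_c": ("lacto-N-neotetraose", "C26H45NO21"),
        "fuc__L_c": ("L-fucose", "C6H12O5"),
        "fcl_c": ("L-fuculose", "C6H12O5"),
        "fc1p_c": ("L-fuculose 1-phosphate", "C6H13O8P"),
        "lald__L_c": ("L-lactaldehyde", "C3H6O2"),
        "12ppd__R_c": ("(R)-1,2-propanediol", "C3H8O2"),
        "neu5ac_c": ("N-acetylneuraminate", "C11H19NO9"),
        "acmana_c": ("N-acetyl-D-mannosamine", "C8H15NO6"),
        "acmanap_c": ("N-acetyl-D-mannosamine 6-phosphate", "C8H16NO9P"),
        "acgam_c": ("N-acetyl-D-glucosamine", "C8H15NO6"),
        "acgam6p_c": ("N-acetyl-D-glucosamine 6-phosphate", "C8H16NO9P"),
        "gam6p_c": ("D-glucosamine 6-phosphate", "C6H14NO8P"),
        "g6p_c": ("D-glucose 6-phosphate", "C6H13O9P"),
        "f6p_c": ("D-fructose 6-phosphate", "C6H13O9P"),
        "g1p_c": ("D-glucose 1-phosphate", "C6H13O9P"),
        "gal1p_c": ("D-galactose 1-phosphate", "C6H13O9P"),
        "e4p_c": ("D-erythrose 4-phosphate", "C4H9O7P"),
        "s7p_c": ("sedoheptulose 7-phosphate", "C7H15O10P"),
        "r5p_c": ("D-ribose 5-phosphate", "C5H11O8P"),
        "ru5p__D_c": ("D-ribulose 5-phosphate", "C5H11O8P"),
        "xu5p__D_c": ("D-xylulose 5-phosphate", "C5H11O8P"),
        "gap_c": ("glyceraldehyde 3-phosphate", "C3H7O6P"),
        "dhap_c": ("dihydroxyacetone phosphate", "C3H7O6P"),
        "13dpg_c": ("1,3-bisphospho-D-glycerate", "C3H8O10P2"),
        "3pg_c": ("3-phospho-D-glycerate", "C3H7O7P"),
        "2pg_c": ("2-phospho-D-glycerate", "C3H7O7P"),
        "pep_c": ("phosphoenolpyruvate", "C3H5O6P"),
        "pyr_c": ("pyruvate", "C3H4O3"),
        "actp_c": ("acetyl phosphate", "C2H5O5P"),
        "ac_c": ("acetate", "C2H4O2"),
        "lac__L_c": ("L-lactate", "C3H6O3"),
        "for_c": ("formate", "CH2O2"),
        "etoh_c": ("ethanol", "C2H6O"),
        "accoa_c": ("acetyl-CoA", "C23H38N7O17P3S"),
        "coa_c": ("coenzyme A", "C21H36N7O16P3S"),
        "succ_c": ("succinate", "C4H6O4"),
        "nh4_c": ("ammonium", "H4N"),
        "co2_c": ("carbon dioxide", "CO2"),
        "atp_c": ("ATP", "C10H16N5O13P3"),
        "adp_c": ("ADP", "C10H15N5O10P2"),
        "pi_c": ("orthophosphate", "HPO4"),
        "nad_c": ("NAD+", "C21H27N7O14P2"),
        "nadh_c": ("NADH", "C21H28N7O14P2"),
    }
    ext = {
        "glc__D_e": ("D-glucose", "C6H12O6"),
        "lcts_e": ("lactose", "C12H22O11"),
        "fl3_e": ("3-fucosyllactose", "C18H32O15"),
        "sl6_e": ("6-sialyllactose", "C23H39NO19"),
        "lnnt_e": ("lacto-N-neotetraose", "C26H45NO21"),
        "ac_e": ("acetate", "C2H4O2"),
        "lac__L_e": ("L-lactate", "C3H6O3"),
        "for_e": ("formate", "CH2O2"),
        "etoh_e": ("ethanol", "C2H6O"),
        "12ppd__R_e": ("(R)-1,2-propanediol", "C3H8O2"),
        "succ_e": ("succinate", "C4H6O4"),
        "pyr_e": ("pyruvate", "C3H4O3"),
        "nh4_e": ("ammonium", "H4N"),
        "co2_e": ("carbon dioxide", "CO2"),
        "pi_e": ("orthophosphate", "HPO4"),
        "neu5ac_e": ("N-acetylneuraminate", "C11H19NO9"),
        "acgam_e": ("N-acetyl-D-glucosamine", "C8H15NO6"),
    }
    mets = [Metabolite(mid, name, formula, "c")
            for mid, (name, formula) in cyt.items()]
    mets += [Metabolite(mid, name, formula, "e")
             for mid, (name, formula) in ext.items()]
    return mets


# reaction table: id -> (stoichiometry, lb, ub, gpr, subsystem, name)
def _rxns(opts: FixtureOptions):
    R = 1000.0
    rxns: list[Reaction] = []

    def add(rid, stoich, lb, ub, gpr, subsystem, name=""):
        rxns.append(Reaction(rid, dict(stoich), lb, ub, name=name,
                             gpr=parse_gpr(gpr), subsystem=subsystem))

    # exchanges: met_e ->, uptake = negative flux (opened by the medium)
    for mid, lb in [
        ("glc__D_e", 0), ("lcts_e", 0), ("fl3_e", 0), ("sl6_e", 0),
        ("lnnt_e", 0), ("ac_e", 0), ("lac__L_e", 0), ("for_e", 0),
        ("etoh_e", 0), ("12ppd__R_e", 0), ("succ_e", 0), ("pyr_e", 0),
        ("nh4_e", -R), ("co2_e", -R), ("pi_e", -R),
        ("neu5ac_e", 0), ("acgam_e", 0),
    ]:
        add(f"EX_{mid}", {mid: -1}, lb, R, "", "Exchange")

    # transport
    add("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, 0, R, "Blon_9001",
        "Transport", "glucose transport")
    add("LCTSt", {"lcts_e": -1, "lcts_c": 1}, 0, R, "Blon_9002",
        "Transport", "lactose permease")
    add("FL3abc", {"fl3_e": -1, "atp_c": -1, "fl3_c": 1, "adp_c": 1,
                   "pi_c": 1}, 0, R, "Blon_9003 and Blon_9004",
        "Transport", "3'FL ABC transporter")
    add("SL6abc", {"sl6_e": -1, "atp_c": -1, "sl6_c": 1, "adp_c": 1,
                   "pi_c": 1}, 0, R, "Blon_9005 and Blon_9006",
        "Transport", "6'SL ABC transporter")
    add("LNNTabc", {"lnnt_e": -1, "atp_c": -1, "lnnt_c": 1, "adp_c": 1,
                    "pi_c": 1}, 0, R, "Blon_9007 and Blon_9008",
        "Transport", "LNnT ABC transporter")
    # aminosugar overflow: sialic acid and GlcNAc utilization is partial in
    # B. infantis, so both can be shed rather than fully catabolized
    for met, rid in [("ac", "ACt"), ("lac__L", "LACt"), ("for", "FORt"),
                     ("etoh", "ETOHt"), ("12ppd__R", "12PPDt"),
                     ("succ", "SUCCt"), ("pyr", "PYRt"),
                     ("neu5ac", "NEU5ACt"), ("acgam", "ACGAMt")]:
        add(rid, {f"{met}_c": -1, f"{met}_e": 1}, 0, R, "", "Transport")
    add("NH4t", {"nh4_e": -1, "nh4_c": 1}, -R, R, "", "Transport")
    add("CO2t", {"co2_e": -1, "co2_c": 1}, -R, R, "", "Transport")
    add("PIt", {"pi_e": -1, "pi_c": 1}, -R, R, "", "Transport")

    # glycan hydrolysis
    add("LACZ", {"lcts_c": -1, "glc__D_c": 1, "gal_c": 1}, 0, R,
        "Blon_9010 or Blon_9011", "Glycan degradation", "beta-galactosidase")
    add("AFUC", {"fl3_c": -1, "fuc__L_c": 1, "lcts_c": 1}, 0, R,
        "Blon_9012", "Glycan degradation", "alpha-fucosidase")
    add("SIAL", {"sl6_c": -1, "neu5ac_c": 1, "lcts_c": 1}, 0, R,
        "Blon_9013", "Glycan degradation", "alpha-sialidase")
    add("BHEX", {"lnnt_c": -1, "gal_c": 1, "acgam_c": 1, "lcts_c": 1}, 0, R,
        "Blon_9014 or Blon_9015 or Blon_9016", "Glycan degradation",
        "beta-hexosaminidase route")

    # Leloir pathway
    add("GALK", {"gal_c": -1, "atp_c": -1, "gal1p_c": 1, "adp_c": 1}, 0, R,
        "Blon_9017", "Leloir pathway", "galactokinase")
    add("GALT", {"gal1p_c": -1, "g1p_c": 1}, 0, R,
        "Blon_9018 and Blon_9019", "Leloir pathway",
        "uridylyltransferase + UDP-glucose 4-epimerase (lumped)")
    add("PGMT", {"g1p_c": -1, "g6p_c": 1}, -R, R, "Blon_9020",
        "Leloir pathway", "phosphoglucomutase")

    # upper glycolysis
    add("HEX1", {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, 0, R,
        "Blon_9021", "Glycolysis", "hexokinase")
    add("PGI", {"g6p_c": -1, "f6p_c": 1}, -R, R, "Blon_9022",
        "Glycolysis", "glucose-6-phosphate isomerase")

    # bifid shunt (the phosphoketolase XFP is bifunctional: F6P and X5P)
    add("F6PPK", {"f6p_c": -1, "pi_c": -1, "e4p_c": 1, "actp_c": 1}, 0, R,
        "Blon_9023", "Bifid shunt", "fructose-6-phosphate phosphoketolase")
    add("TALA", {"gap_c": -1, "s7p_c": -1, "e4p_c": 1, "f6p_c": 1}, -R, R,
        "Blon_9024", "Bifid shunt", "transaldolase")
    add("TKT1", {"r5p_c": -1, "xu5p__D_c": -1, "gap_c": 1, "s7p_c": 1},
        -R, R, "Blon_9025", "Bifid shunt", "transketolase")
    add("RPI", {"r5p_c": -1, "ru5p__D_c": 1}, -R, R, "Blon_9026",
        "Bifid shunt", "ribose-5-phosphate isomerase")
    add("RPE", {"ru5p__D_c": -1, "xu5p__D_c": 1}, -R, R, "Blon_9027",
        "Bifid shunt", "ribulose-5-phosphate epimerase")
    add("XPK", {"xu5p__D_c": -1, "pi_c": -1, "gap_c": 1, "actp_c": 1}, 0, R,
        "Blon_9023", "Bifid shunt", "xylulose-5-phosphate phosphoketolase")

    # lower glycolysis
    add("GAPD", {"gap_c": -1, "nad_c": -1, "pi_c": -1, "13dpg_c": 1,
                 "nadh_c": 1}, -R, R, "Blon_9028", "Glycolysis",
        "glyceraldehyde-3-phosphate dehydrogenase")
    add("PGK", {"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1}, -R, R,
        "Blon_9029", "Glycolysis", "phosphoglycerate kinase")
    add("PGM", {"3pg_c": -1, "2pg_c": 1}, -R, R, "Blon_9030",
        "Glycolysis", "phosphoglycerate mutase")
    add("ENO", {"2pg_c": -1, "pep_c": 1}, -R, R, "Blon_9031",
        "Glycolysis", "enolase")
    add("PYK", {"pep_c": -1, "adp_c": -1, "pyr_c": 1, "atp_c": 1}, 0, R,
        "Blon_9032", "Glycolysis", "pyruvate kinase")

    # fermentation
    add("ACKr", {"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1}, -R, R,
        "Blon_9033", "Fermentation", "acetate kinase")
    add("LDH_L", {"pyr_c": -1, "nadh_c": -1, "lac__L_c": 1, "nad_c": 1},
        0, R, "Blon_9034 or Blon_9035", "Fermentation",
        "L-lactate dehydrogenase")
    if opts.include_pfl_ethanol:
        add("PFL", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1},
            0, R, "Blon_9036 or Blon_9037", "Fermentation",
            "pyruvate formate lyase")
        add("ADHE", {"accoa_c": -1, "nadh_c": -2, "etoh_c": 1, "coa_c": 1,
                     "nad_c": 2}, 0, R, "Blon_9038", "Fermentation",
            "aldehyde/alcohol dehydrogenase (lumped)")
    if opts.include_succinate_stub:
        # present but flux-disabled: no succinate secretion is predicted
        add("SUCS", {"pep_c": -1, "co2_c": -1, "nadh_c": -2, "succ_c": 1,
                     "pi_c": 1, "nad_c": 2}, 0, 0, "Blon_9039",
            "Fermentation", "succinate branch (lumped, disabled)")

    # fucose branch (3'FL)
    if opts.include_fucose:
        add("FCI", {"fuc__L_c": -1, "fcl_c": 1}, -R, R, "Blon_9040",
            "Fucose metabolism", "L-fucose isomerase")
        add("FCK", {"fcl_c": -1, "atp_c": -1, "fc1p_c": 1, "adp_c": 1},
            0, R, "Blon_9041", "Fucose metabolism", "L-fuculokinase")
        add("FCA", {"fc1p_c": -1, "dhap_c": 1, "lald__L_c": 1}, 0, R,
            "Blon_9042", "Fucose metabolism",
            "fuculose-1-phosphate aldolase")
        add("LCARS", {"lald__L_c": -1, "nadh_c": -1, "12ppd__R_c": 1,
                      "nad_c": 1}, 0, R, "Blon_9043", "Fucose metabolism",
            "lactaldehyde reductase")
        add("TPI", {"dhap_c": -1, "gap_c": 1}, -R, R, "Blon_9044",
            "Fucose metabolism", "triose-phosphate isomerase")

    # sialic acid branch (6'SL)
    if opts.include_neuac:
        add("NANA", {"neu5ac_c": -1, "acmana_c": 1, "pyr_c": 1}, 0, R,
            "Blon_9045", "Aminosugar metabolism",
            "N-acetylneuraminate lyase")
        add("NANK", {"acmana_c": -1, "atp_c": -1, "acmanap_c": 1,
                     "adp_c": 1}, 0, R, "Blon_9046",
            "Aminosugar metabolism", "N-acetylmannosamine kinase")
        add("NANE", {"acmanap_c": -1, "acgam6p_c": 1}, -R, R, "Blon_9047",
            "Aminosugar metabolism",
            "N-acetylmannosamine-6-phosphate epimerase")
    if opts.include_glcnac:
        add("ACGAMK", {"acgam_c": -1, "atp_c": -1, "acgam6p_c": 1,
                       "adp_c": 1}, 0, R, "Blon_9050",
            "Aminosugar metabolism", "N-acetylglucosamine kinase")
    if opts.include_neuac or opts.include_glcnac:
        add("AGDC", {"acgam6p_c": -1, "gam6p_c": 1, "ac_c": 1}, 0, R,
            "Blon_9048", "Aminosugar metabolism",
            "N-acetylglucosamine-6-phosphate deacetylase")
        add("G6PDA", {"gam6p_c": -1, "f6p_c": 1, "nh4_c": 1}, 0, R,
            "Blon_9049", "Aminosugar metabolism",
            "glucosamine-6-phosphate deaminase")

    # maintenance ATP drain (NGAM unconstrained: lower bound 0)
    add("ATPM", {"atp_c": -1, "adp_c": 1, "pi_c": 1}, 0, R, "",
        "Maintenance", "ATP maintenance drain")

    # biomass: precursor drain + growth-associated maintenance ATP
    add("BIOMASS",
        {"g6p_c": -4.0, "pyr_c": -2.5, "nh4_c": -0.25,
         "atp_c": -opts.gam, "adp_c": opts.gam, "pi_c": opts.gam},
        0, R, "", "Biomass", "biomass drain (GAM embedded)")
    return rxns


def build_bifid_fixture(opts: FixtureOptions | None = None) -> MetabolicModel:
    """Construct the bifid-shunt fixture model.

    The phosphoketolase core enforces the textbook net conversion
    2 glucose -> 3 acetate + 2 lactate + 5 ATP, so the 2.5 ATP/glucose and
    3:2 acetate:lactate anchors are structural, not fitted, and hold for
    any GAM value (the biomass ATP drain sits downstream of them).
    """
    opts = opts or FixtureOptions()
    mets = _mets()
    rxns = _rxns(opts)
    genes = sorted({g for r in rxns for g in r.gpr.genes()})
    model = MetabolicModel(
        id="bifid_shunt_fixture",
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        objective_reaction_id="BIOMASS",
        gam=opts.gam,
    )
    model.validate()
    return model


def default_medium(condition: str, opts: FixtureOptions | None = None
                   ) -> MediumSpec:
    """Medium for one study condition: 2% wt/vol, mole-normalized uptake."""
    opts = opts or FixtureOptions()
    if condition not in SUBSTRATE_EXCHANGES:
        raise KeyError(f"unknown substrate {condition!r}")
    return MediumSpec(
        carbon_source_id=SUBSTRATE_EXCHANGES[condition],
        molecular_weight=SUBSTRATE_MW[condition],
        reference_molecular_weight=SUBSTRATE_MW["lactose"],
        reference_substrate_id="EX_lcts_e",
        wt_vol_fraction=0.02,
        base_uptake_bound=opts.uptake_bound,
        non_carbon_allowances={"EX_nh4_e": -1000.0, "EX_co2_e": -1000.0,
                               "EX_pi_e": -1000.0},
    )


def carbon_imbalances(model: MetabolicModel) -> dict[str, float]:
    """Net carbon of every internal reaction (should be 0 except drains).

    Exchanges and the biomass/ATPM drains are boundary reactions and are
    excluded.
    """
    out = {}
    for rxn in model.reactions:
        if model.is_exchange(rxn) or rxn.id in ("BIOMASS",):
            continue
        net = sum(coeff * carbon_count(model.metabolite(mid).formula)
                  for mid, coeff in rxn.stoichiometry.items())
        out[rxn.id] = net
    return out


# --------------------------------------------------------------------------
# Expression profiles

# gene groups for the expression generator
_GROUPS = {
    "core": [
        "Blon_9002",                      # lactose permease (on everywhere:
                                          # lactose is the core of every HMO)
        "Blon_9010", "Blon_9011",         # beta-galactosidases
        "Blon_9017", "Blon_9018", "Blon_9019", "Blon_9020",   # Leloir
        "Blon_9021", "Blon_9022", "Blon_9023",
        "Blon_9024", "Blon_9025", "Blon_9026", "Blon_9027",   # shunt
        "Blon_9028", "Blon_9029", "Blon_9030", "Blon_9031", "Blon_9032",
        "Blon_9033", "Blon_9034", "Blon_9035",                # ack/ldh
        "Blon_9036", "Blon_9037", "Blon_9038",                # pfl/adh
    ],
    "3FL": ["Blon_9003", "Blon_9004", "Blon_9012", "Blon_9040",
            "Blon_9041", "Blon_9042", "Blon_9043", "Blon_9044"],
    "6SL": ["Blon_9005", "Blon_9006", "Blon_9013", "Blon_9045",
            "Blon_9046", "Blon_9047"],
    "LNnT": ["Blon_9007", "Blon_9008", "Blon_9014", "Blon_9015",
             "Blon_9016", "Blon_9050"],
    "aminosugar": ["Blon_9048", "Blon_9049"],   # shared by 6SL and LNnT
    "background": ["Blon_9001", "Blon_9039"],   # glc transporter, succ stub
}

# expression bands (normalized-count scale)
_BAND_CORE = 110.0
_BAND_ON = 80.0
_BAND_CROSSED = 30.0
_BAND_SILENT = 1.5

#: housekeeping genes outside the metabolic model: 20 low-expressed genes
#: form a buffer band around the 30th-percentile cut, 15 are high
_N_HK_LOW, _N_HK_HIGH = 20, 15


def _on_groups(condition: str) -> set[str]:
    on = {"core", condition}
    if condition in ("6SL", "LNnT"):
        on.add("aminosugar")
    return on


def build_expression_fixture(model: MetabolicModel, condition: str,
                             opts: FixtureOptions | None = None
                             ) -> ExpressionProfile:
    """Condition-specific expression profile with crossed-expression noise.

    Bifid-shunt/core genes are highly expressed in every condition; feeder
    genes are high only in their own condition and near-silent otherwise,
    except for a seeded random fraction of "crossed" genes given moderate
    values (e.g. a fucosidase transcribed during growth on lactose).
    Housekeeping genes outside the model pad the distribution so the 30th
    percentile falls between the silent band and the crossed band.
    """
    if condition not in CONDITIONS:
        raise KeyError(f"condition must be one of {CONDITIONS}")
    opts = opts or FixtureOptions()
    seed = (opts.random_seed * 7919 + CONDITIONS.index(condition)) % (2**31)
    rng = np.random.default_rng(seed)
    on = _on_groups(condition)
    values: dict[str, float] = {}
    silent_genes: list[str] = []
    for group, genes in _GROUPS.items():
        for gene in genes:
            if group == "core":
                base = _BAND_CORE
            elif group in on:
                base = _BAND_ON
            else:
                base = _BAND_SILENT
                silent_genes.append(gene)
            values[gene] = base
    n_crossed = int(round(opts.crossed_fraction * len(silent_genes)))
    crossed = rng.choice(silent_genes, size=n_crossed, replace=False)
    for gene in crossed:
        values[gene] = _BAND_CROSSED
    for k in range(_N_HK_LOW):
        values[f"Blon_8{k:03d}"] = float(rng.uniform(8.0, 15.0))
    for k in range(_N_HK_HIGH):
        values[f"Blon_7{k:03d}"] = float(rng.uniform(40.0, 150.0))
    noise = rng.lognormal(mean=0.0, sigma=opts.noise_sigma, size=len(values))
    values = {g: v * n for (g, v), n in zip(sorted(values.items()), noise)}
    return ExpressionProfile(condition=condition, values=values)


# --------------------------------------------------------------------------
# Growth phenotype table

#: default design: 10 substrates with the designed confusion matrix
#: TP=4 (the four study conditions), FP=1 (glucose: the fixture grows but
#: B. infantis grows poorly on free glucose), TN=3, FN=2 (substrates
#: fermented in vivo but absent from the fixture)
DEFAULT_GROWTH_DESIGN = [
    ("lactose", True, 0.30),
    ("3FL", True, 0.24),
    ("6SL", True, 0.22),
    ("LNnT", True, 0.28),
    ("glucose", False, None),
    ("fucose", False, None),
    ("ribose", False, None),
    ("sorbitol", False, None),
    ("2FL", True, 0.20),
    ("raffinose", True, 0.15),
]


def build_growth_table(design=None, opts: FixtureOptions | None = None):
    """Phenotype table plus per-substrate media.

    Returns ``(table, media)`` where ``table`` is a DataFrame with columns
    substrate / observed_growth / observed_rate and ``media`` maps each
    substrate to a MediumSpec, or to None when the fixture has no exchange
    for it (such substrates are predicted non-growing by construction,
    yielding designed true/false negatives).
    """
    opts = opts or FixtureOptions()
    if design is None:
        design = DEFAULT_GROWTH_DESIGN
    if not design:
        raise ValueError("empty growth design")
    rows, media = [], {}
    for substrate, grows, rate in design:
        if rate is not None and rate < 0:
            raise ValueError(f"negative observed rate for {substrate!r}")
        rows.append({"substrate": substrate,
                     "observed_growth": int(bool(grows)),
                     "observed_rate": rate})
        if substrate in SUBSTRATE_EXCHANGES:
            media[substrate] = default_medium(substrate, opts)
        else:
            media[substrate] = None
    table = pd.DataFrame(rows)
    return table, media
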