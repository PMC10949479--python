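# bifidoflux

Constraint-based analysis of human-milk-oligosaccharide (HMO) metabolism
in *Bifidobacterium longum* subsp. *infantis* — for systems biologists who
want a tested, reusable implementation of the full simulation toolchain:
genome-scale model representation with GPR boolean logic, FBA / pFBA /
FVA with an acetate:lactate production-ratio constraint, GIMME
transcriptomics integration, single-gene essentiality scans,
growth-prediction scoring (F-score, MCC, RMSE), and flux-coupling network
analysis with topology and rewiring metrics.

*B. infantis* ferments lactose and HMOs (3′-fucosyllactose,
6′-sialyllactose, lacto-N-neotetraose) through the **bifid shunt**, the
fructose-6-phosphate phosphoketolase pathway with net stoichiometry

```
2 glucose + 5 ADP + 5 Pi  →  3 acetate + 2 lactate + 5 ATP
```

All simulation is linear programming over the steady-state flux polytope

```
max  μ      s.t.  S·v = 0,   lb ≤ v ≤ ub
```

optionally with the homogeneous ratio row `v_ac − r·v_lac = 0` pinning
acetate:lactate secretion (r = 1.75 for the 3.5:2 ratio used in all
constrained analyses). Because genome-scale reconstructions of this
organism live in supplementary archives, the package ships a synthetic
bifid-shunt model (`bifidoflux.synthetic_data`) with stoichiometrically
exact core chemistry and feeder pathways for all four substrates, plus
condition-specific expression profiles and a designed growth-phenotype
table, so every stage of the pipeline is testable end to end without any
download. See `docs/methods.md` for the model, algorithms, and their
assumptions.

## Worked example

Growth on 3′-fucosyllactose under the 3.5:2 acetate:lactate constraint:

```python
from bifidoflux.synthetic_data import build_bifid_fixture, default_medium
from bifidoflux.netcore import apply_medium, RatioConstraint
from bifidoflux import fluxcalc

model = build_bifid_fixture()
medium = default_medium("3FL")          # 2% wt/vol, mole-normalized uptake
bounded = fluxcalc.add_ratio_constraint(
    apply_medium(model, medium),
    RatioConstraint("EX_ac_e", "EX_lac__L_e", 1.75))
sol = fluxcalc.pfba(bounded)            # parsimonious flux distribution
yields = fluxcalc.compute_yields(sol, bounded, medium)
print(f"mu = {sol.mu:.4f} 1/h")
print(f"biomass yield = {yields.biomass_yield:.4f} gDCW/g 3'FL")
for met, y in sorted(yields.metabolite_yields.items()):
    print(f"yield {met:12s} = {y:.4f} g/gDCW")
```

prints

```
mu = 0.6489 1/h
biomass yield = 0.1896 gDCW/g 3'FL
yield 12ppd__R_e   = 0.8218 g/gDCW
yield ac_e         = 1.5854 g/gDCW
yield etoh_e       = 0.0579 g/gDCW
yield for_e        = 0.0579 g/gDCW
yield lac__L_e     = 1.3589 g/gDCW
yield pyr_e        = 0.8416 g/gDCW
```

The specific growth rate is 0.65 h⁻¹ at a biomass yield of 0.19 gDCW per
gram of substrate. Acetate and lactate dominate at exactly the imposed
1.75 molar ratio; 1,2-propanediol and pyruvate appear because — uniquely
among the four substrates — the fucose moiety of 3′FL is split into
lactaldehyde (reduced to 1,2-PD) and DHAP; and formate/ethanol are low but
nonzero, the signature of the pyruvate-formate-lyase valve that
regenerates NAD⁺ when biomass synthesis withdraws pyruvate. Succinate is
never secreted.

The same pipeline is scriptable from the shell:

```
bifidoflux make-fixtures --out fixtures
bifidoflux run-all --model fixtures/model.json \
    --expression fixtures/expression.tsv --out results
bifidoflux evaluate fixtures/model.json fixtures/phenotypes.tsv
```

`run-all` writes, per condition, the pFBA flux table with FVA ranges, an
Escher-compatible flux JSON, yield and essentiality tables, the GIMME
deactivation list, and the coupled-reaction network (GraphML), plus
cross-condition outputs: context-model report, common essential genes, and
the consensus network with per-node Dn rewiring scores.

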