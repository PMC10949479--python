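# Methods

`bifidoflux` implements the constraint-based analysis toolchain used to
study human-milk-oligosaccharide (HMO) metabolism in *Bifidobacterium
longum* subsp. *infantis*: a genome-scale model data structure with
gene–protein–reaction (GPR) boolean logic, linear-programming engines
(FBA, parsimonious FBA, flux variability analysis), an end-product ratio
constraint, GIMME transcriptomics integration, single-gene deletion scans,
growth-prediction scoring, and flux-coupling network analysis. Because
published genome-scale reconstructions of this organism and their RNA-seq
inputs live in supplementary archives rather than being package inputs,
all pipeline stages are exercised on a synthetic bifid-shunt model
generated by `bifidoflux.synthetic_data`.

## Steady-state model and solvers

All analyses operate on the standard steady-state polytope

```
S · v = 0,    lb ≤ v ≤ ub
```

with fluxes `v` in mmol·gDCW⁻¹·h⁻¹ and the biomass flux μ in h⁻¹.
Exchange reactions are written `met_e →` (export positive), so uptake is a
negative flux bounded below by −(uptake bound) — the convention of the
BiGG/AGORA model dialect. Every LP is solved with HiGHS through
`scipy.optimize.linprog` at a feasibility/optimality tolerance of 1e-9;
all downstream zero tests use 1e-6, one order looser, so classifications
(blocked, essential, deactivated) do not flap on solver noise.

- **FBA** maximizes one reaction's flux (by default biomass).
- **pFBA** fixes the FBA optimum (with a 1e-9 slack, since exact equality
  at a floating-point optimum can be infeasible) and minimizes Σ|v| with
  reversible reactions split into nonnegative halves. This selects a
  parsimonious representative among alternate optima and suppresses futile
  cycles without integer variables.
- **FVA** reports each reaction's flux minimum and maximum subject to the
  objective staying at or above a fraction of its optimum (default 0.99).
- **Ratio constraint**: a homogeneous row `v_ac − r·v_lac = 0` appended to
  the equality system, applied to the *exchange* fluxes of acetate and
  lactate because the measured quantities are extracellular end products.
  The default r = 1.75 encodes the 3.5:2 acetate:lactate ratio adopted for
  all constrained analyses.
- **Blocked reactions** are those whose objective-free FVA range is [0, 0]
  under the model's own bounds; the expression/flux consistency check
  reports reactions whose GPR is satisfied by an expressed-gene set but
  which cannot carry flux (optionally while biomass stays above a fraction
  of its optimum) — the gap report used when refining a reconstruction.

Yields follow the conventions of the field: biomass yield
μ / (|uptake| · MW/1000) in gDCW per g substrate, end-product yields
(export · MW/1000)/μ in g per gDCW, with molecular weights computed from
metabolite formulas.

## GIMME integration

Reaction-level expression maps AND nodes to the lowest and OR nodes to the
highest expressed gene. Unmeasured genes are skipped rather than treated
as silent (absence of measurement is not evidence of silence), and
reactions without gene association are never penalized or deactivated, so
spontaneous transport steps stay usable. The expression threshold is a
percentile (default the 30th, linear interpolation) of the per-gene
distribution. Extraction solves

```
min Σ_{x_i < t} (t − x_i)·|v_i|   s.t.  S·v = 0, bounds, μ ≥ f·μ*
```

with the growth fraction f defaulting to 0.9, the canonical choice from
the algorithm's original description (the required fraction is otherwise
unreported for this analysis). Deactivation is post hoc: a below-threshold
reaction is removed (bounds zeroed) only if it carries zero flux in the
penalized optimum, so low-expression reactions that are the sole route to
biomass survive and every context model still grows; the residual penalty
is reported as the inconsistency score.

## Essentiality

A gene knockout zeroes the bounds of every reaction whose GPR evaluates
false without that gene, then re-solves plain FBA (classification depends
only on the optimum, so the parsimonious stage is skipped for speed).
Classes: essential (growth ratio ≤ 1e-6), reduced growth
(ratio < 1 − 0.05), no effect otherwise; both tolerances are arguments.
Cross-condition summaries report the intersection of essential sets.

## Flux coupling and network analysis

Coupling is a property of the flux cone {S·v = 0, v_irr ≥ 0} (including
any ratio rows); bound magnitudes only enter through the blocked-reaction
prefilter. Reversible reactions are split, and for each ordered half pair
the LP `min/max u_i subject to u_j = 1, u ≥ 0` yields bounds whose
combination classifies the pair: equal nonzero bounds → fully coupled
(with that ratio); both directions bounded away from zero → partially
coupled; one direction only → directional; neither → uncoupled. The
reverse direction follows from homogeneity (Rmin(j|i) = 1/Rmax(i|j)), so
each unordered half pair costs two LPs. A net reaction pair takes the
strongest relation among its feasible half pairs.

Coupled-reaction networks are anchored at the six end-product exchanges
(lactate, acetate, succinate, formate, ethanol, 1,2-propanediol): nodes
are the connected components of the full/partial coupling graph touching a
seed, edges are typed full/partial, and directional relations never form
edges. Topology metrics use the mainstream conventions: mean unweighted
local clustering with degree < 2 nodes contributing 0, shortest-path edge
betweenness, and a continuous maximum-likelihood power-law exponent
α = 1 + n/Σln(d/d_min) reported as a descriptive statistic only (no
goodness-of-fit decision is attached).

**Rewiring (Dn) score.** The rewiring metric popularized by DyNet-style
consensus analyses is published without a formula, so the score here is a
documented interpretation: for each node, every network containing it
contributes a binary incidence vector over the union of the node's
neighbors across networks; Dn is the mean Euclidean distance of those
vectors to their centroid, normalized by the node's mean degree (minimum
1). Dn = 0 exactly when the neighbor set is identical in every network
containing the node. The consensus graph is the union of nodes and edges,
each edge annotated with its network multiplicity.

## The synthetic bifid-shunt fixture

The generator emulates the study system at desk scale (~50 genes,
~70 reactions, two compartments) rather than reproducing a genome-scale
reconstruction (hundreds of genes, over a thousand reactions). Its core
is the textbook
fructose-6-phosphate phosphoketolase pathway with exact stoichiometry

```
2 glucose + 5 ADP + 5 Pi → 3 acetate + 2 lactate + 5 ATP
```

via hexokinase/phosphoglucose isomerase, the bifunctional phosphoketolase
(F6P and X5P activities on one gene, as in *Bifidobacterium*),
transaldolase, transketolase, ribose-5-phosphate isomerase and epimerase,
lower glycolysis, acetate kinase, and lactate dehydrogenase. The
2.5 ATP/glucose and 3:2 acetate:lactate anchors are therefore structural
consequences of the network, independent of the biomass composition and of
the growth-associated maintenance (GAM) value — they hold for both GAM
values of interest (20 and 40 mmol ATP·gDCW⁻¹; default 40, the value
adopted with the AGORA-style biomass). Non-growth-associated maintenance
defaults to 0 (unconstrained for lack of data).

Feeder pathways: lactose permease + β-galactosidase + Leloir pathway;
3′FL via an ATP-driven ABC transporter and α-fucosidase into the fucose
branch (isomerase, fuculokinase, aldolase, lactaldehyde reductase →
1,2-propanediol, with the DHAP half re-entering glycolysis — so 1,2-PD and
pyruvate are producible only when the fucosylated substrate is fed); 6′SL
via sialidase and the aminosugar pathway (NeuAc lyase, ManNAc kinase,
epimerase, GlcNAc-6P deacetylase, GlcN-6P deaminase); LNnT via
β-hexosaminidase into galactose + GlcNAc + lactose. A pyruvate-formate
lyase / alcohol dehydrogenase branch is the NAD⁺-regenerating valve that
produces the characteristic low formate and ethanol fluxes whenever
biomass withdraws pyruvate; a lumped succinate branch is present but
bounds-disabled, so succinate secretion is always zero and its exchange
forms an isolated network node. Every internal reaction is carbon-balanced
(checked from formulas); the biomass drain (4 G6P + 2.5 pyruvate +
0.25 NH₄⁺ + GAM ATP per gDCW) and exchanges are the only boundaries.

Two deliberate design choices:

- **Aminosugar overflow.** NeuAc and GlcNAc have export transporters.
  The GlcNAc-6P deacetylase makes acetate obligatory when aminosugars are
  fully catabolized, which would make the imposed 3.5:2 ratio infeasible
  on the sialylated and tetrasaccharide substrates in a minimal network;
  partial utilization with overflow — which is also what expression data
  suggest for sialic acid in *B. infantis* — restores feasibility.
- **Minimal medium rigidity.** The in silico medium is minimal by design
  (carbon source + phosphate, ammonium, CO₂). A consequence is that the
  NADH balance pins lactate production, so the acetate:lactate ratio and
  μ are tightly linked and ratios below 3:2 are infeasible at positive
  growth. The published model's insensitivity of μ to the ratio setting
  stems from rich-medium side channels that this fixture intentionally
  lacks; tests therefore assert that the imposed ratio holds exactly and
  that constrained growth never exceeds the unconstrained optimum, not
  ratio-insensitivity.

In silico media contain one carbon source each at 2% wt/vol; uptake
bounds are mole-normalized to lactose (uptake = 10 · MW_lactose/MW_substrate
mmol·gDCW⁻¹·h⁻¹), so equal mass concentrations give comparable molar
feeds.

**Expression profiles** assign high values (~110, lognormal noise
σ = 0.15) to core shunt/glycolysis/fermentation genes in every condition,
high (~80) to a condition's own feeder genes, near-silent (~1.5) to
off-condition feeder genes, and moderate (~30) to a seeded random fraction
(default 0.15) of "crossed" genes — off-condition genes that are
nonetheless transcribed, as observed for fucosidases on lactose. Each
profile also carries 35 housekeeping genes outside the model: 20 low
(8–15) and 15 high (40–150). The low housekeeping band absorbs the
30th-percentile cut, so the threshold lands reproducibly between the
silent and the crossed/active bands in every condition regardless of the
noise draw — mimicking a transcriptome in which most genes are not
metabolic. Profiles are deterministic given the seed.

**Growth phenotype table** (10 substrates): the four study substrates
grow and are predicted to grow (TP); free glucose is a designed false
positive (the fixture grows on it, while *B. infantis* grows poorly on
free glucose); free fucose, ribose, and sorbitol are true negatives; 2′FL
and raffinose are fermented in vivo but absent from the fixture, giving
designed false negatives. Pipeline evaluation reproduces the designed
confusion matrix (TP=4, FP=1, TN=3, FN=2) exactly.

## Evaluation metrics

Binary growth calls use μ > 1e-6 h⁻¹ (aligned with the essentiality zero
tolerance). F = TP/(TP + (FP+FN)/2) and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) are implemented
literally from their definitions; when an MCC denominator factor is zero
the score is 0 with a warning (a common convention). On the published
confusion counts (TP=34, FP=4, TN=6, FN=4) the literal formulas give
F = 34/38 ≈ 0.8947 — matching the printed 89.4% — and MCC ≈ 0.495;
the printed MCC (0.482) and sensitivity/specificity are internally
inconsistent with those counts, so only the F-score is treated as an
exact target. RMSE over paired growth rates is the plain root mean
squared deviation.

## Validation strategy and problem sizes

Published yield, topology, and essentiality figures for *B. infantis* are
properties of full genome-scale reconstructions and are out of reach at
fixture scale, so validation is property-based against independent
brute-force oracles:

- LP engines vs exhaustive vertex enumeration (active-set combinatorics)
  on 200 random networks of ≤ 8 reactions: FBA equals the best vertex,
  pFBA total flux is no larger than any optimal vertex's, FVA bounds equal
  the vertex extremes of the objective-cut polytope, and all solutions are
  mass-balanced within 1e-6.
- FCA vs extreme-ray enumeration (nullspace analysis over column
  supports) on random networks of ≤ 6 reactions.
- Essentiality vs a scan that re-evaluates every GPR by boolean
  substitution (Python `eval` of the rule text) and re-solves growth with
  cobrapy/GLPK — an independent parser and an independent solver.
- GIMME growth preservation (μ ≥ 0.9 μ*) and monotonicity of the
  below-threshold set and inconsistency score over the percentile sweep
  {10, 30, 50, 70}.
- Qualitative flux signatures: 1,2-PD producible iff 3′FL is fed,
  succinate flux zero in all conditions, and relaxing the ratio constraint
  never increasing coupled-network edge counts.

Passing these shows the algorithms are correct and that the fixture
reproduces the qualitative metabolic signatures of the study system; it
does not show quantitative agreement with any real *B. infantis* data —
the fixture's biomass composition, uptake bounds, and expression bands are
stylized, its medium is minimal, and its size is two orders of magnitude
below a genome-scale reconstruction.

Problem sizes were chosen so the whole suite runs in a few minutes on one
CPU: the fixture has ~70 reactions, FCA on a context model solves a few
thousand small LPs, and the oracle families use 200 (vertex) and 30 (ray)
random networks.

## Known limitations

- The fucose, sialic-acid, and aminosugar branches are lumped to one
  reaction per enzymatic step; cofactor usage beyond ATP/NADH/Pi is not
  tracked, and protons/water are omitted (only carbon balance is checked).
- The GIMME objective uses the linear (t − x)·|v| penalty only; no
  iMAT/INIT-style alternatives.
- FCA treats a net reaction pair via its strongest half-pair relation;
  exotic sign-mixed couplings between reversible pairs are therefore
  reported optimistically.
- The Dn score is an interpretation (see above), suitable for ranking
  rewired nodes, not for comparison with values computed by other tools.
- No thermodynamic (loopless) constraints, dynamic FBA, or quadratic
  objectives.
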