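# Methods

This note documents the models, algorithms, parameter defaults and numerical
choices behind `proteogem`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Flux balance analysis

Growth is the solution of the linear program: maximize the biomass reaction
flux `Z = v_biomass` subject to steady-state mass balance `S v = 0` and box
bounds `a_i ≤ v_i ≤ b_i`. Fluxes are in mmol/gDW/h. Default bounds are
[0, 1000] for irreversible and [−1000, 1000] for reversible reactions; a
substrate uptake rate *u* is imposed as a lower bound of −*u* on the
substrate's exchange reaction, following the COBRA sign convention (uptake
negative, secretion positive). The LP is solved with HiGHS through
`scipy.optimize.linprog`.

**Growth units.** The biomass flux is reported directly as doublings/h,
mirroring how constraint-based growth simulations of *T. fusca* are
conventionally quoted; no ln 2 conversion is applied between specific growth
rate and doubling rate. This is a reporting convention, not a model change.

**Alternate optima.** Genome-scale LPs are degenerate: the objective value is
unique but individual fluxes are not. The package treats the objective as the
solver contract; per-reaction statements are made only through flux
variability analysis (`flux_variability`), which re-solves min/max LPs per
reaction with the objective pinned at its optimum (optionally a fraction of
it). Tests assert single fluxes only on networks constructed to be
non-degenerate.

**Infeasibility is data.** A draft model that cannot satisfy its constraints
under a realistic uptake (as automatically generated drafts often cannot)
returns `status="infeasible"` rather than raising, so failing models can be
compared and reported alongside working ones.

**Tolerances.** Steady-state residual check 1e−6 (absolute, on |S v|);
LP feasibility is left at the HiGHS defaults (~1e−9 primal tolerance);
"positive growth" means biomass flux > 1e−6.

## Evidence-driven reconstruction

High-confidence proteins are those with log10 expectation value strictly
below −10 (about a 1-in-10^10 chance of a random identification); the cutoff
is exposed as a parameter and the inequality is strict, so a protein at
exactly −10 is excluded. Sub-threshold identifications are retained in the
evidence table but contribute nothing to the draft; whether they should is
an open modeling question, and excluding them is the conservative choice.

Confident proteins map to EC numbers through an annotation table (a protein
with several ECs contributes all of them — no disambiguation rule is
imposed), and every reference-database reaction whose EC set intersects the
evidenced set enters the draft. Database reactions without EC annotation are
reachable only through curation rows, never through EC matching, so the
provenance of every draft reaction is explicit.

The shipped curation adds cellobiose utilization: hydrolysis
`C00185 + C00001 → 2 C00031` (beta-glucosidase, EC 3.2.1.21, locus Tfu_0937)
plus a cellobiose exchange. The 1:1:2 stoichiometry is the canonical
disaccharide hydrolysis; the enzyme assignment follows the expression
evidence on cellobiose-grown cells.

## Gap-filling

A draft's *blocked* biomass precursors are found one LP per precursor: the
biomass reaction is replaced by free drains for all precursors and the drain
of the probed metabolite is maximized; a maximum of zero (≤ 1e−6) marks it
blocked. Candidate repairs are database reactions touching a blocked
metabolite, scored by shortest-path distance in the metabolite–reaction
bipartite graph from the candidate to the nearest metabolite already in the
model. Two refinements matter:

* **Currency metabolites** (H2O C00001, ATP C00002, NAD C00003, NADP C00006,
  ADP C00008, phosphate C00009, CoA C00010, H+ C00080) are excluded from the
  graph, otherwise every reaction is two steps from every other.
* **Blocked metabolites are excluded from the distance sources.** A blocked
  precursor is still referenced by the biomass reaction, so every producer
  of it would trivially score distance 1; measuring distance to the
  *non-blocked* network instead ranks a producer whose substrates are
  already available above one that needs an unavailable intermediate first.

Selection is a MILP: one binary per candidate gates its flux bounds
(`lb·y ≤ v ≤ ub·y`), steady state holds over the merged network, biomass
flux must be positive, and the objective minimizes total candidate weight
(distance plus a 1e−6-scaled lexicographic perturbation that makes the
optimum generically unique, hence deterministic tie-breaking by reaction
id). If the initial pool (reactions touching blocked precursors) cannot
restore growth, the pool widens to all graph-reachable database reactions,
then to the whole database — multi-reaction repairs deeper than the blocked
frontier are found this way. Every pooled candidate is recorded in the
report, so added ⊆ candidates always holds.

The MILP's internal growth floor is 1e−3 (falling back to 1e−4 and 1e−5):
a floor of exactly 1e−6 sits inside the MIP solver's feasibility tolerance
and can be "satisfied" at zero flux. The chosen set is always re-verified
with an exact LP at the 1e−6 threshold before being accepted, so the firmer
internal floor affects search, not soundness. Because flux bounds are 1000
and restored optima in practice are orders of magnitude above 1e−3, the
firmer floor is not restrictive; a network whose maximum achievable growth
lay between 1e−6 and 1e−5 would be reported unfillable — a documented
limitation.

Generated boundary exchanges for dead-end extracellular metabolites are
available behind an opt-in flag (`allow_exchanges`): automatically built
drafts are often repaired mostly by exchanges, but free exchanges can mask
true pathway gaps, so the mode is never on by default. The original
workflow's manual evidence check for candidate reactions is replaced by the
distance-weighted objective, which encodes the same preference for
well-connected, plausible additions in machine-checkable form.

## Expression integration (iMAT-style)

Reactions are called `present` (some associated protein passes the
confidence filter), `absent` (all associated proteins measured, none pass)
or `unknown` (no association, or proteins never measured). The MILP assigns
one indicator per called reaction — present satisfied when |v| ≥ `eps_active`
(two binaries, one per direction, at most one active), absent satisfied when
|v| ≤ 1e−6 — and maximizes the number of satisfied calls over steady-state
flux distributions. Defaults: `eps_active` = 1.0 flux units (an activation
threshold is required by this formulation family and is inherently
arbitrary; it is a parameter, and analyses with uptake-limited fluxes below
1 should lower it), zero tolerance 1e−6. Biomass production is *not* forced
during integration — the objective is pure agreement, appropriate for model
validation — with an optional minimum-growth constraint for users who want
both.

## Pathway analytics

* **Completeness**: `round(100 · matched / reference)` with halves rounded
  away from zero (13/40 → 33, not banker's 32; validated against all 81
  packaged reference cells). A pathway is called present at ≥ 20%. The
  packaged reference table tabulates *reactions*; the presence rule is
  phrased in terms of gene coverage in common usage — the two coincide here
  because reactions carry the gene evidence, but the scoring unit is the
  reaction.
* **Model comparison** identifies a reaction by its KEGG R-number when the
  id matches `R#####`, else by a canonical hash of sorted
  (compound, coefficient) pairs, so models with heterogeneous id schemes
  intersect correctly.
* **Hub connectivity** counts reactions at |v| > 0.01 around the seven
  TCA-cycle exchange hubs (pyruvate C00022, acetoacetyl-CoA C00332,
  acetyl-CoA C00024, alpha-ketoglutarate C00026, succinyl-CoA C00091,
  fumarate C00122, oxaloacetate C00036), plus a deduplicated union. These
  counts inherit the alternate-optima caveat above.
* **Terpenoid backbone.** The packaged set holds 16 curated rows — 7
  mevalonate-route and 9 DXP-route reactions — of which 15 are unique (the
  IPP/DMAPP isomerase R01123 closes both routes). The curated equations
  deliberately omit cofactors (e.g. the HMG-CoA reductase step lacks
  NADPH), so they are suitable for flux-feasibility testing but are not
  mass-balanced; they are used verbatim and never rebalanced. Feasibility
  toward IPP (C00129) is tested by adding a temporary drain and maximizing
  it; on a toy acetyl-CoA-fed network the linear mevalonate route carries
  one equal flux per reaction while the isomerase can stay at zero — the
  flux *value* is not asserted because it depends on the supply bound.

## Synthetic study conditions

The generator's defaults are the study conditions: substrate uptake
0.25 mmol/gDW/h (the experimentally measured cellobiose uptake), confidence
cutoff −10, three parallel linear pathways of four reactions each, and a
proteome-scale table of 2101 identified proteins of which 1700 clear the
cutoff. Confident scores are drawn uniform in [−40, −11] and sub-threshold
scores in [−9, 0]: only the −10 boundary matters to downstream logic, so
the shapes are deliberately simple. Decoy proteins carry ECs absent from
the model. The toy network's growth optimum is closed-form
(`uptake / Σ 1/yield_j`), knockouts are verified essential by a
single-deletion scan before removal, and all generators are
seed-deterministic.

What passing on synthetic data shows: the LP/MILP machinery is exact at
small scale, reconstruction/repair recover planted ground truth, and the
pipeline wiring preserves it end to end. What it does not show: behavior on
realistic network topology (loops, cofactor coupling, promiscuous enzymes),
on noisy EC annotations, or at genome scale, where candidate pools are
orders of magnitude larger and gap-filling answers are not unique.
Whole-model growth reproduction additionally depends on the original
three-model spreadsheet, which is importable via
`pipeline.load_supplementary_models` but not redistributed.

## Biomass equation

The packaged growth objective is transcribed digit-for-digit from its
source, including two idiosyncrasies kept on purpose: L-glutamine's entry
(C00716… listed out of numeric order as 0.20970184 C00716 between C00064 and
C00070) and the C00059 coefficient 0.00780931, one final digit off the
trace value 0.00780937 used for every other trace compound. Whether the
equation is mass/charge balanced is not asserted anywhere — it is an
empirical growth recipe, not a balanced reaction — and no balancing is
enforced. 49 reactants, 5 products, 54 distinct compounds.

## Problem sizes

The test-suite and acceptance-script workloads are sized for a desk run:
100 random networks of ≤ 7 reactions for the vertex-enumeration check
(3^n basic-solution systems each), 50 knockout/recovery experiments with
23-reaction databases, exhaustive iMAT patterns for ≤ 6 calls, and toy
pipelines of ~15 reactions. These sizes make the independent oracles exact;
the implementation itself has no such limits.

## Known limitations

* Single flat compartment pair {cytosol, extracellular}; no pH/charge
  balancing, thermodynamics or atom mapping.
* Reaction reversibility is inferred from the lower bound sign only.
* The gap-fill distance graph ignores stoichiometric coefficients and
  reaction direction.
* iMAT uses binary present/absent calls, not the tri-level
  high/moderate/low of richer formulations, and no transcriptomics input.
* Exchange generation considers extracellular dead ends only.
* SBML I/O is delegated to cobrapy and covers the flat single/two
  compartment mapping used here, not arbitrary SBML models.
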