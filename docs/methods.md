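# Methods

## Scope and model class

`gemflux` analyses genome-scale metabolic models (GEMs) under the
steady-state constraint-based formalism.  A model is a stoichiometric
matrix S (metabolites × reactions) together with per-reaction flux bounds
l ≤ v ≤ u in mmol gDW⁻¹ h⁻¹.  Flux balance analysis (FBA) solves

    max  c·v   s.t.   S v = 0,   l ≤ v ≤ u

with c selecting a single reaction, usually the biomass objective function
(BOF).  The BOF drains precursors in growth-proportional stoichiometry, so
its flux is the growth rate μ; when the drained biomass weighs about
1 g mmol⁻¹, μ is numerically comparable to a specific growth rate in h⁻¹.
That weight is computed from the biomass stoichiometry and standard atomic
masses (IUPAC 2021 standard weights, embedded at six significant figures)
as (reactant mass − product mass)/1000 g mmol⁻¹, and is invariant under
scaling the biomass equation, because the growth-rate interpretation
rescales by the same factor.

Only objective values and flux-variability ranges are deterministic
contracts.  Production optima are usually degenerate; reported flux
vectors (and the CO₂/ATP rates read off them) are one optimal vertex and
may legitimately differ between solvers or runs of equal objective value.

## Solver

All LPs and MILPs are solved with HiGHS through SciPy (`linprog`/`milp`),
with primal and dual feasibility tolerances of 1e-9.  Steady state is
enforced to solver tolerance; conservation is asserted in tests at
max|S·v| ≤ 1e-6.  Infeasibility and unboundedness are reported as solution
statuses, never exceptions, except where an operation's contract requires
a feasible model up front (e.g. FVA refuses to iterate over an infeasible
model).

## Flux variability and the loop law

FVA minimises and maximises each reaction flux over the feasible region;
any prior objective fixing must already be encoded in the bounds (the
`fix_flux` helper pins both bounds of a reaction to a value inside its
original range).  Loopless FVA additionally forbids thermodynamically
infeasible internal cycles.  A reaction is *internal* iff it moves no
species across the system boundary — not an exchange, demand, sink, or
biomass pseudo-reaction and not one-sided.  The default method is the
nullspace MILP: binary direction indicators aᵢ per internal reaction
couple the flux sign to a potential-like variable Gᵢ ∈ ±[1, 1000], and a
basis K of the nullspace of S restricted to internal columns enforces
KᵀG = 0, which excludes any flux pattern conformal to an internal cycle.
Big-M is 1000, matching the default bound magnitude.  This formulation is
exact and is verified against exhaustive sign-pattern enumeration on small
models.  A CycleFreeFlux-style post-processing fallback
(`method="cycle_free"`) is offered for speed on genome-scale models: each
plain-FVA vertex is projected to a loop-free flux by fixing its boundary
fluxes, trapping each internal flux between 0 and its vertex value, and
minimising the L1 norm.  The fallback's ranges are always contained in the
plain FVA ranges but can under-report the exact loopless range when the
optimal vertex pairs the target reaction with a cycle at a different
boundary pattern; the MILP is the reference.

*Pinned reactions* are those whose (loopless) FVA bounds coincide within
|max − min| ≤ abs_tol + rel_tol·max(|max|, |min|), with abs_tol = 1e-8 and
rel_tol = 1e-5 by default.  The additive combination mirrors the common
closeness predicate.  Before the FVA, growth is fixed (default
0.4 mmol gDW⁻¹ h⁻¹) and the production objective is computed and itself
fixed at its optimum, so the pinned set describes what the optimum
determines.  Pseudo-reactions are deliberately included — the exchange of
the carbon source and the production sink are typically among the pinned
set and are informative.

## Quality audit

**Balance.** Per non-pseudo reaction, element residuals are Σ coeff·count
per element and the charge residual Σ coeff·charge.  Pseudo-reactions
(recognised by id prefix `EX_`/`DM_`/`SK_`/`sink_` or SBO term for
exchange/demand/sink/biomass — the union of both signals, since deposited
models vary) are excluded: they create or destroy matter by design.
Missing formulas or charges, and generic-moiety pseudo-elements R/X, make
a reaction *unverifiable*, which is reported distinctly from *imbalanced*;
absence is never imputed as zero.  Element residual tolerance is 1e-6
(coefficients may be fractional); charge residuals of integer charges
should vanish exactly and are tested at 1e-9.

**Topology.** A metabolite is an *orphan* if no reaction can produce it
and a *dead end* if none can consume it, judging direction from the
bounds, so reversible reactions act as both producers and consumers, and
exchange/sink reactions count for their species.

**Stoichiometric consistency.** The model is consistent where a strictly
positive conserved mass vector m with Sᵢₙₜᵀm = 0 exists over the
non-pseudo reactions.  The reported fraction is the share of metabolites
that can carry mass ≥ ε (ε = 1e-4, mass cap 1000) in some feasible
assignment, computed exactly with the standard MILP relaxation (binary
indicator per metabolite, maximise the count); an LP surrogate
(maximise Σ min(mᵢ, ε)) is available behind `exact=False` for speed.

**Energy-generating cycles (EGCs).** Thirteen energy/redox carriers are
scanned: ATP, CTP, GTP, UTP, ITP, NADH, NADPH, FMN, FAD, menaquinol-8,
2-demethylmenaquinol-8, acetyl-CoA and L-glutamate.  All exchange bounds
are closed, the cytosol–periplasm proton exchange is kept open, and one
canonical dissipation reaction per carrier is added one-at-a-time and
maximised — hydrolysis forms for the triphosphates (NTP + H₂O → NDP + Pi
+ H⁺), reoxidation forms for the redox carriers (NAD(P)H → NAD(P)⁺ + H⁺;
quinol → quinone + 2H⁺; the flavins are scanned via their reduced
species), acetyl-CoA + H₂O → acetate + CoA + H⁺, and glutamate + H₂O →
2-oxoglutarate + NH₄⁺ + 2H⁺, each balanced in the cytosol.  A nonzero
optimum exposes a cycle that charges the carrier for free; the reactions
with |flux| > 1e-6 at that optimum are reported as the cycle support.
Carriers whose species are absent are skipped with a note rather than
failing the scan.

## Media and growth

A medium is a named map exchange-reaction → uptake magnitude, shipped as
YAML data with a uniform default magnitude of 10 mmol gDW⁻¹ h⁻¹ for every
component, ions included.  Applying a medium sets listed exchange lower
bounds to −magnitude and all other exchange lower bounds to 0; secretion
(upper) bounds are untouched.  The aerobic switch overrides the oxygen
exchange separately (−magnitude or 0), and oxygen uptake defaults to the
same −10 convention, exposed as configuration since unlimited-oxygen
variants change complete-medium growth rates.  The carbon source is
marked explicitly in the medium file and swapped, not inferred from
chemistry.  Growth below 1e-6 is reported as zero.  Three media are
bundled: CGXII (the C. glutamicum minimal medium, protocatechuate
included), M9, and a chemically defined LB approximation — LB has no
exact chemical definition, so that file is labelled an approximation and
is excluded from quantitative comparisons.

## Production analyses

Production of a metabolite is probed with a sink reaction (irreversible
drain, bounds 0/1000, id `sink_<met>` with the compartment suffix
dropped; adding twice is a no-op).  The amino-acid profile fixes growth
at 0.4 mmol gDW⁻¹ h⁻¹ under glucose uptake 10, then maximises each of
the 20 canonical amino-acid sinks (BiGG cytosolic ids shipped as data)
and records the production rate, the molar yield on glucose
(rate/uptake), the CO₂ efflux, and the ATP production rate.  ATP
accounting counts, per reaction, only positive cytosolic-ATP
contributions max(0, coeff(atp_c)·flux); transport phosphorylation is
thus counted where it nets ATP in the cytosol.  Because the optimum is
degenerate, CO₂/ATP rates are vertex-dependent even though the
production rate is not; tests therefore accept the small interval spanned
by the equivalent vertices.

The trade-off curve fixes growth on a grid (30 even points from 0 to the
growth optimum by default) and maximises the product sink at each point.
LP parametric theory guarantees the curve is non-increasing and concave
in μ; both are asserted on every model tested.  The knockout experiment
runs the identical pipeline for wild type and knockout (reaction bounds
0/0, or gene knockout through the GPR rules: AND = all subunits
required, OR = isoenzymes) and emits both flux distributions; a knockout
that makes the growth fix infeasible is reported in the record status,
not raised.

## Synthetic generators

The generators provide the study conditions offline and are first-class,
tested code.

**Linear chain.**  Exchange ⇌ transport → unit-stoichiometry chain →
biomass drain.  Every metabolite carries the same real formula, so all
conversions are balanced and the audits run unmodified.  By flow
conservation the growth optimum equals the uptake bound exactly — the
simplest nontrivial FBA oracle.

**Glutamate core.**  A fixed (not randomised) ~29-reaction network of the
primary route from D-glucose to L-glutamate: PEP:sugar phosphotransferase
uptake, a lumped glycolysis (G6P + 2 NAD⁺ + ADP + 2 Pi → 2 PEP + 2 NADH +
ATP + 2 H₂O + 3 H⁺), pyruvate kinase, both anaplerotic carboxylases (PEP
carboxylase, and pyruvate carboxylase at one ATP), pyruvate
dehydrogenase, citrate synthase, aconitase, NADP-dependent isocitrate
dehydrogenase, NADPH-dependent glutamate dehydrogenase, an acetate
overflow (phosphotransacetylase + acetate kinase lump), respiration as a
single NADH-oxidation/oxidative-phosphorylation lump at P/O = 2, ATP
maintenance, and a biomass reaction draining 0.0149 glutamate and 40 ATP
per unit growth.  All reactions are elementally and charge balanced with
real formulas.  The fixed topology makes the production analytics exact
closed forms that live in the test suite as constants: each glucose
yields at most one glutamate (its PEP/pyruvate pair supplies exactly one
oxaloacetate plus one acetyl-CoA), 7 ATP per glucose routed to glutamate
and 12 per glucose routed to the overflow, hence

    p(μ) = 10 − 0.0149·μ          for μ ≤ 1.75   (carbon-limited)
    p(μ) = 24 − 8.0149·μ          for μ ≥ 1.75   (ATP-limited)

with μ_max = 24/8.0149 ≈ 2.994.  The two-segment shape reproduces the
qualitative behaviour of genome-scale trade-off curves — a shallow
carbon-limited decline with slope equal to the biomass glutamate
coefficient, then a steep energy-limited fall.  The glutamate biomass
coefficient (0.0149), glucose uptake (10) and the growth fix (0.4) are
the study conditions; the ATP demand (40 mmol gDW⁻¹, a typical
growth-associated maintenance magnitude), P/O ratio 2 and the acetate
overflow as the non-product carbon/energy outlet are the package's own
physiological choices, made once.  The core's reference state leaves
oxygen non-limiting (bound 1000) so that glucose is the single binding
resource in the closed forms; applying a −10 oxygen medium instead makes
respiration binding and the closed forms no longer apply.  The PC
knockout is exactly compensated by PEP carboxylase (with pyruvate kinase
shuttling PEP to pyruvate, the two routes have identical net ATP cost at
the production optimum), and knocking out both anaplerotic routes
abolishes glutamate production — the double-route structure the knockout
analyses require.

**Planted defects.**  Defects are planted as separate branch reactions so
that each is found by exactly one detector: a mass imbalance as a new
branch product whose formula is perturbed by one hydrogen, drained by a
sink (sinks are pseudo-reactions, so only the planted reaction is
flagged, and the branch creates no dead end); dead ends and orphans as
one-sided terminal branches with unchanged formulas; an energy cycle as
the exact reverse of a carrier's dissipation reaction added as an
internal reaction.  Planted ids are recorded in
`model.notes["planted_defects"]`, which is what the exactness tests
compare against.  Generation is fully deterministic: identical generator
specs yield byte-identical SBML.

What the generators do *not* emulate: genome-scale redundancy (thousands
of reactions, isoenzyme-rich GPRs), compartmentalised proton motive
force, annotation richness, fractional biomass compositions over dozens
of precursors, or numerically delicate near-degenerate bounds.  Passing
the synthetic suite therefore demonstrates correctness of the machinery
on exactly solvable instances, not predictive fidelity on any real
organism; the deposited-model harness (`scripts/reproduce_deposited.py`)
exists for the latter and requires the user to supply the downloaded
SBML file.

## SBML and table I/O

Files are SBML Level 3 Version 1 with fbc version 2 (strict) and groups
version 1, written and parsed with libSBML.  The model element declares
`extentUnits`/`timeUnits` and `substanceUnits` (mmol gDW⁻¹, i.e. mole at
scale −3 per gram) with `volumeUnits` fl; flux bounds are shared constant
parameters in mmol gDW⁻¹ h⁻¹, one per distinct value.  GPR strings
round-trip through fbc gene-product associations (the textual form may
gain parentheses; semantics are preserved and tested by truth-table
comparison).  Annotations are MIRIAM-style identifiers.org CV terms;
only presence/coverage is computed, never resolved online.  Subsystems
are serialised as groups with reaction members.  Missing formula/charge
round-trip as absent.  Writing is deterministic.

The CSV converter accepts comma-separated UTF-8 tables with a header row;
equations use `->`/`=>`/`→` (irreversible) or `<->`/`<=>`/`⇌`
(reversible), species on both sides cancel, and blank bounds fall back to
the BiGG convention (0/1000 irreversible, −1000/1000 reversible).  The
original spreadsheet dialect of the older C. glutamicum reconstruction is
undocumented, so this dialect is a documented stand-in.

## Problem sizes

The test suite and the acceptance script run entirely on the generators:
chains of 1–30 steps, the 29-reaction core, and tiny (≤ 10-reaction)
oracle instances where brute-force vertex enumeration and exhaustive
sign-pattern enumeration are feasible.  The exact loop-law MILP is the
default for these sizes; for genome-scale FVA the CycleFreeFlux fallback
is the practical choice and is exposed everywhere the MILP is.

## Known limitations

* The loop-law MILP assumes bound magnitudes ≤ 1000 (Big-M); models with
  wider bounds need the constant raised.
* The CycleFreeFlux fallback can return strictly narrower ranges than
  the exact loopless range (documented above).
* CO₂/ATP rates at production optima are vertex-dependent under
  degeneracy; only production rates are contractual.
* The consistency MILP can be slow on badly inconsistent genome-scale
  models; the LP surrogate is exact only when the model is fully
  consistent or the inconsistent set is unique.
* No pFBA, MOMA, flux sampling, dynamic FBA, or ΔG-based thermodynamic
  constraints; no annotation enrichment or web lookups.
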