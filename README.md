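# gemflux

Constraint-based analysis of genome-scale metabolic models (GEMs):
SBML (fbc/groups) I/O, flux balance analysis, flux variability analysis
with an exact loop law, model-quality auditing, medium-constrained growth
simulation, and amino-acid production phenotyping — built around the
analysis workflow used to validate high-quality reconstructions of the
industrial amino-acid producer *Corynebacterium glutamicum*.

## Who this is for

Systems biologists and metabolic engineers who need to (a) read, write,
convert and audit GEMs in SBML Level 3 with the fbc and groups packages,
and (b) reproduce the standard phenotype analyses — growth on defined
media under aerobic/anaerobic conditions, carbon-source scans, production
trade-offs, knockouts, and pinned-reaction identification via loopless
FVA — without a commercial solver: all optimisation runs on HiGHS through
SciPy.

## The core computation

Flux balance analysis maximises an objective flux subject to steady state
and bounds,

    max c·v    s.t.  S v = 0,  l ≤ v ≤ u,

with fluxes in mmol gDW⁻¹ h⁻¹.  The biomass objective function (BOF)
drains precursors in growth-proportional stoichiometry, so its flux is
the growth rate μ; when the drained biomass weighs ≈ 1 g mmol⁻¹ (a
quantity the package computes from formulas and standard atomic masses),
μ is numerically comparable to a specific growth rate in h⁻¹.  Flux
variability analysis reports per-reaction min/max fluxes; its loopless
variant excludes thermodynamically infeasible internal cycles via an
exact nullspace-MILP loop law (with a fast CycleFreeFlux-style fallback).
Reactions whose loopless range collapses to a point — *pinned*
reactions — are the ones an optimum fully determines.

The quality audit covers per-reaction elemental/charge balance (pseudo-
reactions excluded, missing data reported as *unverifiable* rather than
imbalanced), dead-end and orphan metabolites, stoichiometric consistency
(existence of strictly positive conserved masses, solved as a MILP),
biomass molecular weight, an energy-generating-cycle scan over 13
energy/redox carriers with canonical dissipation reactions, and
annotation/SBO coverage.

Deterministic synthetic generators — a linear chain with a provable
optimum and a glutamate-producing core network with a hand-derivable
growth/production trade-off and plantable defects — make every stage
verifiable offline; see `docs/methods.md` for the model details and the
closed-form expectations.

## Worked example

Generate the bundled glutamate core model and run the headline analyses:

```python
from gemflux import make_glutamate_core, write_sbml
write_sbml(make_glutamate_core(), "core.xml")
```

```text
$ gemflux growth core.xml --out run
mu = 2.99442 mmol gDW^-1 h^-1

$ gemflux knockout core.xml --reaction PC --out ko
production before KO: 9.99404; after KO: 9.99404

$ gemflux tradeoff core.xml --points 7 --out t && cat t/tradeoff.tsv
mu      max_production  status
0       10      optimal
0.49907 9.99256 optimal
0.998141        9.98513 optimal
1.49721 9.97769 optimal
1.99628 8       optimal
2.49535 4       optimal
2.99442 7.20257e-15     optimal
```

Reading the numbers: the maximal growth rate is μ_max = 24/8.0149 ≈
2.994 mmol gDW⁻¹ h⁻¹ (ATP-limited).  Maximal glutamate production starts
at 10 (one glutamate per glucose at uptake 10) and falls along the
biomass glutamate coefficient (slope −0.0149) while carbon is limiting,
then along the ATP budget (slope −8.0149) until it reaches zero at
μ_max — the shallow-then-steep shape characteristic of genome-scale
trade-off curves.  Knocking out pyruvate carboxylase (PC) changes
production not at all: PEP carboxylase carries the anaplerotic flux at
identical net ATP cost, which is why `gemflux pinned` lists the
glycolysis/TCA backbone (GLCpts, CS, ACONT, ICDHyr, the glucose exchange
and the glutamate sink) but neither PC, PPC nor PYK.

The audit subcommand gives a clean bill for the generators and a CI-style
exit code:

```text
$ gemflux audit core.xml --out audit
{"consistent_fraction": 1.0, "biomass_weight_g_per_mmol": 0.0021772...}
```

Other entry points: `gemflux aa-profile` (production economics of the 20
canonical amino acids at fixed growth), `gemflux synth --spec spec.yaml`
(deterministic synthetic models with plantable defects), and
`gemflux convert` (CSV reaction/metabolite/gene tables → SBML L3V1+fbc).

To run the same analyses on a deposited genome-scale reconstruction,
download the SBML file (e.g. BioModels MODEL2102050001) and point the
harness at it:

```bash
python scripts/reproduce_deposited.py --model iCGB21FR.xml \
    --out results/deposited.json
```

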