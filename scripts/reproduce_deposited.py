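#!/usr/bin/env python
"""Recompute the headline results on the deposited C. glutamicum model.

Requires a locally downloaded copy of the iCGB21FR SBML file (BioModels
accession MODEL2102050001); nothing is downloaded here.  Recomputes entity
counts, the quality audit (imbalanced reactions, dead ends/orphans,
stoichiometric consistency, biomass weight, energy-cycle scan), growth on
the bundled media under aerobic/anaerobic conditions, the carbon-source
scan, the amino-acid production profile at growth 0.4, the
growth-glutamate trade-off, the pyruvate-carboxylase knockout pair, and
the pinned-reaction set from loopless FVA.

Usage:
    python scripts/reproduce_deposited.py --model iCGB21FR.xml \
        --out results/deposited.json [--exact-loopless]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from gemflux import (add_sink, amino_acid_profile, apply_medium,
                     balance_audit, biomass_weight, bundled_media, egc_scan,
                     fba, find_dead_ends, knockout_experiment, model_summary,
                     pinned_reactions, read_sbml, stoichiometric_consistency,
                     swap_carbon_source, tradeoff_curve)

CARBON_SOURCES = ["EX_glc__D_e", "EX_fru_e", "EX_sucr_e", "EX_rib__D_e",
                  "EX_glcn_e", "EX_pyr_e", "EX_ac_e", "EX_lac__L_e",
                  "EX_ppa_e"]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model", type=Path, required=True,
                        help="Path to the downloaded iCGB21FR SBML file.")
    parser.add_argument("--out", type=Path,
                        default=Path("results/deposited.json"))
    parser.add_argument("--exact-loopless", action="store_true",
                        help="Use the exact loop-law MILP for the pinned-"
                             "reaction FVA (slow); default is the "
                             "CycleFreeFlux post-processing.")
    args = parser.parse_args()

    model = read_sbml(str(args.model))
    media = bundled_media()
    cgxii = media["CGXII"]
    out: dict = {"summary": model_summary(model)}
    out["n_reaction_sbo_terms"] = len(out["summary"]["sbo_histogram"])

    records = balance_audit(model)
    out["n_imbalanced_reactions"] = sum(not r.ok for r in records)
    topo = find_dead_ends(model)
    out["n_dead_end"] = len(topo["dead_end"])
    out["n_orphan"] = len(topo["orphan"])
    out["stoichiometric_consistency"] = stoichiometric_consistency(
        model, exact=False).consistent_fraction
    try:
        out["biomass_weight_g_per_mmol"] = biomass_weight(model)
    except Exception as exc:  # noqa: BLE001
        out["biomass_weight_g_per_mmol"] = None
        out["biomass_weight_note"] = str(exc)
    out["max_egc_dissipation"] = max(
        (r.dissipation_flux for r in egc_scan(model) if not r.skipped),
        default=0.0)

    growth: dict = {}
    for name, medium in media.items():
        for aerobic in (True, False):
            constrained = apply_medium(model, medium, aerobic=aerobic)
            sol = fba(constrained)
            key = f"{name}_{'aerobic' if aerobic else 'anaerobic'}"
            growth[key] = sol.objective if sol.optimal else 0.0
    out["growth"] = growth

    scan: dict = {}
    for source in CARBON_SOURCES:
        for aerobic in (True, False):
            key = f"{source}_{'aerobic' if aerobic else 'anaerobic'}"
            try:
                medium = swap_carbon_source(cgxii, source)
                sol = fba(apply_medium(model, medium, aerobic=aerobic))
                scan[key] = sol.objective if sol.optimal else 0.0
            except Exception as exc:  # noqa: BLE001
                scan[key] = f"error: {exc}"
    out["carbon_sources"] = scan

    constrained = apply_medium(model, cgxii, aerobic=True)
    profile = amino_acid_profile(constrained, glucose_uptake=10.0,
                                 growth_fix=0.4)
    out["amino_acid_profile"] = {
        r.target: {"production_rate": r.production_rate,
                   "co2_rate": r.co2_rate, "atp_rate": r.atp_rate,
                   "status": r.status}
        for r in profile}
    rates = [(r.atp_rate, r.production_rate) for r in profile
             if r.status == "optimal"]
    if len(rates) >= 3:
        from scipy.stats import spearmanr
        rho, _ = spearmanr([r[0] for r in rates], [r[1] for r in rates])
        out["atp_vs_production_spearman"] = rho

    sink = add_sink(constrained, "glu__L_c")
    curve = tradeoff_curve(constrained, sink, n_points=30)
    out["glutamate_tradeoff"] = curve.points
    ko = knockout_experiment(constrained, reaction_id="PC",
                             product="glu__L_c", growth_fix=0.4)
    out["glutamate_at_0p4_wild_type"] = ko["before"].production_rate
    out["glutamate_at_0p4_pc_knockout"] = ko["after"].production_rate

    method = "milp" if args.exact_loopless else "cycle_free"
    pinned = pinned_reactions(constrained, sink, growth_fix=0.4,
                              rel_tol=1e-5, abs_tol=1e-8, loopless=True,
                              method=method)
    out["pinned_reactions"] = pinned.reaction_ids

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2, default=str) + "\n")
    print(json.dumps({k: v for k, v in out.items()
                      if k not in ("amino_acid_profile",
                                   "glutamate_tradeoff")}, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
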