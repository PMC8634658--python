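"""Model-quality audits: balance, topology, consistency, energy cycles.

The audits mirror the curation checklist applied to high-quality genome
scale reconstructions: per-reaction elemental/charge balance (pseudo
reactions excluded), dead-end and orphan metabolites, stoichiometric
consistency (existence of strictly positive conserved metabolite masses),
biomass molecular weight (ideally ~1 g mmol^-1 so the growth flux is
numerically comparable to a rate in 1/h), an energy-generating-cycle scan
over the 13 canonical energy/redox carriers, and annotation/SBO coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .formula import ElementTally, parse_formula
from .model import GemModel, Reaction
from .optimize import SOLVER_OPTIONS, _solve_lp, build_matrix, fba

__all__ = [
    "BalanceRecord",
    "EGCResult",
    "ConsistencyReport",
    "UnverifiableBiomassError",
    "balance_audit",
    "find_dead_ends",
    "stoichiometric_consistency",
    "biomass_weight",
    "egc_scan",
    "annotation_coverage",
    "EGC_CARRIERS",
    "DISSIPATION_RECIPES",
]

ELEMENT_TOL = 1e-6  # coefficients may be fractional
CHARGE_TOL = 1e-9   # charges are integers; residual should vanish exactly
FLUX_SUPPORT_TOL = 1e-6


class UnverifiableBiomassError(ValueError):
    """Biomass participants lack chemical formulas; message lists them."""


@dataclass
class BalanceRecord:
    reaction_id: str
    element_residuals: Dict[str, float]  # products minus reactants
    charge_residual: Optional[float]
    verdict: str  # balanced | mass_imbalanced | charge_imbalanced | both | unverifiable

    @property
    def ok(self) -> bool:
        return self.verdict in ("balanced", "unverifiable")


@dataclass
class EGCResult:
    carrier: str
    dissipation_flux: float
    cycle_support: List[str]
    skipped: bool = False
    note: str = ""


@dataclass
class ConsistencyReport:
    consistent_fraction: float
    inconsistent_metabolites: List[str]
    biomass_weight: Optional[float] = None


# ---------------------------------------------------------------------------
# Elemental and charge balance
# ---------------------------------------------------------------------------

def _audit_one(rxn: Reaction, mets: Dict[str, "object"]) -> BalanceRecord:
    mass_verifiable = True
    charge_verifiable = True
    residuals: Dict[str, float] = {}
    charge_res = 0.0
    for mid, coeff in rxn.stoichiometry.items():
        met = mets[mid]
        if met.formula is None:
            mass_verifiable = False
        else:
            tally = parse_formula(met.formula)
            if not tally.balanceable:
                mass_verifiable = False
            else:
                for elem, count in tally.items():
                    residuals[elem] = residuals.get(elem, 0.0) + coeff * count
        if met.charge is None:
            charge_verifiable = False
        else:
            charge_res += coeff * met.charge

    residuals = {e: r for e, r in residuals.items() if abs(r) > ELEMENT_TOL}
    mass_bad = mass_verifiable and bool(residuals)
    charge_bad = charge_verifiable and abs(charge_res) > CHARGE_TOL
    if mass_bad and charge_bad:
        verdict = "both"
    elif mass_bad:
        verdict = "mass_imbalanced"
    elif charge_bad:
        verdict = "charge_imbalanced"
    elif not (mass_verifiable and charge_verifiable):
        verdict = "unverifiable"
    else:
        verdict = "balanced"
    return BalanceRecord(
        reaction_id=rxn.id,
        element_residuals=residuals if mass_verifiable else {},
        charge_residual=charge_res if charge_verifiable else None,
        verdict=verdict,
    )


def balance_audit(model: GemModel) -> List[BalanceRecord]:
    """One record per non-pseudo reaction.

    Exchange, demand, sink and biomass pseudo-reactions are excluded: they
    intentionally create or destroy matter.  A reaction is *unverifiable*
    (not imbalanced) when a participant lacks a formula or charge or
    carries a generic-moiety pseudo-element.
    """
    mets = {m.id: m for m in model.metabolites}
    return [_audit_one(r, mets) for r in model.reactions if not r.is_pseudo]


# ---------------------------------------------------------------------------
# Dead-end and orphan metabolites
# ---------------------------------------------------------------------------

def find_dead_ends(model: GemModel) -> Dict[str, List[str]]:
    """Metabolites never consumed (*dead_end*) or never produced (*orphan*).

    Direction is judged from the bounds, so a reversible reaction both
    produces and consumes each participant, and exchange/sink reactions
    count as producers and consumers of their species.
    """
    producible = set()
    consumable = set()
    for rxn in model.reactions:
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for mid, coeff in rxn.stoichiometry.items():
            if (coeff > 0 and fwd) or (coeff < 0 and rev):
                producible.add(mid)
            if (coeff < 0 and fwd) or (coeff > 0 and rev):
                consumable.add(mid)
    dead_end = [m.id for m in model.metabolites if m.id not in consumable]
    orphan = [m.id for m in model.metabolites if m.id not in producible]
    return {"dead_end": dead_end, "orphan": orphan}


# ---------------------------------------------------------------------------
# Stoichiometric consistency
# ---------------------------------------------------------------------------

def stoichiometric_consistency(model: GemModel, epsilon: float = 1e-4,
                               max_mass: float = 1000.0,
                               exact: bool = True) -> ConsistencyReport:
    """Fraction of metabolites assignable a strictly positive conserved mass.

    Seeks molecular masses m >= 0 with S_int' m = 0 over the non-pseudo
    reactions and maximises the number of metabolites with m_i >= epsilon.
    ``exact=True`` solves the standard MILP relaxation (binary indicator
    per metabolite); ``exact=False`` maximises the LP surrogate
    sum(min(m_i, epsilon)) which is faster and exact whenever the model is
    either fully consistent or the inconsistent set is unique.
    """
    internal = [r for r in model.reactions if not r.is_pseudo]
    met_ids = [m.id for m in model.metabolites]
    if not met_ids:
        return ConsistencyReport(1.0, [])
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    n = len(met_ids)
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(internal):
        for mid, coeff in rxn.stoichiometry.items():
            rows.append(j)
            cols.append(met_pos[mid])
            vals.append(coeff)
    # rows: one conservation equation m·stoich = 0 per internal reaction
    S_T = sp.csc_matrix((vals, (rows, cols)), shape=(len(internal), n))

    if exact:
        # variables: m (n) | z (n, binary); maximise sum z
        A_eq = sp.hstack([S_T, sp.csc_matrix((len(internal), n))])
        A_link = sp.hstack([sp.identity(n, format="csc"),
                            -epsilon * sp.identity(n, format="csc")])
        constraints = [
            LinearConstraint(A_eq, 0.0, 0.0),
            LinearConstraint(A_link, 0.0, np.inf),  # m_i >= eps * z_i
        ]
        c = np.concatenate([np.zeros(n), -np.ones(n)])
        res = milp(c, constraints=constraints,
                   bounds=Bounds(np.zeros(2 * n),
                                 np.concatenate([max_mass * np.ones(n),
                                                 np.ones(n)])),
                   integrality=np.concatenate([np.zeros(n), np.ones(n)]))
        if res.status != 0:
            raise RuntimeError(f"consistency MILP failed with status {res.status}")
        z = res.x[n:]
        consistent = z > 0.5
    else:
        # variables: m (n) | t (n), t_i <= min(m_i, eps); maximise sum t
        A_eq = sp.hstack([S_T, sp.csc_matrix((len(internal), n))])
        A_link = sp.hstack([sp.identity(n, format="csc"),
                            -sp.identity(n, format="csc")])
        from scipy.optimize import linprog
        res = linprog(
            np.concatenate([np.zeros(n), -np.ones(n)]),
            A_eq=A_eq, b_eq=np.zeros(len(internal)),
            A_ub=-A_link, b_ub=np.zeros(n),  # t_i - m_i <= 0
            bounds=np.column_stack([
                np.zeros(2 * n),
                np.concatenate([max_mass * np.ones(n), epsilon * np.ones(n)]),
            ]),
            method="highs", options=dict(SOLVER_OPTIONS))
        if res.status != 0:
            raise RuntimeError(f"consistency LP failed with status {res.status}")
        consistent = res.x[n:] >= epsilon * (1 - 1e-6)

    inconsistent = [met_ids[i] for i in range(n) if not consistent[i]]
    return ConsistencyReport(
        consistent_fraction=float(np.count_nonzero(consistent)) / n,
        inconsistent_metabolites=inconsistent,
    )


# ---------------------------------------------------------------------------
# Biomass molecular weight
# ---------------------------------------------------------------------------

def biomass_weight(model: GemModel, biomass_id: Optional[str] = None) -> float:
    """Molecular weight of the produced biomass in g mmol^-1.

    Computed as (sum of reactant mass - sum of product mass) / 1000 over
    the biomass pseudo-reaction with standard atomic weights; a value close
    to 1 means growth flux and specific growth rate (1/h) coincide
    numerically.
    """
    biomass_id = biomass_id or model.objective
    if biomass_id is None:
        raise ValueError("no biomass reaction specified and model has no objective")
    rxn = model.reaction(biomass_id)
    mets = {m.id: m for m in model.metabolites}
    missing = []
    grams = 0.0
    for mid, coeff in rxn.stoichiometry.items():
        met = mets[mid]
        if met.formula is None:
            missing.append(mid)
            continue
        tally = parse_formula(met.formula)
        if not tally.balanceable:
            missing.append(mid)
            continue
        grams += -coeff * tally.weight()  # reactants (coeff<0) add mass
    if missing:
        raise UnverifiableBiomassError(
            f"biomass participants without usable formula: {sorted(missing)}")
    return grams / 1000.0


# ---------------------------------------------------------------------------
# Energy-generating cycles
# ---------------------------------------------------------------------------

#: The 13 energy/redox carriers scanned by default.  Keys are carrier
#: names, values are the cytosolic species of the charged form.
EGC_CARRIERS: Dict[str, str] = {
    "ATP": "atp_c", "CTP": "ctp_c", "GTP": "gtp_c", "UTP": "utp_c",
    "ITP": "itp_c", "NADH": "nadh_c", "NADPH": "nadph_c",
    "FMN": "fmnh2_c", "FAD": "fadh2_c",
    "MQL8": "mql8_c", "2DMMQL8": "2dmmql8_c",
    "ACCOA": "accoa_c", "GLU": "glu__L_c",
}

#: Canonical dissipation reactions (hydrolysis / reoxidation forms), all in
#: the cytosol with protons balanced in the carrier's own compartment.
DISSIPATION_RECIPES: Dict[str, Dict[str, float]] = {
    "ATP": {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
    "CTP": {"ctp_c": -1, "h2o_c": -1, "cdp_c": 1, "pi_c": 1, "h_c": 1},
    "GTP": {"gtp_c": -1, "h2o_c": -1, "gdp_c": 1, "pi_c": 1, "h_c": 1},
    "UTP": {"utp_c": -1, "h2o_c": -1, "udp_c": 1, "pi_c": 1, "h_c": 1},
    "ITP": {"itp_c": -1, "h2o_c": -1, "idp_c": 1, "pi_c": 1, "h_c": 1},
    "NADH": {"nadh_c": -1, "nad_c": 1, "h_c": 1},
    "NADPH": {"nadph_c": -1, "nadp_c": 1, "h_c": 1},
    "FMN": {"fmnh2_c": -1, "fmn_c": 1, "h_c": 2},
    "FAD": {"fadh2_c": -1, "fad_c": 1, "h_c": 2},
    "MQL8": {"mql8_c": -1, "mqn8_c": 1, "h_c": 2},
    "2DMMQL8": {"2dmmql8_c": -1, "2dmmq8_c": 1, "h_c": 2},
    "ACCOA": {"accoa_c": -1, "h2o_c": -1, "ac_c": 1, "coa_c": 1, "h_c": 1},
    "GLU": {"glu__L_c": -1, "h2o_c": -1, "akg_c": 1, "nh4_c": 1, "h_c": 2},
}


def egc_scan(model: GemModel,
             carriers: Optional[Iterable[str]] = None) -> List[EGCResult]:
    """Scan for energy-generating cycles, one carrier at a time.

    All exchange reactions are closed (bounds 0/0); the proton exchange
    between cytosol and periplasm stays open.  For each carrier a canonical
    dissipation reaction is added and maximised: a nonzero optimum exposes
    an internal cycle that charges the carrier for free, and the reactions
    carrying flux at that optimum form the cycle support.  Carriers whose
    species are absent from the model are skipped with a note.
    """
    names = list(carriers) if carriers is not None else list(EGC_CARRIERS)
    closed = model.copy()
    for rxn in closed.reactions:
        if rxn.is_exchange:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    if closed.has_metabolite("h_c") and closed.has_metabolite("h_p") \
            and not closed.has_reaction("Ht_cp_egc"):
        from .model import Reaction as _Rxn
        closed.add_reaction(_Rxn(
            id="Ht_cp_egc", name="proton exchange cytosol/periplasm",
            stoichiometry={"h_c": -1.0, "h_p": 1.0},
            lower_bound=-1000.0, upper_bound=1000.0))

    results = []
    for name in names:
        if name not in DISSIPATION_RECIPES:
            results.append(EGCResult(name, 0.0, [], skipped=True,
                                     note=f"unknown carrier {name!r}"))
            continue
        recipe = DISSIPATION_RECIPES[name]
        missing = [mid for mid in recipe if not closed.has_metabolite(mid)]
        if missing:
            results.append(EGCResult(name, 0.0, [], skipped=True,
                                     note=f"species absent: {sorted(missing)}"))
            continue
        probe = closed.copy()
        diss_id = f"DISSIPATION_{name}"
        from .model import Reaction as _Rxn
        probe.add_reaction(_Rxn(
            id=diss_id, name=f"{name} dissipation",
            stoichiometry={k: float(v) for k, v in recipe.items()},
            lower_bound=0.0, upper_bound=1000.0))
        sol = fba(probe, objective_id=diss_id, sense="maximize")
        flux = sol.objective if sol.optimal else 0.0
        support = [rid for rid, v in sol.fluxes.items()
                   if abs(v) > FLUX_SUPPORT_TOL and rid != diss_id]
        results.append(EGCResult(name, float(flux), sorted(support)))
    return results


# ---------------------------------------------------------------------------
# Annotation and SBO coverage
# ---------------------------------------------------------------------------

def annotation_coverage(model: GemModel) -> Dict[str, object]:
    """Deterministic annotation presence counts plus the SBO histogram."""
    from .model import model_summary

    def cover(entities) -> Dict[str, object]:
        entities = list(entities)
        if not entities:
            return {"fraction_annotated": 0.0, "databases": []}
        annotated = [e for e in entities if e.annotations]
        dbs = sorted({db for e in entities for db in e.annotations})
        return {
            "fraction_annotated": len(annotated) / len(entities),
            "databases": dbs,
        }

    return {
        "metabolites": cover(model.metabolites),
        "reactions": cover(model.reactions),
        "genes": cover(model.genes),
        "sbo_histogram": model_summary(model)["sbo_histogram"],
        "n_databases": len({db for coll in (model.metabolites, model.reactions,
                                            model.genes)
                            for e in coll for db in e.annotations}),
    }
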