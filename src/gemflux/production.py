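"""Amino-acid production economics, growth-product trade-offs, knockouts,
and pinned-reaction identification.

The production phenotype of a metabolite is probed with a sink reaction:
an irreversible drain added to the model, set as the objective and
maximised while growth is fixed to a viability level (default
0.4 mmol gDW^-1 h^-1) and glucose uptake to 10 mmol gDW^-1 h^-1.  Each
record carries the production rate, the molar yield on glucose, the CO2
efflux and the summed cytosolic-ATP production at that optimum.

Because production optima are usually degenerate, production rates are
deterministic but CO2/ATP rates are read off one optimal vertex and may
shift between alternative optima of equal production.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .model import GemModel, Reaction, SBO_SINK
from .optimize import (ConstraintError, FluxRange, InfeasibleModelError, fba,
                       fix_flux, fva, knockout)

__all__ = [
    "ProductionRecord",
    "TradeoffCurve",
    "PinnedReactionSet",
    "add_sink",
    "amino_acid_profile",
    "tradeoff_curve",
    "knockout_experiment",
    "pinned_reactions",
    "amino_acid_map",
]

GLUCOSE_EXCHANGE = "EX_glc__D_e"
CO2_EXCHANGE = "EX_co2_e"
CYTOSOLIC_ATP = "atp_c"
DEFAULT_GROWTH_FIX = 0.4
DEFAULT_GLUCOSE_UPTAKE = 10.0


@dataclass
class ProductionRecord:
    target: str
    production_rate: float  # mmol gDW^-1 h^-1
    yield_on_glucose: float  # molar ratio, production / glucose uptake bound
    co2_rate: float
    atp_rate: float
    status: str = "optimal"


@dataclass
class TradeoffCurve:
    product: str
    points: List[Tuple[float, float]]  # (fixed growth, max product rate)
    statuses: List[str] = field(default_factory=list)

    @property
    def mu_values(self) -> List[float]:
        return [p[0] for p in self.points]

    @property
    def rates(self) -> List[float]:
        return [p[1] for p in self.points]


@dataclass
class PinnedReactionSet:
    reaction_ids: List[str]
    ranges: List[FluxRange]


def amino_acid_map() -> Dict[str, str]:
    """The 20 canonical amino acids -> cytosolic metabolite ids (data file)."""
    raw = importlib.resources.files("gemflux").joinpath(
        "data/amino_acids.yaml").read_text(encoding="utf-8")
    return dict(yaml.safe_load(raw))


def add_sink(model: GemModel, metabolite_id: str) -> str:
    """Add an irreversible drain ``met -> ∅`` in place; return its id.

    The id is ``sink_<met>`` with the compartment suffix dropped; adding a
    sink twice is a no-op returning the existing id.
    """
    if not model.has_metabolite(metabolite_id):
        raise KeyError(f"no metabolite {metabolite_id!r} in model")
    base = metabolite_id
    for suffix in ("_c", "_p", "_e"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    sink_id = f"sink_{base}"
    if model.has_reaction(sink_id):
        return sink_id
    model.add_reaction(Reaction(
        id=sink_id,
        name=f"sink reaction for {model.metabolite(metabolite_id).name or base}",
        stoichiometry={metabolite_id: -1.0},
        lower_bound=0.0, upper_bound=1000.0,
        sbo=SBO_SINK,
    ))
    return sink_id


def _production_record(model: GemModel, sink_id: str, target: str,
                       glucose_uptake: float) -> ProductionRecord:
    sol = fba(model, objective_id=sink_id, sense="maximize")
    if not sol.optimal:
        return ProductionRecord(target=target, production_rate=0.0,
                                yield_on_glucose=0.0, co2_rate=0.0,
                                atp_rate=0.0, status=sol.status)
    rate = max(0.0, sol.objective)
    co2 = max(0.0, sol.fluxes.get(CO2_EXCHANGE, 0.0))
    atp = 0.0
    for rxn in model.reactions:
        coeff = rxn.stoichiometry.get(CYTOSOLIC_ATP)
        if coeff:
            atp += max(0.0, coeff * sol.fluxes[rxn.id])
    return ProductionRecord(
        target=target,
        production_rate=rate,
        yield_on_glucose=rate / glucose_uptake if glucose_uptake else 0.0,
        co2_rate=co2,
        atp_rate=atp,
    )


def _constrain(model: GemModel, growth_fix: Optional[float],
               glucose_uptake: Optional[float]) -> GemModel:
    out = model.copy()
    if glucose_uptake is not None and out.has_reaction(GLUCOSE_EXCHANGE):
        out.reaction(GLUCOSE_EXCHANGE).lower_bound = -glucose_uptake
    if growth_fix is not None:
        if out.objective is None:
            raise ValueError("model has no biomass objective to fix")
        out = fix_flux(out, out.objective, growth_fix)
    return out


def amino_acid_profile(model: GemModel,
                       glucose_uptake: float = DEFAULT_GLUCOSE_UPTAKE,
                       growth_fix: float = DEFAULT_GROWTH_FIX,
                       targets: Optional[Dict[str, str]] = None
                       ) -> List[ProductionRecord]:
    """Production record per amino acid under fixed growth.

    *model* must already carry its medium constraints.  ``targets`` maps
    amino-acid name -> cytosolic metabolite id (defaults to the canonical
    20); absent metabolites are reported with status ``absent``.
    """
    targets = targets if targets is not None else amino_acid_map()
    base = _constrain(model, growth_fix, glucose_uptake)
    check = fba(base, objective_id=base.objective, sense="maximize")
    if not check.optimal:
        raise InfeasibleModelError(
            f"model cannot sustain growth fixed at {growth_fix} "
            f"mmol gDW^-1 h^-1 under the current medium")
    records = []
    for name, met_id in targets.items():
        if not base.has_metabolite(met_id):
            records.append(ProductionRecord(
                target=name, production_rate=0.0, yield_on_glucose=0.0,
                co2_rate=0.0, atp_rate=0.0, status="absent"))
            continue
        probe = base.copy()
        sink_id = add_sink(probe, met_id)
        records.append(_production_record(probe, sink_id, name, glucose_uptake))
    return records


def tradeoff_curve(model: GemModel, product_sink_id: str,
                   mu_grid: Optional[Sequence[float]] = None,
                   n_points: int = 30) -> TradeoffCurve:
    """Maximum product rate as a function of fixed growth rate.

    The default grid is ``n_points`` evenly spaced growth values from 0 to
    the unconstrained growth optimum.  Points beyond feasibility are
    recorded with status ``infeasible`` and rate 0.
    """
    if not model.has_reaction(product_sink_id):
        raise KeyError(f"no sink reaction {product_sink_id!r} in model")
    if mu_grid is None:
        mu_max_sol = fba(model, sense="maximize")
        if not mu_max_sol.optimal:
            raise InfeasibleModelError("cannot establish the growth optimum")
        mu_grid = np.linspace(0.0, mu_max_sol.objective, n_points)
    points, statuses = [], []
    for mu in mu_grid:
        try:
            fixed = fix_flux(model, model.objective, float(mu))
        except ConstraintError:
            points.append((float(mu), 0.0))
            statuses.append("infeasible")
            continue
        sol = fba(fixed, objective_id=product_sink_id, sense="maximize")
        if sol.optimal:
            points.append((float(mu), float(sol.objective)))
            statuses.append("optimal")
        else:
            points.append((float(mu), 0.0))
            statuses.append(sol.status)
    return TradeoffCurve(product=product_sink_id, points=points,
                         statuses=statuses)


def knockout_experiment(model: GemModel, reaction_id: str = "PC",
                        product: str = "glu__L_c",
                        growth_fix: float = DEFAULT_GROWTH_FIX,
                        glucose_uptake: float = DEFAULT_GLUCOSE_UPTAKE
                        ) -> Dict[str, object]:
    """Wild-type vs single-knockout production under identical constraints.

    Returns ``{"before": ProductionRecord, "after": ProductionRecord,
    "fluxes_before": {...}, "fluxes_after": {...}}``; a knockout that makes
    the growth fix infeasible is reported in the record status, not raised.
    """
    if not model.has_reaction(reaction_id):
        raise KeyError(f"no reaction {reaction_id!r} in model")
    out: Dict[str, object] = {}
    for label, working in (("before", model),
                           ("after", knockout(model, reaction_id))):
        probe = working.copy()
        sink_id = add_sink(probe, product)
        try:
            probe = _constrain(probe, growth_fix, glucose_uptake)
        except ConstraintError:
            out[label] = ProductionRecord(
                target=product, production_rate=0.0, yield_on_glucose=0.0,
                co2_rate=0.0, atp_rate=0.0, status="infeasible")
            out[f"fluxes_{label}"] = {}
            continue
        record = _production_record(probe, sink_id, product, glucose_uptake)
        out[label] = record
        sol = fba(probe, objective_id=sink_id, sense="maximize")
        out[f"fluxes_{label}"] = sol.fluxes if sol.optimal else {}
    return out


def pinned_reactions(model: GemModel, objective_id: str,
                     growth_fix: Optional[float] = DEFAULT_GROWTH_FIX,
                     rel_tol: float = 1e-5, abs_tol: float = 1e-8,
                     loopless: bool = True,
                     method: str = "milp") -> PinnedReactionSet:
    """Reactions whose loopless-FVA min and max coincide within tolerance.

    The growth rate is first fixed, the objective optimum is computed and
    itself fixed, then (loopless) FVA runs over all reactions, including
    pseudo-reactions.  A reaction is pinned iff
    ``|max - min| <= abs_tol + rel_tol * max(|max|, |min|)``.
    """
    working = model.copy()
    if growth_fix is not None:
        if working.objective is None:
            raise ValueError("model has no biomass objective to fix")
        working = fix_flux(working, working.objective, growth_fix)
    opt = fba(working, objective_id=objective_id, sense="maximize")
    if not opt.optimal:
        raise InfeasibleModelError(
            f"objective {objective_id!r} is {opt.status} at the growth fix")
    working = fix_flux(working, objective_id, opt.objective)
    ranges = fva(working, loopless=loopless, method=method)
    pinned, pinned_ranges = [], []
    for rng in ranges:
        tol = abs_tol + rel_tol * max(abs(rng.maximum), abs(rng.minimum))
        if abs(rng.maximum - rng.minimum) <= tol:
            pinned.append(rng.reaction_id)
            pinned_ranges.append(rng)
    return PinnedReactionSet(reaction_ids=pinned, ranges=pinned_ranges)
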