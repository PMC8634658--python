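"""Growth media as exchange-bound sets, and growth-matrix simulation.

A medium is data, not code: a named set of exchange reactions with uptake
magnitudes (mmol gDW^-1 h^-1; uniform default 10).  Applying a medium sets
the lower bound of each listed exchange to minus its magnitude and closes
all other uptakes; the aerobic/anaerobic switch overrides the oxygen
exchange separately.  Secretion (upper) bounds are never touched.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import yaml

from .model import GemModel
from .optimize import fba

__all__ = [
    "Medium",
    "GrowthResult",
    "load_medium",
    "bundled_media",
    "apply_medium",
    "swap_carbon_source",
    "growth_matrix",
    "DEFAULT_UPTAKE",
    "GROWTH_TOL",
]

DEFAULT_UPTAKE = 10.0
#: growth below this is reported as zero ("no growth")
GROWTH_TOL = 1e-6
OXYGEN_EXCHANGE = "EX_o2_e"


@dataclass
class Medium:
    """Named medium: exchange-reaction id -> uptake magnitude (> 0)."""

    name: str
    components: Dict[str, float] = field(default_factory=dict)
    carbon_source: Optional[str] = None
    notes: str = ""

    def __post_init__(self) -> None:
        for rid, mag in self.components.items():
            if mag <= 0:
                raise ValueError(
                    f"medium {self.name!r}: magnitude for {rid} must be "
                    f"positive, got {mag}")
        if self.carbon_source is not None \
                and self.carbon_source not in self.components:
            raise ValueError(
                f"medium {self.name!r}: carbon source {self.carbon_source!r} "
                f"not among components")


@dataclass
class GrowthResult:
    medium: str
    aerobic: bool
    carbon_source: str  # exchange id or "as-defined"
    mu: float
    status: str


def load_medium(path: str) -> Medium:
    """Read a medium YAML file ({name, carbon_source, components, notes})."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    return Medium(
        name=raw.get("name", "medium"),
        components={k: float(v) for k, v in (raw.get("components") or {}).items()},
        carbon_source=raw.get("carbon_source"),
        notes=raw.get("notes", ""),
    )


def bundled_media() -> Dict[str, Medium]:
    """The media shipped with the package (CGXII, M9, LB approximation)."""
    out = {}
    root = importlib.resources.files("gemflux").joinpath("data/media")
    for entry in sorted(root.iterdir(), key=lambda p: p.name):
        if entry.name.endswith(".yaml"):
            raw = yaml.safe_load(entry.read_text(encoding="utf-8"))
            medium = Medium(
                name=raw.get("name", entry.name[:-5]),
                components={k: float(v)
                            for k, v in (raw.get("components") or {}).items()},
                carbon_source=raw.get("carbon_source"),
                notes=raw.get("notes", ""),
            )
            out[medium.name] = medium
    return out


def apply_medium(model: GemModel, medium: Medium, aerobic: bool = True,
                 oxygen_exchange: str = OXYGEN_EXCHANGE,
                 default_uptake: float = DEFAULT_UPTAKE) -> GemModel:
    """Return a copy of *model* constrained to *medium*.

    Listed exchanges get lower bound -magnitude, all other exchanges get
    lower bound 0; the oxygen exchange is forced open (aerobic) or shut
    (anaerobic) regardless of the medium list.  Unknown component ids
    raise with the full missing list.
    """
    exchange_ids = {r.id for r in model.exchanges}
    missing = [rid for rid in medium.components if rid not in exchange_ids]
    if missing:
        raise KeyError(
            f"medium {medium.name!r} lists exchanges absent from the model: "
            f"{sorted(missing)}")
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in medium.components:
            rxn.lower_bound = -medium.components[rxn.id]
        else:
            rxn.lower_bound = 0.0
        if rxn.id == oxygen_exchange:
            if aerobic:
                rxn.lower_bound = -medium.components.get(
                    oxygen_exchange, default_uptake)
            else:
                rxn.lower_bound = 0.0
    return out


def swap_carbon_source(medium: Medium, new_source_exchange_id: str,
                       magnitude: float = DEFAULT_UPTAKE) -> Medium:
    """Replace the medium's designated carbon source with another exchange."""
    if medium.carbon_source is None:
        raise ValueError(
            f"medium {medium.name!r} has no designated carbon-source slot")
    if not new_source_exchange_id.startswith("EX_"):
        raise ValueError(
            f"{new_source_exchange_id!r} is not an exchange reaction id")
    components = dict(medium.components)
    if new_source_exchange_id == medium.carbon_source:
        return replace(medium, components=components)
    components.pop(medium.carbon_source, None)
    components[new_source_exchange_id] = magnitude
    return replace(medium, components=components,
                   carbon_source=new_source_exchange_id)


def growth_matrix(model: GemModel, media: Sequence[Medium],
                  carbon_sources: Optional[Sequence[str]] = None,
                  conditions: Sequence[bool] = (True, False)) -> List[GrowthResult]:
    """One FBA per (medium [× carbon source]) × aerobic-condition cell.

    Per-cell failures are recorded in the result status and never abort
    the matrix.  Deterministic row order: media outer, carbon sources
    middle, aerobic before anaerobic.
    """
    results = []
    for medium in media:
        variants = [(medium, "as-defined")]
        if carbon_sources:
            variants = [(swap_carbon_source(medium, src), src)
                        for src in carbon_sources]
        for variant, source in variants:
            for aerobic in conditions:
                try:
                    constrained = apply_medium(model, variant, aerobic=aerobic)
                    sol = fba(constrained)
                    mu = sol.objective if sol.optimal else 0.0
                    if mu is None or mu < GROWTH_TOL:
                        mu = 0.0
                    status = sol.status
                except Exception as exc:  # noqa: BLE001 - recorded per cell
                    mu, status = 0.0, f"error: {exc}"
                results.append(GrowthResult(
                    medium=medium.name, aerobic=aerobic,
                    carbon_source=source, mu=float(mu), status=status))
    return results
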