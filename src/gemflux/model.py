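"""In-memory representation of a genome-scale metabolic model.

A :class:`GemModel` holds metabolites, reactions, gene products, subsystem
groups, the biomass objective, and the unit convention (fluxes in
mmol gDW^-1 h^-1).  It is a plain data container: all analysis lives in the
``optimize``/``audit``/``media``/``production`` modules.

Conventions follow the BiGG namespace: compartment suffixes ``_c`` (cytosol),
``_p`` (periplasm), ``_e`` (extracellular); pseudo-reactions are recognised
by id prefix (``EX_``/``DM_``/``SK_``/``sink_``) or SBO term (exchange,
demand, sink, biomass), whichever signal is present.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Union

from .formula import ElementTally, parse_formula

__all__ = [
    "Metabolite",
    "Reaction",
    "Gene",
    "GemModel",
    "Units",
    "ModelIntegrityError",
    "GprError",
    "parse_gpr",
    "eval_gpr",
    "gpr_genes",
    "model_summary",
]

COMPARTMENT_NAMES = {"c": "cytosol", "p": "periplasm", "e": "extracellular"}

#: SBO accessions marking pseudo-reactions (union with id-prefix detection).
SBO_EXCHANGE = "SBO:0000627"
SBO_DEMAND = "SBO:0000628"
SBO_BIOMASS = "SBO:0000629"
SBO_ATPM = "SBO:0000630"
SBO_SINK = "SBO:0000632"
PSEUDO_SBO = {SBO_EXCHANGE, SBO_DEMAND, SBO_BIOMASS, SBO_SINK}
_PSEUDO_PREFIX = re.compile(r"^(EX_|DM_|SK_|sink_)", re.IGNORECASE)
_EXCHANGE_PREFIX = re.compile(r"^EX_", re.IGNORECASE)


class ModelIntegrityError(ValueError):
    """A cross-reference inside the model does not resolve."""


class GprError(ValueError):
    """A gene-protein-reaction rule fails to parse."""


# ---------------------------------------------------------------------------
# GPR rules: boolean AND/OR trees over gene identifiers
# ---------------------------------------------------------------------------

GprNode = Union[str, tuple]  # gene id, or ("and"|"or", [children])

_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gpr(rule: str) -> GprNode:
    """Parse a GPR string like ``(g1 and g2) or g3`` into an AST.

    Returns a gene id (leaf) or a tuple ``(op, children)`` with ``op`` in
    {"and", "or"}; "and" binds tighter than "or".
    """
    tokens = _GPR_TOKEN.findall(rule)
    if not tokens:
        raise GprError("empty GPR rule")
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprNode:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and() -> GprNode:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_atom() -> GprNode:
        tok = peek()
        if tok is None:
            raise GprError(f"unexpected end of GPR rule {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprError(f"unbalanced parentheses in {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprError(f"unexpected token {tok!r} in {rule!r}")
        return take()

    node = parse_or()
    if pos != len(tokens):
        raise GprError(f"trailing tokens in GPR rule {rule!r}")
    return node


def eval_gpr(node: GprNode, active_genes: Set[str]) -> bool:
    """Evaluate a GPR AST given the set of genes still present."""
    if isinstance(node, str):
        return node in active_genes
    op, children = node
    if op == "and":
        return all(eval_gpr(c, active_genes) for c in children)
    return any(eval_gpr(c, active_genes) for c in children)


def gpr_genes(node: GprNode) -> Set[str]:
    """All gene ids referenced by a GPR AST."""
    if isinstance(node, str):
        return {node}
    out: Set[str] = set()
    for child in node[1]:
        out |= gpr_genes(child)
    return out


# ---------------------------------------------------------------------------
# Model components
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None  # None = unknown, never imputed as empty
    charge: Optional[int] = None
    annotations: Dict[str, List[str]] = field(default_factory=dict)
    sbo: Optional[str] = None

    @property
    def tally(self) -> Optional[ElementTally]:
        return None if self.formula is None else parse_formula(self.formula)


@dataclass
class Reaction:
    id: str
    name: str = ""
    #: metabolite id -> signed coefficient (negative = consumed)
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[str] = None
    sbo: Optional[str] = None
    subsystems: List[str] = field(default_factory=list)
    annotations: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_pseudo(self) -> bool:
        """Exchange/demand/sink/biomass pseudo-reaction (prefix OR SBO)."""
        if self.sbo in PSEUDO_SBO:
            return True
        return bool(_PSEUDO_PREFIX.match(self.id))

    @property
    def is_exchange(self) -> bool:
        if self.sbo == SBO_EXCHANGE:
            return True
        return bool(_EXCHANGE_PREFIX.match(self.id))

    @property
    def is_boundary(self) -> bool:
        """Moves a species across the system boundary (one-sided reaction)."""
        if self.is_pseudo:
            return True
        return len(self.stoichiometry) > 0 and (
            all(c < 0 for c in self.stoichiometry.values())
            or all(c > 0 for c in self.stoichiometry.values())
        )


@dataclass
class Gene:
    id: str
    label: str = ""  # locus tag(s), old and new
    annotations: Dict[str, List[str]] = field(default_factory=dict)
    sbo: Optional[str] = None


@dataclass
class Units:
    extent: str = "mmol gDW^-1"
    time: str = "h"
    volume: str = "fl"


@dataclass
class GemModel:
    id: str = "model"
    name: str = ""
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[Gene] = field(default_factory=list)
    #: subsystem / pathway name -> member reaction ids
    groups: Dict[str, List[str]] = field(default_factory=dict)
    objective: Optional[str] = None
    units: Units = field(default_factory=Units)
    notes: Dict[str, object] = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index()

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    def _met_index(self) -> Dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def gene_ids(self) -> Set[str]:
        return {g.id for g in self.genes}

    def copy(self) -> "GemModel":
        return _copy.deepcopy(self)

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Check all cross-references and bound sanity; raise on violation."""
        met_ids = set()
        for m in self.metabolites:
            if m.id in met_ids:
                raise ModelIntegrityError(f"duplicate metabolite id {m.id!r}")
            met_ids.add(m.id)
            if m.compartment not in COMPARTMENT_NAMES:
                raise ModelIntegrityError(
                    f"metabolite {m.id!r}: compartment {m.compartment!r} "
                    f"not in {sorted(COMPARTMENT_NAMES)}"
                )
        rxn_ids = set()
        genes = self.gene_ids
        for r in self.reactions:
            if r.id in rxn_ids:
                raise ModelIntegrityError(f"duplicate reaction id {r.id!r}")
            rxn_ids.add(r.id)
            if r.lower_bound > r.upper_bound:
                raise ModelIntegrityError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            for met_id in r.stoichiometry:
                if met_id not in met_ids:
                    raise ModelIntegrityError(
                        f"reaction {r.id!r} references undefined species {met_id!r}"
                    )
            if not r.stoichiometry and not r.is_pseudo:
                raise ModelIntegrityError(
                    f"reaction {r.id!r} has empty stoichiometry and is not a "
                    f"declared pseudo-reaction"
                )
            if r.gpr:
                for g in gpr_genes(parse_gpr(r.gpr)):
                    if g not in genes:
                        raise ModelIntegrityError(
                            f"reaction {r.id!r} GPR references unknown gene {g!r}"
                        )
        if self.objective is not None and self.objective not in rxn_ids:
            raise ModelIntegrityError(
                f"objective reaction {self.objective!r} not in model"
            )
        for group, members in self.groups.items():
            for rid in members:
                if rid not in rxn_ids:
                    raise ModelIntegrityError(
                        f"group {group!r} references unknown reaction {rid!r}"
                    )

    # -- mutation helpers ---------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if self.has_metabolite(met.id):
            raise ModelIntegrityError(f"metabolite {met.id!r} already present")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if self.has_reaction(rxn.id):
            raise ModelIntegrityError(f"reaction {rxn.id!r} already present")
        for met_id in rxn.stoichiometry:
            if not self.has_metabolite(met_id):
                raise ModelIntegrityError(
                    f"reaction {rxn.id!r} references undefined species {met_id!r}"
                )
        self.reactions.append(rxn)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def model_summary(model: GemModel) -> Dict[str, object]:
    """Entity counts and the reaction SBO-term histogram.

    The histogram maps SBO accession -> number of reactions carrying it,
    the tabular analogue of an SBO-prevalence bar chart.
    """
    sbo_hist: Dict[str, int] = {}
    for r in model.reactions:
        if r.sbo:
            sbo_hist[r.sbo] = sbo_hist.get(r.sbo, 0) + 1
    return {
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "n_genes": len(model.genes),
        "n_groups": len(model.groups),
        "sbo_histogram": dict(sorted(sbo_hist.items())),
    }
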