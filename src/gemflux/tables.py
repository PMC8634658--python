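"""CSV reaction/metabolite/gene tables → :class:`GemModel` converter.

Dialect: comma-separated UTF-8 with a header row.  Reaction equations are
plain strings like ``accoa_c + h2o_c + oaa_c -> cit_c + coa_c + h_c`` with
any of the arrows ``->``, ``=>``, ``<->``, ``<=>``, ``⇌``, ``→`` (the
double-headed forms mark reversibility).  Blank bounds fall back to the
BiGG convention: 0/1000 for irreversible rows, -1000/1000 for reversible.
"""

from __future__ import annotations

import csv
import re
from typing import Dict, List, Optional, Tuple

from .model import Gene, GemModel, Metabolite, Reaction

__all__ = ["from_tables", "parse_equation", "TableParseError"]

DEFAULT_UB = 1000.0
DEFAULT_LB_REV = -1000.0

_REVERSIBLE_ARROWS = ("<=>", "<->", "⇌", "↔")
_IRREVERSIBLE_ARROWS = ("-->", "->", "=>", "→")


class TableParseError(ValueError):
    """A CSV row could not be interpreted; message names the offending token."""


def _split_arrow(equation: str) -> Tuple[str, str, bool]:
    for arrow in _REVERSIBLE_ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            return left, right, True
    for arrow in _IRREVERSIBLE_ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            return left, right, False
    raise TableParseError(f"no reaction arrow found in equation {equation!r}")


_COEFF = re.compile(r"^\d+(\.\d+)?([eE][+-]?\d+)?$")


def _parse_side(side: str, sign: float, stoich: Dict[str, float],
                equation: str) -> None:
    side = side.strip()
    if not side or side in ("∅", "0"):
        return
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise TableParseError(
                f"empty term (stray '+') in equation {equation!r}")
        parts = term.split()
        if len(parts) == 1:
            coeff, met = 1.0, parts[0]
        elif len(parts) == 2 and _COEFF.match(parts[0]):
            coeff, met = float(parts[0]), parts[1]
        else:
            raise TableParseError(
                f"cannot parse term {term!r} in equation {equation!r}")
        stoich[met] = stoich.get(met, 0.0) + sign * coeff


def parse_equation(equation: str) -> Tuple[Dict[str, float], bool]:
    """Parse an equation string into (signed stoichiometry, reversible)."""
    left, right, reversible = _split_arrow(equation)
    stoich: Dict[str, float] = {}
    _parse_side(left, -1.0, stoich, equation)
    _parse_side(right, +1.0, stoich, equation)
    # cancel species appearing on both sides with equal coefficients
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return stoich, reversible


def _read_rows(path: str) -> List[Dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise TableParseError(f"{path}: missing header row")
        return [{(k or "").strip().lower(): (v or "").strip()
                 for k, v in row.items()} for row in reader]


def _opt_float(value: str) -> Optional[float]:
    return float(value) if value else None


def from_tables(reactions_csv: str, metabolites_csv: str,
                genes_csv: Optional[str] = None,
                model_id: str = "model") -> GemModel:
    """Build a model from reaction/metabolite(/gene) CSV tables.

    Metabolite columns: ``id, name, compartment, formula, charge[, sbo]``.
    Reaction columns: ``id, name, equation, lower_bound, upper_bound,
    gpr, subsystem[, sbo]``.  Gene columns: ``id, label``.
    Unknown columns are ignored; duplicate ids raise.
    """
    model = GemModel(id=model_id)

    seen = set()
    for row in _read_rows(metabolites_csv):
        mid = row.get("id", "")
        if not mid:
            raise TableParseError(f"{metabolites_csv}: row without id")
        if mid in seen:
            raise TableParseError(f"duplicate metabolite id {mid!r}")
        seen.add(mid)
        compartment = row.get("compartment", "") or (
            mid.rsplit("_", 1)[-1] if "_" in mid else "c")
        charge = row.get("charge", "")
        model.metabolites.append(Metabolite(
            id=mid,
            name=row.get("name", ""),
            compartment=compartment,
            formula=row.get("formula") or None,
            charge=int(charge) if charge else None,
            sbo=row.get("sbo") or None,
        ))

    if genes_csv is not None:
        seen = set()
        for row in _read_rows(genes_csv):
            gid = row.get("id", "")
            if not gid:
                raise TableParseError(f"{genes_csv}: row without id")
            if gid in seen:
                raise TableParseError(f"duplicate gene id {gid!r}")
            seen.add(gid)
            model.genes.append(Gene(id=gid, label=row.get("label", "")))

    seen = set()
    known_genes = {g.id for g in model.genes}
    for row in _read_rows(reactions_csv):
        rid = row.get("id", "")
        if not rid:
            raise TableParseError(f"{reactions_csv}: row without id")
        if rid in seen:
            raise TableParseError(f"duplicate reaction id {rid!r}")
        seen.add(rid)
        equation = row.get("equation", "")
        try:
            stoich, reversible = parse_equation(equation)
        except TableParseError as exc:
            raise TableParseError(f"reaction {rid!r}: {exc}") from None
        lb = _opt_float(row.get("lower_bound", ""))
        ub = _opt_float(row.get("upper_bound", ""))
        if lb is None:
            lb = DEFAULT_LB_REV if reversible else 0.0
        if ub is None:
            ub = DEFAULT_UB
        gpr = row.get("gpr") or None
        if gpr:
            # genes referenced only in GPR strings are registered implicitly
            from .model import gpr_genes, parse_gpr
            for g in sorted(gpr_genes(parse_gpr(gpr))):
                if g not in known_genes:
                    model.genes.append(Gene(id=g))
                    known_genes.add(g)
        subsystems = [s.strip() for s in row.get("subsystem", "").split(";")
                      if s.strip()]
        model.reactions.append(Reaction(
            id=rid,
            name=row.get("name", ""),
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            sbo=row.get("sbo") or None,
            subsystems=subsystems,
        ))
        for sub in subsystems:
            model.groups.setdefault(sub, []).append(rid)

    objective = row_objective = [r.id for r in model.reactions
                                 if r.sbo == "SBO:0000629"
                                 or "biomass" in r.id.lower()]
    if row_objective:
        model.objective = objective[0]
    model.validate()
    return model
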