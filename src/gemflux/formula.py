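"""Chemical formulas as element tallies.

Metabolite formulas in genome-scale models are plain element-count strings
(``C6H12O6``).  Generic moieties are encoded with the pseudo-elements ``R``
and ``X`` (e.g. acyl chains, polymer ends); reactions touching such species
cannot be mass-balanced and are reported as unverifiable rather than
imbalanced.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

__all__ = [
    "ElementTally",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "molecular_weight",
    "ATOMIC_WEIGHTS",
]


class FormulaError(ValueError):
    """Raised when a formula string does not match the element-count grammar."""


#: IUPAC 2021 standard atomic weights, 6 significant figures, g/mol.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.00800, "He": 4.00260, "Li": 6.94000, "Be": 9.01218, "B": 10.8100,
    "C": 12.0110, "N": 14.0070, "O": 15.9990, "F": 18.9984, "Ne": 20.1797,
    "Na": 22.9898, "Mg": 24.3050, "Al": 26.9815, "Si": 28.0850, "P": 30.9738,
    "S": 32.0600, "Cl": 35.4500, "Ar": 39.9500, "K": 39.0983, "Ca": 40.0780,
    "Sc": 44.9559, "Ti": 47.8670, "V": 50.9415, "Cr": 51.9961, "Mn": 54.9380,
    "Fe": 55.8450, "Co": 58.9332, "Ni": 58.6934, "Cu": 63.5460, "Zn": 65.3800,
    "Ga": 69.7230, "Ge": 72.6300, "As": 74.9216, "Se": 78.9710, "Br": 79.9040,
    "Kr": 83.7980, "Rb": 85.4678, "Sr": 87.6200, "Y": 88.9058, "Zr": 91.2240,
    "Nb": 92.9064, "Mo": 95.9500, "Ag": 107.868, "Cd": 112.414, "Sn": 118.710,
    "Sb": 121.760, "I": 126.904, "Cs": 132.905, "Ba": 137.327, "W": 183.840,
    "Pt": 195.084, "Au": 196.967, "Hg": 200.592, "Pb": 207.200,
}

#: Pseudo-elements marking generic moieties; tallies containing them cannot
#: be balanced or weighed.
PSEUDO_ELEMENTS = frozenset({"R", "X"})

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementTally(Mapping[str, int]):
    """Immutable element → count mapping for one chemical species.

    An empty tally is a legal value meaning "formula unknown"; callers must
    distinguish it from a zero-mass species.
    """

    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for elem, n in self.counts.items():
            if n < 0:
                raise FormulaError(f"negative count for element {elem!r}")

    def __getitem__(self, key: str) -> int:
        return self.counts[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def balanceable(self) -> bool:
        """False when the tally carries a generic-moiety pseudo-element."""
        return not (PSEUDO_ELEMENTS & self.counts.keys())

    def weight(self) -> float:
        """Molecular weight in g/mol; raises on pseudo-elements."""
        if not self.balanceable:
            bad = sorted(PSEUDO_ELEMENTS & self.counts.keys())
            raise FormulaError(f"cannot weigh generic moiety element(s) {bad}")
        return sum(ATOMIC_WEIGHTS[e] * n for e, n in self.counts.items())


def parse_formula(text: str) -> ElementTally:
    """Parse an element-count formula string into an :class:`ElementTally`.

    The grammar is ``([A-Z][a-z]?\\d*)*``; repeated elements accumulate.
    ``R`` and ``X`` are accepted as pseudo-elements and flag the tally as
    non-balanceable.
    """
    if text is None:
        raise FormulaError("formula is None")
    text = text.strip()
    counts: Counter = Counter()
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"illegal character at position {pos} in {text!r}")
        elem, digits = m.group(1), m.group(2)
        if elem not in ATOMIC_WEIGHTS and elem not in PSEUDO_ELEMENTS:
            raise FormulaError(f"unknown element {elem!r} in {text!r}")
        counts[elem] += int(digits) if digits else 1
        pos = m.end()
    return ElementTally(dict(counts))


# Hill-system ordering: C first, H second, everything else alphabetical.
def _hill_key(elem: str) -> tuple:
    return {"C": (0,), "H": (1,)}.get(elem, (2, elem))


def format_formula(tally: ElementTally) -> str:
    """Render a tally back to a canonical (Hill-ordered) formula string."""
    parts = []
    for elem in sorted(tally.counts, key=_hill_key):
        n = tally.counts[elem]
        if n == 0:
            continue
        parts.append(elem if n == 1 else f"{elem}{n}")
    return "".join(parts)


def molecular_weight(formula: str) -> float:
    """Molecular weight (g/mol) of a formula string."""
    return parse_formula(formula).weight()
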