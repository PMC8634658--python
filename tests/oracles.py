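"""Independent brute-force oracles for LP results on tiny models.

These deliberately avoid the package's solver path: the stoichiometric
matrix is rebuilt dense from the reaction dicts, optima come from explicit
vertex enumeration of the flux polytope, and loopless ranges from
exhaustive sign-pattern enumeration with an explicit cycle check.
"""

from __future__ import annotations

import itertools
import re
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

_PSEUDO = re.compile(r"^(EX_|DM_|SK_|sink_)", re.IGNORECASE)


def dense_system(model) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]:
    """Dense S, lb, ub and reaction id order built directly from the model."""
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rxn in enumerate(model.reactions):
        for mid, coeff in rxn.stoichiometry.items():
            S[met_ids.index(mid), j] = coeff
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub, rxn_ids


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-7) -> List[np.ndarray]:
    """All vertices of {v : S v = 0, lb <= v <= ub} by active-set search."""
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    vertices: List[np.ndarray] = []
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue  # no unique solution on this face
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, value in zip(fixed, choice):
                v[j] = value
            rhs = -S[:, fixed] @ np.array(choice) if fixed else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if not any(np.allclose(v, w, atol=1e-6) for w in vertices):
                vertices.append(v)
    return vertices


def brute_force_fba(model, objective_id: str,
                    sense: str = "maximize") -> Optional[float]:
    """Optimal objective by vertex enumeration; None when infeasible."""
    S, lb, ub, rxn_ids = dense_system(model)
    j = rxn_ids.index(objective_id)
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return None
    values = [v[j] for v in vertices]
    return max(values) if sense == "maximize" else min(values)


# ---------------------------------------------------------------------------
# Loopless oracle
# ---------------------------------------------------------------------------

def _internal_indices(model) -> List[int]:
    out = []
    for j, rxn in enumerate(model.reactions):
        if _PSEUDO.match(rxn.id):
            continue
        coeffs = list(rxn.stoichiometry.values())
        if not coeffs or all(c < 0 for c in coeffs) or all(c > 0 for c in coeffs):
            continue
        out.append(j)
    return out


def _pattern_has_cycle(S_int: np.ndarray, sigma: Tuple[int, ...]) -> bool:
    """Is there an internal cycle y (S_int y = 0) conformal to sigma?"""
    k = len(sigma)
    support = [i for i in range(k) if sigma[i] != 0]
    if not support:
        return False
    bounds = []
    for i in range(k):
        if sigma[i] > 0:
            bounds.append((0.0, None))
        elif sigma[i] < 0:
            bounds.append((None, 0.0))
        else:
            bounds.append((0.0, 0.0))
    # require total conformal magnitude >= 1 to exclude y = 0
    A_ub = -np.array([[float(sigma[i]) for i in range(k)]])
    res = linprog(np.zeros(k), A_eq=S_int, b_eq=np.zeros(S_int.shape[0]),
                  A_ub=A_ub, b_ub=np.array([-1.0]), bounds=bounds,
                  method="highs")
    return res.status == 0


def loopless_fva_oracle(model, reaction_id: str) -> Tuple[float, float]:
    """Loopless flux range by exhaustive sign-pattern enumeration.

    Enumerates every orientation pattern of the internal reactions,
    discards patterns that can carry an internal cycle, optimises the
    target flux inside each surviving orthant, and aggregates.
    """
    S, lb, ub, rxn_ids = dense_system(model)
    j = rxn_ids.index(reaction_id)
    internal = _internal_indices(model)
    S_int = S[:, internal]
    best_min, best_max = np.inf, -np.inf
    for sigma in itertools.product((-1, 0, 1), repeat=len(internal)):
        if _pattern_has_cycle(S_int, sigma):
            continue
        pat_lb, pat_ub = lb.copy(), ub.copy()
        for pos, idx in enumerate(internal):
            if sigma[pos] > 0:
                pat_lb[idx] = max(pat_lb[idx], 0.0)
            elif sigma[pos] < 0:
                pat_ub[idx] = min(pat_ub[idx], 0.0)
            else:
                pat_lb[idx] = pat_ub[idx] = 0.0
        if np.any(pat_lb > pat_ub):
            continue
        for sign in (1.0, -1.0):
            c = np.zeros(len(rxn_ids))
            c[j] = sign
            res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([pat_lb, pat_ub]),
                          method="highs")
            if res.status == 0:
                value = sign * res.fun
                best_min = min(best_min, value)
                best_max = max(best_max, value)
    return best_min, best_max
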