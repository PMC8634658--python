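"""Stoichiometric matrix construction and linear-programming machinery.

Flux balance analysis (FBA) maximises an objective flux subject to the
steady-state condition S·v = 0 and per-reaction bounds.  Flux variability
analysis (FVA) reports the min/max attainable flux per reaction; its
loopless variant additionally forbids thermodynamically infeasible internal
cycles via the nullspace-MILP loop law (binary direction indicators coupled
to a "potential" variable per internal reaction, with the internal-nullspace
orthogonality constraint), solved exactly with HiGHS through SciPy.  A
CycleFreeFlux-style post-processing fallback is provided for speed.

Only objective values and FVA ranges are deterministic contracts; when the
optimum is degenerate the individual flux vector returned is one arbitrary
optimal vertex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model import GemModel, Reaction, eval_gpr, parse_gpr

__all__ = [
    "StoichMatrix",
    "LPSolution",
    "FluxRange",
    "InfeasibleModelError",
    "ConstraintError",
    "build_matrix",
    "fba",
    "fix_flux",
    "knockout",
    "fva",
]

#: HiGHS feasibility/optimality tolerances used for every solve.
SOLVER_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

#: Big-M constant of the loop-law MILP; matches the default bound magnitude.
BIG_M = 1000.0

_ZERO_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    """The model admits no steady-state flux under its current bounds."""


class ConstraintError(ValueError):
    """A requested constraint conflicts with existing bounds."""


@dataclass
class StoichMatrix:
    """Sparse metabolites × reactions stoichiometric matrix with indices."""

    S: sp.csc_matrix
    metabolite_ids: List[str]
    reaction_ids: List[str]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.S.shape


@dataclass
class LPSolution:
    """Outcome of one FBA solve (flux unit mmol gDW^-1 h^-1)."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective: Optional[float]
    fluxes: Dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    reaction_id: str
    minimum: float
    maximum: float


def build_matrix(model: GemModel) -> StoichMatrix:
    """Exact sparse stoichiometric matrix in model (deterministic) order."""
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        for mid, coeff in rxn.stoichiometry.items():
            rows.append(met_pos[mid])
            cols.append(j)
            vals.append(coeff)
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    return StoichMatrix(S=S, metabolite_ids=met_ids, reaction_ids=rxn_ids)


def _bounds_arrays(model: GemModel) -> Tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return lb, ub


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


def _solve_lp(S: sp.spmatrix, lb: np.ndarray, ub: np.ndarray,
              c: np.ndarray) -> Tuple[str, Optional[float], Optional[np.ndarray]]:
    """Minimise c·v subject to S v = 0, lb <= v <= ub."""
    n_mets = S.shape[0]
    res = linprog(c, A_eq=S, b_eq=np.zeros(n_mets),
                  bounds=np.column_stack([lb, ub]),
                  method="highs", options=dict(SOLVER_OPTIONS))
    status = _STATUS.get(res.status, "numerical")
    if status == "optimal":
        return status, float(res.fun), np.asarray(res.x)
    return status, None, None


def fba(model: GemModel, objective_id: Optional[str] = None,
        sense: str = "maximize") -> LPSolution:
    """Flux balance analysis; returns status, objective and one flux vector.

    Infeasible/unbounded problems are reported through ``status``, never as
    exceptions.  An unknown objective id raises ``KeyError``.
    """
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be maximize|minimize, got {sense!r}")
    objective_id = objective_id or model.objective
    if objective_id is None:
        raise ValueError("model has no objective and none was given")
    matrix = build_matrix(model)
    try:
        j = matrix.reaction_ids.index(objective_id)
    except ValueError:
        raise KeyError(f"no reaction {objective_id!r} in model") from None
    lb, ub = _bounds_arrays(model)
    c = np.zeros(len(matrix.reaction_ids))
    c[j] = -1.0 if sense == "maximize" else 1.0
    status, fun, x = _solve_lp(matrix.S, lb, ub, c)
    if status != "optimal":
        return LPSolution(status=status, objective=None, fluxes={})
    objective = -fun if sense == "maximize" else fun
    fluxes = dict(zip(matrix.reaction_ids, x))
    return LPSolution(status="optimal", objective=objective, fluxes=fluxes)


def fix_flux(model: GemModel, reaction_id: str, value: float) -> GemModel:
    """Return a copy with both bounds of *reaction_id* pinned to *value*."""
    rxn = model.reaction(reaction_id)
    if not (rxn.lower_bound - _ZERO_TOL <= value <= rxn.upper_bound + _ZERO_TOL):
        raise ConstraintError(
            f"cannot fix {reaction_id!r} to {value}: outside bounds "
            f"[{rxn.lower_bound}, {rxn.upper_bound}]"
        )
    out = model.copy()
    target = out.reaction(reaction_id)
    target.lower_bound = value
    target.upper_bound = value
    return out


def knockout(model: GemModel, target: str) -> GemModel:
    """Return a copy with a reaction or gene knocked out.

    A reaction knockout zeroes its bounds.  A gene knockout zeroes the
    bounds of every reaction whose GPR rule evaluates to false once the
    gene is removed (AND = all subunits required, OR = isoenzymes).
    """
    out = model.copy()
    if out.has_reaction(target):
        rxn = out.reaction(target)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
        return out
    if target in out.gene_ids:
        remaining = out.gene_ids - {target}
        for rxn in out.reactions:
            if rxn.gpr and not eval_gpr(parse_gpr(rxn.gpr), remaining):
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
        return out
    raise KeyError(f"no reaction or gene {target!r} in model")


# ---------------------------------------------------------------------------
# Flux variability analysis
# ---------------------------------------------------------------------------

def _internal_mask(model: GemModel) -> np.ndarray:
    """True for reactions subject to the loop law (non-boundary reactions)."""
    return np.array([not r.is_boundary for r in model.reactions], dtype=bool)


def _internal_nullspace(S: sp.csc_matrix, internal: np.ndarray) -> np.ndarray:
    """Orthonormal basis of null(S restricted to internal columns)."""
    S_int = S[:, internal].toarray()
    if S_int.shape[1] == 0:
        return np.zeros((0, 0))
    return scipy.linalg.null_space(S_int)


def _loopless_milp_range(matrix: StoichMatrix, lb: np.ndarray, ub: np.ndarray,
                         internal: np.ndarray, K: np.ndarray,
                         j: int) -> Tuple[float, float]:
    """Exact loopless min/max of reaction *j* via the loop-law MILP."""
    n = len(matrix.reaction_ids)
    idx_int = np.flatnonzero(internal)
    k = len(idx_int)
    # variable layout: v (n) | a (k, binary) | G (k)
    n_var = n + 2 * k
    blocks = []
    lo, hi = [], []

    S_eq = sp.hstack([matrix.S, sp.csc_matrix((matrix.S.shape[0], 2 * k))])
    blocks.append(S_eq)
    lo += [0.0] * matrix.S.shape[0]
    hi += [0.0] * matrix.S.shape[0]

    if k:
        rows_v = sp.lil_matrix((2 * k, n_var))
        for row, i in enumerate(idx_int):
            # v_i - M a_i <= 0  (a=0 forces v_i <= 0)
            rows_v[2 * row, i] = 1.0
            rows_v[2 * row, n + row] = -BIG_M
            # v_i + M (1 - a_i) >= 0  ->  v_i + M a_i >= -... rearranged:
            # v_i >= -M (1 - a_i)  ->  v_i - M a_i >= -M
            rows_v[2 * row + 1, i] = 1.0
            rows_v[2 * row + 1, n + row] = -BIG_M
        # row 2r:   -inf <= v_i - M a_i <= 0
        # row 2r+1: -M  <= v_i - M a_i <= +inf  (same matrix rows, split bounds)
        blocks.append(rows_v.tocsc())
        for _ in range(k):
            lo += [-np.inf, -BIG_M]
            hi += [0.0, np.inf]

        rows_g = sp.lil_matrix((k, n_var))
        for row in range(k):
            # a=1 -> G in [-M, -1]; a=0 -> G in [1, M]
            # 1 <= G_i + (M+1) a_i <= M
            rows_g[row, n + row] = BIG_M + 1.0
            rows_g[row, n + k + row] = 1.0
        blocks.append(rows_g.tocsc())
        lo += [1.0] * k
        hi += [BIG_M] * k

        if K.size:
            K_rows = sp.hstack([
                sp.csc_matrix((K.shape[1], n + k)),
                sp.csc_matrix(K.T),
            ])
            blocks.append(K_rows)
            lo += [0.0] * K.shape[1]
            hi += [0.0] * K.shape[1]

    A = sp.vstack(blocks, format="csc")
    constraint = LinearConstraint(A, np.array(lo), np.array(hi))
    var_lb = np.concatenate([lb, np.zeros(k), -BIG_M * np.ones(k)])
    var_ub = np.concatenate([ub, np.ones(k), BIG_M * np.ones(k)])
    integrality = np.concatenate(
        [np.zeros(n), np.ones(k), np.zeros(k)])

    out = []
    for sign in (1.0, -1.0):  # minimise, then maximise
        c = np.zeros(n_var)
        c[j] = sign
        res = milp(c, constraints=[constraint],
                   bounds=Bounds(var_lb, var_ub), integrality=integrality)
        if res.status != 0:
            raise InfeasibleModelError(
                f"loop-law MILP {'min' if sign > 0 else 'max'} for reaction "
                f"{matrix.reaction_ids[j]!r} returned status {res.status}"
            )
        out.append(sign * res.fun)
    return out[0], out[1]


def _cycle_free_value(matrix: StoichMatrix, lb: np.ndarray, ub: np.ndarray,
                      internal: np.ndarray, v_star: np.ndarray,
                      j: int) -> float:
    """CycleFreeFlux projection: strip internal loops from an optimal vertex.

    Holds every non-internal flux at its value in ``v_star``, restricts each
    internal flux to the closed interval between 0 and its value, and
    minimises the L1 norm of the internal fluxes.  The projected vector is
    loop-free; its j-th component is the fallback loopless bound.
    """
    n = len(v_star)
    new_lb = v_star.copy()
    new_ub = v_star.copy()
    for i in np.flatnonzero(internal):
        if v_star[i] >= 0:
            new_lb[i], new_ub[i] = 0.0, v_star[i]
        else:
            new_lb[i], new_ub[i] = v_star[i], 0.0
    c = np.zeros(n)
    c[internal] = np.sign(v_star[internal])
    status, _, x = _solve_lp(matrix.S, new_lb, new_ub, c)
    if status != "optimal":  # pragma: no cover - projection is always feasible
        return v_star[j]
    return float(x[j])


def fva(model: GemModel, reaction_ids: Optional[Sequence[str]] = None,
        loopless: bool = False, method: str = "milp") -> List[FluxRange]:
    """Min/max feasible steady-state flux per reaction.

    Any prior objective fixing must already be encoded in the bounds (see
    :func:`fix_flux`).  With ``loopless=True`` internal thermodynamically
    infeasible cycles are excluded: ``method="milp"`` solves the loop-law
    MILP exactly; ``method="cycle_free"`` post-processes each plain-FVA
    vertex (fast, may leave slightly wider ranges on pathological models).
    """
    matrix = build_matrix(model)
    lb, ub = _bounds_arrays(model)
    status, _, _ = _solve_lp(matrix.S, lb, ub, np.zeros(len(lb)))
    if status != "optimal":
        raise InfeasibleModelError(f"model is {status} under current bounds")

    if reaction_ids is None:
        targets = list(matrix.reaction_ids)
    else:
        for rid in reaction_ids:
            if rid not in matrix.reaction_ids:
                raise KeyError(f"no reaction {rid!r} in model")
        targets = list(reaction_ids)
    positions = {rid: matrix.reaction_ids.index(rid) for rid in targets}

    internal = _internal_mask(model)
    K = _internal_nullspace(matrix.S, internal) if loopless else np.zeros((0, 0))

    ranges = []
    for rid in targets:
        j = positions[rid]
        if loopless and method == "milp":
            vmin, vmax = _loopless_milp_range(matrix, lb, ub, internal, K, j)
        else:
            vals = []
            for sign in (1.0, -1.0):
                c = np.zeros(len(lb))
                c[j] = sign
                st, fun, x = _solve_lp(matrix.S, lb, ub, c)
                if st != "optimal":
                    raise InfeasibleModelError(
                        f"FVA subproblem for {rid!r} is {st}")
                value = sign * fun
                if loopless and internal[j]:
                    value = _cycle_free_value(matrix, lb, ub, internal, x, j)
                vals.append(value)
            vmin, vmax = vals
        if vmin > vmax:  # numerical inversion at solver tolerance
            vmin, vmax = vmax, vmin
        ranges.append(FluxRange(reaction_id=rid, minimum=vmin, maximum=vmax))
    return ranges
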