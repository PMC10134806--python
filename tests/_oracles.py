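"""Independent oracles used to cross-check the implementation.

These deliberately re-derive results by brute force (vertex enumeration,
exhaustive subset search, bisection on the scalar fixed-point equation) and
share no code path with the routines they check.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from marinegem.model_core import MetabolicModel


def vertex_enumerate_optimum(model: MetabolicModel, tol: float = 1e-9) -> Optional[float]:
    """LP optimum of c'v s.t. Sv=0, l<=v<=u by enumerating basic solutions.

    Every vertex of the feasible polytope has n - rank(S) variables at a
    finite bound; for each choice of basic columns and bound assignment the
    square system is solved and feasibility checked.  Returns the best
    objective over all vertices, or None when no feasible vertex exists.
    Only practical for a handful of reactions.
    """
    S, _mets, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    r = np.linalg.matrix_rank(S) if S.size else 0
    j_obj = rxn_ids.index(model.objective_id)
    sign = 1.0 if model.objective_sense == "maximize" else -1.0

    best: Optional[float] = None
    for basic in combinations(range(n), r):
        B = S[:, list(basic)]
        if np.linalg.matrix_rank(B) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        choices = []
        for j in nonbasic:
            opts = [b for b in (lb[j], ub[j]) if np.isfinite(b)]
            if not opts:
                opts = [0.0]  # free variable pinned at 0 still yields a basic point
            choices.append(sorted(set(opts)))
        for assignment in product(*choices):
            v = np.zeros(n)
            for j, val in zip(nonbasic, assignment):
                v[j] = val
            rhs = -S[:, nonbasic] @ np.array(assignment) if nonbasic else np.zeros(S.shape[0])
            sol, residual, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v[list(basic)] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            obj = v[j_obj]
            if best is None or sign * obj > sign * best:
                best = obj
    return best


def exhaustive_gapfill(
    grows: Callable[[Sequence[str]], bool],
    candidate_ids: Sequence[str],
) -> Optional[List[Tuple[str, ...]]]:
    """All minimum-cardinality candidate subsets that restore growth.

    ``grows(subset)`` must report whether the model extended with that
    subset reaches the growth threshold.  Returns every minimal subset (so
    tie-breaking can be checked separately), or None when no subset works.
    """
    ids = list(candidate_ids)
    for size in range(len(ids) + 1):
        winners = [combo for combo in combinations(ids, size) if grows(combo)]
        if winners:
            return winners
    return None


def fixed_point_by_bisection(
    response: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float = 1e-4,
) -> float:
    """Root of g - response(g) on [lo, hi] for a nonincreasing response.

    g - response(g) is then nondecreasing, so plain bisection applies; this
    is independent of fixed-point iteration.
    """
    f_lo = lo - response(lo)
    f_hi = hi - response(hi)
    if f_lo > 0:
        return lo
    if f_hi < 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mid - response(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
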