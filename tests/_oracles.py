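"""Independent oracles used to check the optimization code.

These deliberately avoid the package's LP/MILP code paths: the FBA oracle
enumerates basic solutions of the flux polytope directly, the iMAT oracle
enumerates activation patterns, and the gap-fill oracle enumerates candidate
subsets — each checking feasibility with plain bound-tightened LPs.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog


def vertex_enumeration_optimum(
    S: np.ndarray, lbs: np.ndarray, ubs: np.ndarray, obj: int
) -> float:
    """Max v[obj] over {S v = 0, lb <= v <= ub} by basic-solution enumeration.

    Every vertex of the polytope fixes some variables at a bound and solves
    the remaining square-or-overdetermined equality system uniquely; with
    finite bounds the LP optimum is attained at such a point.  All 3^n
    assignments (at-lower / at-upper / free) are scanned.
    """
    n = len(lbs)
    best = -np.inf
    for assign in itertools.product((0, 1, 2), repeat=n):
        free = [j for j, a in enumerate(assign) if a == 2]
        v = np.array(
            [lbs[j] if a == 0 else (ubs[j] if a == 1 else 0.0)
             for j, a in enumerate(assign)]
        )
        if free:
            A = S[:, free]
            if np.linalg.matrix_rank(A, tol=1e-10) < len(free):
                continue  # no unique solution; covered by a tighter assignment
            b = -S @ v
            x, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ x - b)) > 1e-8:
                continue  # inconsistent system
            v[free] = x
        elif np.max(np.abs(S @ v)) > 1e-8 if S.size else False:
            continue
        if np.all(v >= lbs - 1e-9) and np.all(v <= ubs + 1e-9):
            best = max(best, v[obj])
    return best


def random_network(
    rng: np.random.Generator, n_rxns: int, n_mets: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """A random bounded flux polytope (always feasible: v = 0 is interior)."""
    S = rng.integers(-2, 3, size=(n_mets, n_rxns)).astype(float)
    lbs = np.where(rng.random(n_rxns) < 0.5, -rng.uniform(0.5, 5.0, n_rxns), 0.0)
    ubs = rng.uniform(0.5, 5.0, n_rxns)
    obj = int(rng.integers(0, n_rxns))
    return S, lbs, ubs, obj


def lp_growth(model, eps: float = 1e-6) -> bool:
    """Independent growth check: plain linprog on the model's own matrices."""
    from proteogem.model_core import build_stoichiometric_matrix

    sm = build_stoichiometric_matrix(model)
    ids = list(sm.reaction_ids)
    c = np.zeros(len(ids))
    c[ids.index(model.biomass_id)] = -1.0
    res = linprog(
        c, A_eq=sparse.csr_matrix(sm.matrix), b_eq=np.zeros(sm.matrix.shape[0]),
        bounds=[(model[r].lower_bound, model[r].upper_bound) for r in ids],
        method="highs",
    )
    return res.status == 0 and -res.fun > eps


def subset_restores_growth(model, reactions, eps: float = 1e-6) -> bool:
    probe = model.copy()
    for rxn in reactions:
        probe.add_reaction(rxn.copy())
    return lp_growth(probe, eps)


def imat_oracle(
    model, calls: Dict[str, str], eps_active: float, zero_tol: float = 1e-6
) -> int:
    """Max agreement by exhausting activation patterns with feasibility LPs.

    Options per called reaction: a present call may be satisfied forward
    (v >= eps), backward (v <= -eps) or left unsatisfied; an absent call may
    be satisfied (|v| <= tol) or not.  Each pattern is a bound tightening;
    agreement is the best satisfied count over feasible patterns.
    """
    from proteogem.model_core import build_stoichiometric_matrix

    sm = build_stoichiometric_matrix(model)
    ids = list(sm.reaction_ids)
    base = [(model[r].lower_bound, model[r].upper_bound) for r in ids]
    called = sorted(c for c in calls if c in model)
    options = [
        ("+", "-", "u") if calls[c] == "present" else ("z", "u") for c in called
    ]
    best = 0
    for pattern in itertools.product(*options):
        bounds = list(base)
        score = 0
        ok = True
        for rid, opt in zip(called, pattern):
            j = ids.index(rid)
            lb, ub = bounds[j]
            if opt == "+":
                lb = max(lb, eps_active)
            elif opt == "-":
                ub = min(ub, -eps_active)
            elif opt == "z":
                lb, ub = max(lb, -zero_tol), min(ub, zero_tol)
            else:
                continue
            if lb > ub:
                ok = False
                break
            bounds[j] = (lb, ub)
            score += 1
        if not ok or score <= best:
            continue
        res = linprog(
            np.zeros(len(ids)), A_eq=sparse.csr_matrix(sm.matrix),
            b_eq=np.zeros(sm.matrix.shape[0]), bounds=bounds, method="highs",
        )
        if res.status == 0:
            best = score
    return best


def minimal_restoring_subsets(
    model, candidates: Sequence, max_size: int, eps: float = 1e-6
):
    """All smallest restoring candidate subsets up to ``max_size``."""
    for size in range(0, max_size + 1):
        hits = [
            combo
            for combo in itertools.combinations(candidates, size)
            if subset_restores_growth(model, combo, eps)
        ]
        if hits:
            return size, hits
    return None, []
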