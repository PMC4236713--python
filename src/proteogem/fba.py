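"""Flux balance analysis: maximize an objective flux subject to Sv = 0.

The linear program is

    maximize    Z = v_objective
    subject to  S v = 0
                a_i <= v_i <= b_i   for every reaction i

solved with HiGHS through :func:`scipy.optimize.linprog`.  Alternate optima
are endemic to genome-scale models, so the *objective value* is the solver
contract; individual fluxes should only be interpreted through
:func:`flux_variability` ranges.

Infeasibility is data, not an exception: a model that cannot satisfy its
constraints (as happens to automatically built drafts under a realistic
substrate uptake) is reported through ``FluxResult.status``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import (
    DEFAULT_MAX_FLUX,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_stoichiometric_matrix,
)

__all__ = [
    "FluxResult",
    "solve_fba",
    "set_uptake",
    "classify_fluxes",
    "flux_variability",
    "STEADY_STATE_TOL",
]

#: residual tolerance for the S.v = 0 steady-state check
STEADY_STATE_TOL = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class FluxResult:
    """Outcome of an FBA/iMAT solve.

    ``objective`` is the flux through the objective reaction — for a biomass
    objective this is the growth rate reported directly in doublings/h, the
    unit convention of the underlying growth model.
    """

    objective: float
    fluxes: Dict[str, float]
    status: str
    objective_id: Optional[str] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def steady_state_residual(self, model: MetabolicModel) -> float:
        """Max |S.v| over metabolites; ~0 means mass is conserved."""
        sm = build_stoichiometric_matrix(model)
        v = np.array([self.fluxes.get(r, 0.0) for r in sm.reaction_ids])
        if sm.matrix.size == 0:
            return 0.0
        return float(np.max(np.abs(sm.matrix @ v)))


def _solve_lp(
    S: np.ndarray,
    bounds,
    c: np.ndarray,
) -> Tuple[str, Optional[np.ndarray]]:
    res = linprog(
        c,
        A_eq=sparse.csr_matrix(S) if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    return status, (res.x if res.status == 0 else None)


def solve_fba(
    model: MetabolicModel,
    maximize: Optional[str] = None,
    minimize: bool = False,
) -> FluxResult:
    """Solve the FBA LP for ``model``, maximizing the named reaction flux.

    Defaults to the model's biomass reaction.  Returns ``status``
    ``"infeasible"``/``"unbounded"`` (with zero fluxes) rather than raising,
    so failing drafts can be compared and reported.
    """
    obj_id = maximize or model.biomass_id
    if obj_id is None or obj_id not in model:
        raise ValueError(f"objective reaction {obj_id!r} not in model")
    sm = build_stoichiometric_matrix(model)
    idx = sm.reaction_ids.index(obj_id)
    c = np.zeros(len(sm.reaction_ids))
    c[idx] = 1.0 if minimize else -1.0
    bounds = [(model[r].lower_bound, model[r].upper_bound) for r in sm.reaction_ids]
    status, x = _solve_lp(sm.matrix, bounds, c)
    if x is None:
        return FluxResult(0.0, {r: 0.0 for r in sm.reaction_ids}, status, obj_id)
    fluxes = {r: float(v) for r, v in zip(sm.reaction_ids, x)}
    return FluxResult(fluxes[obj_id], fluxes, "optimal", obj_id)


def set_uptake(model: MetabolicModel, kegg_id: str, rate: float) -> MetabolicModel:
    """Return a copy of ``model`` with the uptake rate of a substrate set.

    Uptake is a negative flux on the metabolite's exchange reaction, so a
    rate of *u* mmol/gDW/h becomes ``lower_bound = -u``.  If no exchange
    exists one is created (with a warning) in the extracellular compartment.
    """
    if rate < 0:
        raise ValueError(f"uptake rate must be non-negative, got {rate}")
    new = model.copy()
    exch = new.find_exchange(kegg_id)
    if exch is None:
        warnings.warn(f"no exchange reaction for {kegg_id}; creating EX_{kegg_id}")
        exch = Reaction(
            f"EX_{kegg_id}", {Metabolite(kegg_id, "e"): -1.0}, 0.0, DEFAULT_MAX_FLUX,
            subsystem="Exchange",
        )
        new.add_reaction(exch)
    exch.lower_bound = -rate
    return new


def classify_fluxes(
    result: FluxResult,
    high: float = 100.0,
    significant: float = 0.01,
) -> Dict[str, Set[str]]:
    """Partition reactions by |flux| against the two reporting thresholds.

    ``highly_active``: |v| > high (default 100, the analysis threshold on a
    0–1000 flux range); ``significant``: |v| > significant (default 0.01);
    ``zero``: everything else.  ``highly_active`` is a subset of
    ``significant``.
    """
    if not result.optimal:
        raise ValueError("flux classification requires an optimal solution")
    highly = {r for r, v in result.fluxes.items() if abs(v) > high}
    sig = {r for r, v in result.fluxes.items() if abs(v) > significant}
    zero = set(result.fluxes) - sig
    return {"highly_active": highly, "significant": sig, "zero": zero}


def flux_variability(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction [min, max] flux with the objective held at its optimum.

    Returns an empty dict if the base problem is not optimal (the status is
    available from :func:`solve_fba`).
    """
    base = solve_fba(model)
    if not base.optimal:
        return {}
    sm = build_stoichiometric_matrix(model)
    n = len(sm.reaction_ids)
    obj_idx = sm.reaction_ids.index(base.objective_id)
    bounds = [(model[r].lower_bound, model[r].upper_bound) for r in sm.reaction_ids]
    # objective >= fraction * optimum, as an upper-bound row on -v_obj
    A_ub = np.zeros((1, n))
    A_ub[0, obj_idx] = -1.0
    b_ub = np.array([-objective_fraction * base.objective + 1e-9])
    targets = list(reactions) if reactions is not None else list(sm.reaction_ids)
    out: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = sm.reaction_ids.index(rid)
        lohi = []
        for sense in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sense
            res = linprog(
                c,
                A_eq=sparse.csr_matrix(sm.matrix),
                b_eq=np.zeros(sm.matrix.shape[0]),
                A_ub=A_ub,
                b_ub=b_ub,
                bounds=bounds,
                method="highs",
            )
            lohi.append(float(res.x[j]) if res.status == 0 else np.nan)
        out[rid] = (lohi[0], lohi[1])
    return out
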