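"""iMAT-style integration of present/absent protein calls with a model.

High-confidence proteomics detections translate into *present* calls on the
reactions their enzymes catalyse; reactions whose associated proteins were
all measured but none confidently detected get *absent* calls; reactions
with no protein association stay *unknown*.  A mixed-integer program then
finds a steady-state flux distribution maximizing agreement with the calls:
a present reaction scores 1 when it carries flux of at least ``eps_active``
in either direction, an absent reaction scores 1 when its flux is
numerically zero.

Biomass production is not forced during integration (the objective is pure
agreement, as appropriate for model validation); an optional minimum-growth
constraint is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba import FluxResult
from .model_core import MetabolicModel, build_stoichiometric_matrix
from .reconstruction import (
    AnnotationTable,
    DEFAULT_LOG_E_THRESHOLD,
    ProteinEvidence,
    filter_evidence,
)

__all__ = ["ExpressionStates", "call_states", "imat", "ZERO_TOL"]

#: |v| below this satisfies an absent call
ZERO_TOL = 1e-6

_CALLS = ("present", "absent", "unknown")


@dataclass
class ExpressionStates:
    """Per-reaction present/absent/unknown calls; unknown is the default."""

    calls: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, call in self.calls.items():
            if call not in _CALLS:
                raise ValueError(f"{rid}: unknown call '{call}'")

    def get(self, rxn_id: str) -> str:
        return self.calls.get(rxn_id, "unknown")

    def called(self) -> Dict[str, str]:
        return {r: c for r, c in self.calls.items() if c != "unknown"}

    def counts(self) -> Dict[str, int]:
        out = {c: 0 for c in _CALLS}
        for c in self.calls.values():
            out[c] += 1
        return out


def call_states(
    model: MetabolicModel,
    evidence: Sequence[ProteinEvidence],
    annot: AnnotationTable,
    threshold_log_e: float = DEFAULT_LOG_E_THRESHOLD,
) -> ExpressionStates:
    """Assign present/absent/unknown calls to the model's reactions.

    A reaction is *present* if any of its genes passes the confidence
    filter; *absent* if all of its genes were measured and none passed;
    *unknown* otherwise (no gene association, or genes never measured).
    Gene-reaction association uses the reaction's ``gene_ids``, falling back
    to EC co-membership through the annotation table.
    """
    confident = {e.protein_id for e in filter_evidence(evidence, threshold_log_e)}
    measured = {e.protein_id for e in evidence}
    ec_to_proteins: Dict[str, set] = {}
    for pid, ecs in annot.items():
        for ec in ecs:
            ec_to_proteins.setdefault(ec, set()).add(pid)

    calls: Dict[str, str] = {}
    for rxn in model:
        proteins = set(rxn.gene_ids)
        if not proteins:
            for ec in rxn.ec_numbers:
                proteins |= ec_to_proteins.get(ec, set())
        if not proteins:
            calls[rxn.rxn_id] = "unknown"
        elif proteins & confident:
            calls[rxn.rxn_id] = "present"
        elif proteins <= measured:
            calls[rxn.rxn_id] = "absent"
        else:
            calls[rxn.rxn_id] = "unknown"
    return ExpressionStates(calls)


def imat(
    model: MetabolicModel,
    states: ExpressionStates,
    eps_active: float = 1.0,
    zero_tol: float = ZERO_TOL,
    min_growth: Optional[float] = None,
) -> Tuple[FluxResult, int]:
    """Maximize agreement between flux activity and present/absent calls.

    One satisfiable indicator per called reaction: present reactions need
    |v| >= ``eps_active`` (a binary per direction, at most one on), absent
    reactions need |v| <= ``zero_tol``.  Returns the agreement-optimal flux
    vector and the attained agreement score (<= number of called reactions).
    """
    called = {r: c for r, c in states.called().items() if r in model}
    sm = build_stoichiometric_matrix(model)
    rxn_ids = list(sm.reaction_ids)
    n = len(rxn_ids)
    if not called:
        res = _feasible_flux(model, sm, min_growth)
        return res, 0

    binaries = []  # (kind, rxn_index, var_offset)
    nvar = n
    obj = []
    for rid in sorted(called):
        j = rxn_ids.index(rid)
        if called[rid] == "present":
            binaries.append(("present", j, nvar))
            nvar += 2
        else:
            binaries.append(("absent", j, nvar))
            nvar += 1
    c = np.zeros(nvar)
    for kind, _, off in binaries:
        c[off] = -1.0
        if kind == "present":
            c[off + 1] = -1.0

    cons = []
    A_eq = sparse.hstack(
        [sparse.csr_matrix(sm.matrix), sparse.csr_matrix((sm.matrix.shape[0], nvar - n))]
    )
    cons.append(LinearConstraint(A_eq, 0.0, 0.0))

    rows, cols, vals, lo, hi = [], [], [], [], []
    r = 0
    for kind, j, off in binaries:
        rxn = model[rxn_ids[j]]
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if kind == "present":
            # forward: yf=1 => v >= eps    (v - (eps-lb) yf >= lb)
            rows += [r, r]; cols += [j, off]; vals += [1.0, -(eps_active - lb)]
            lo.append(lb); hi.append(np.inf); r += 1
            # backward: yb=1 => v <= -eps  (v + (ub+eps) yb <= ub)
            rows += [r, r]; cols += [j, off + 1]; vals += [1.0, ub + eps_active]
            lo.append(-np.inf); hi.append(ub); r += 1
            # at most one direction
            rows += [r, r]; cols += [off, off + 1]; vals += [1.0, 1.0]
            lo.append(-np.inf); hi.append(1.0); r += 1
        else:
            # z=1 => v <= zero_tol  (v + (ub - tol) z <= ub)
            rows += [r, r]; cols += [j, off]; vals += [1.0, ub - zero_tol]
            lo.append(-np.inf); hi.append(ub); r += 1
            # z=1 => v >= -zero_tol (v + (lb + tol) z >= lb)
            rows += [r, r]; cols += [j, off]; vals += [1.0, lb + zero_tol]
            lo.append(lb); hi.append(np.inf); r += 1
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    cons.append(LinearConstraint(A, lo, hi))

    if min_growth is not None:
        bio = np.zeros(nvar)
        bio[rxn_ids.index(model.biomass_id)] = 1.0
        cons.append(LinearConstraint(bio, min_growth, np.inf))

    lbs = np.array([model[rid].lower_bound for rid in rxn_ids] + [0.0] * (nvar - n))
    ubs = np.array([model[rid].upper_bound for rid in rxn_ids] + [1.0] * (nvar - n))
    integrality = np.array([0] * n + [1] * (nvar - n))
    res = milp(c, constraints=cons, bounds=Bounds(lbs, ubs), integrality=integrality)
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"iMAT MILP failed with status {res.status} ({res.message})")
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(rxn_ids)}
    agreement = int(round(-res.fun))
    obj_id = model.biomass_id if model.biomass_id in model else None
    objective = fluxes.get(obj_id, 0.0) if obj_id else 0.0
    return FluxResult(objective, fluxes, "optimal", obj_id), agreement


def _feasible_flux(model, sm, min_growth):
    from scipy.optimize import linprog

    n = len(sm.reaction_ids)
    bounds = [(model[r].lower_bound, model[r].upper_bound) for r in sm.reaction_ids]
    kwargs = {}
    if min_growth is not None:
        A_ub = np.zeros((1, n))
        A_ub[0, list(sm.reaction_ids).index(model.biomass_id)] = -1.0
        kwargs = {"A_ub": A_ub, "b_ub": np.array([-min_growth])}
    res = linprog(
        np.zeros(n), A_eq=sparse.csr_matrix(sm.matrix), b_eq=np.zeros(sm.matrix.shape[0]),
        bounds=bounds, method="highs", **kwargs,
    )
    if res.status != 0:
        return FluxResult(0.0, {r: 0.0 for r in sm.reaction_ids}, "infeasible",
                          model.biomass_id)
    fluxes = {r: float(v) for r, v in zip(sm.reaction_ids, res.x)}
    obj = fluxes.get(model.biomass_id, 0.0) if model.biomass_id else 0.0
    return FluxResult(obj, fluxes, "optimal", model.biomass_id)
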