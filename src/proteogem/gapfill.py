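"""Gap analysis and optimization-based gap-filling.

A draft reconstruction typically cannot produce every biomass precursor:
some metabolites are *blocked* — necessary for biomass production but not
producible (or consumable) by the network at steady state.  Gap-filling
finds them, pulls candidate reactions touching them from a reference
database, scores each candidate by its distance to the existing network in
the metabolite-reaction bipartite graph (currency metabolites excluded so
ATP/water do not shortcut everything), and solves a mixed-integer program
selecting a minimum-total-distance subset that restores a positive biomass
flux.  If the initial candidate pool cannot restore growth the pool is
widened (network-reachable database reactions, then the whole database) and
the MILP is re-run; the report records every round.

Optionally, boundary exchange reactions for dead-end extracellular
metabolites can be offered to the MILP as well — automatically built drafts
are often repaired mostly by exchanges — but this mode is opt-in because it
can mask true pathway gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba import solve_fba
from .model_core import (
    DEFAULT_MAX_FLUX,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_stoichiometric_matrix,
)
from .reconstruction import ReactionDatabase

__all__ = [
    "GapReport",
    "CURRENCY_METABOLITES",
    "GROWTH_EPS",
    "find_blocked_precursors",
    "rank_candidates",
    "gapfill",
]

#: metabolites excluded from distance graphs (ubiquitous cofactor pool)
CURRENCY_METABOLITES = frozenset(
    ["C00001", "C00002", "C00003", "C00006", "C00008", "C00009", "C00010", "C00080"]
)

#: a biomass flux above this counts as "positive growth"
GROWTH_EPS = 1e-6

_UNREACHABLE_WEIGHT = 1e6


@dataclass
class GapReport:
    """Audit trail of one gap-filling run."""

    blocked_metabolites: List[str] = field(default_factory=list)
    candidate_reactions: List[Dict] = field(default_factory=list)
    added_reactions: List[Dict] = field(default_factory=list)
    unfillable: List[str] = field(default_factory=list)
    iterations: int = 0
    success: bool = False
    reason: str = ""
    objective_after: float = 0.0

    def to_dict(self) -> Dict:
        return {
            "blocked_metabolites": self.blocked_metabolites,
            "candidate_reactions": self.candidate_reactions,
            "added_reactions": self.added_reactions,
            "unfillable": self.unfillable,
            "iterations": self.iterations,
            "success": self.success,
            "reason": self.reason,
            "objective_after": self.objective_after,
        }


def find_blocked_precursors(model: MetabolicModel, tol: float = GROWTH_EPS) -> List[str]:
    """Biomass reactants the network cannot produce at steady state.

    For each biomass reactant *m*, the biomass reaction is replaced by free
    drains for *all* precursors and the drain of *m* is maximized; *m* is
    blocked when that maximum is zero (within ``tol``).  Returned in
    deterministic (lexicographic) order.
    """
    biomass = model.biomass_reaction()
    precursors = sorted(biomass.reactants, key=lambda m: m.key)
    probe = model.copy()
    probe.remove_reaction(biomass.rxn_id)
    probe.biomass_id = None
    drain_of = {}
    for met in precursors:
        rid = f"DM_{met.kegg_id}_{met.compartment}"
        if rid not in probe:
            probe.add_reaction(Reaction(rid, {met: -1.0}, 0.0, DEFAULT_MAX_FLUX))
        drain_of[met.key] = rid
    blocked = []
    for met in precursors:
        res = solve_fba(probe, maximize=drain_of[met.key])
        if not res.optimal or res.objective < tol:
            blocked.append(met.kegg_id)
    return blocked


def _bipartite_distances(
    model: MetabolicModel,
    db: ReactionDatabase,
    exclude: Iterable[str] = (),
) -> Dict[str, float]:
    """Bipartite-graph distance of each db reaction to the model's metabolites.

    Nodes are reactions and (non-currency) metabolites of the union network;
    a reaction connects to every metabolite it touches.  Distance is the
    shortest path length from the reaction node to the nearest metabolite
    already present in the model, so a candidate touching a model metabolite
    scores 1, one reaction further out scores 3, and so on.

    ``exclude`` removes metabolites (typically the blocked precursors
    themselves, which the biomass reaction keeps in the model) from the
    source set, so a candidate is scored by how well its *other* connections
    reach the network: a producer whose substrates are already available
    ranks above one that needs an unavailable intermediate first.
    """
    excluded = set(exclude) | CURRENCY_METABOLITES
    G = nx.Graph()
    model_met_keys = {m.key for m in model.metabolites if m.kegg_id not in excluded}
    for rxn in list(model) + list(db):
        rnode = ("R", rxn.rxn_id)
        for met in rxn.stoichiometry:
            if met.kegg_id in CURRENCY_METABOLITES:
                continue
            G.add_edge(rnode, ("M", met.key))
    sources = [("M", k) for k in model_met_keys if ("M", k) in G]
    dist = nx.multi_source_dijkstra_path_length(G, sources) if sources else {}
    return {
        rxn.rxn_id: float(dist.get(("R", rxn.rxn_id), np.inf))
        for rxn in db
        if rxn.rxn_id not in model
    }


def rank_candidates(
    blocked: Sequence[str],
    db: ReactionDatabase,
    model: MetabolicModel,
) -> Tuple[List[Dict], List[str]]:
    """Rank database reactions touching blocked metabolites by distance.

    Returns ``(candidates, unfillable)`` where each candidate is a dict with
    ``rxn_id`` and ``distance``, sorted by (distance, rxn_id); blocked
    metabolites untouched by any database reaction are reported unfillable.
    """
    blocked_set = set(blocked)
    dist = _bipartite_distances(model, db, exclude=blocked_set)
    touched: Dict[str, Set[str]] = {b: set() for b in blocked_set}
    cands = []
    for rxn in db:
        hits = {m.kegg_id for m in rxn.stoichiometry} & blocked_set
        if not hits:
            continue
        for b in hits:
            touched[b].add(rxn.rxn_id)
        if rxn.rxn_id not in model:
            cands.append({"rxn_id": rxn.rxn_id, "distance": dist.get(rxn.rxn_id, np.inf)})
    cands.sort(key=lambda c: (c["distance"], c["rxn_id"]))
    unfillable = sorted(b for b, hits in touched.items() if not hits)
    return cands, unfillable


def _candidate_weights(candidates: List[Dict]) -> Dict[str, float]:
    """Distance-based weights with a tiny lexicographic perturbation.

    The perturbation makes the MILP optimum generically unique, so ties are
    effectively broken by reaction id and the run is deterministic.
    """
    weights = {}
    for i, cand in enumerate(sorted(candidates, key=lambda c: c["rxn_id"])):
        d = cand["distance"]
        base = d if np.isfinite(d) else _UNREACHABLE_WEIGHT
        weights[cand["rxn_id"]] = base + 1e-6 * i
    return weights


def _dead_end_exchange_candidates(model: MetabolicModel) -> List[Reaction]:
    """Exchange reactions for extracellular metabolites that are dead ends."""
    producible: Set[str] = set()
    consumable: Set[str] = set()
    for rxn in model:
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met, coef in rxn.stoichiometry.items():
            if (coef > 0 and fwd) or (coef < 0 and rev):
                producible.add(met.key)
            if (coef < 0 and fwd) or (coef > 0 and rev):
                consumable.add(met.key)
    out = []
    for met in model.metabolites:
        if met.compartment != "e":
            continue
        if met.key in producible and met.key in consumable:
            continue
        rid = f"EX_GF_{met.kegg_id}"
        if rid in model:
            continue
        out.append(Reaction(rid, {met: -1.0}, -DEFAULT_MAX_FLUX, DEFAULT_MAX_FLUX,
                            subsystem="Exchange"))
    return out


def _solve_selection_milp(
    model: MetabolicModel,
    candidates: List[Reaction],
    weights: Dict[str, float],
    growth_eps: float,
) -> Optional[List[str]]:
    """MILP: pick the minimum-weight candidate subset giving biomass > eps.

    Variables are all fluxes of the merged network plus one binary per
    candidate gating its bounds (lb*y <= v <= ub*y).  Returns the chosen
    candidate ids, or None when infeasible.
    """
    merged = model.copy()
    for rxn in candidates:
        merged.add_reaction(rxn.copy())
    sm = build_stoichiometric_matrix(merged)
    rxn_ids = list(sm.reaction_ids)
    n = len(rxn_ids)
    cand_ids = [r.rxn_id for r in candidates]
    cand_pos = {rid: n + k for k, rid in enumerate(cand_ids)}
    nvar = n + len(cand_ids)

    c = np.zeros(nvar)
    for rid in cand_ids:
        c[cand_pos[rid]] = weights[rid]

    cons = []
    # steady state over the merged network
    A_eq = sparse.hstack(
        [sparse.csr_matrix(sm.matrix), sparse.csr_matrix((sm.matrix.shape[0], len(cand_ids)))]
    )
    cons.append(LinearConstraint(A_eq, 0.0, 0.0))
    # gate candidate fluxes: v - ub*y <= 0 and v - lb*y >= 0
    rows, cols, vals, lo, hi = [], [], [], [], []
    r = 0
    for rid in cand_ids:
        j = rxn_ids.index(rid)
        rxn = merged[rid]
        rows += [r, r]; cols += [j, cand_pos[rid]]; vals += [1.0, -rxn.upper_bound]
        lo.append(-np.inf); hi.append(0.0)
        r += 1
        rows += [r, r]; cols += [j, cand_pos[rid]]; vals += [1.0, -rxn.lower_bound]
        lo.append(0.0); hi.append(np.inf)
        r += 1
    if rows:
        A_gate = sparse.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
        cons.append(LinearConstraint(A_gate, lo, hi))
    # positive growth
    bio = np.zeros(nvar)
    bio[rxn_ids.index(merged.biomass_id)] = 1.0
    cons.append(LinearConstraint(bio, growth_eps, np.inf))

    lbs = np.array([merged[rid].lower_bound for rid in rxn_ids] + [0.0] * len(cand_ids))
    ubs = np.array([merged[rid].upper_bound for rid in rxn_ids] + [1.0] * len(cand_ids))
    integrality = np.array([0] * n + [1] * len(cand_ids))
    res = milp(c, constraints=cons, bounds=Bounds(lbs, ubs), integrality=integrality)
    if res.status != 0 or res.x is None:
        return None
    return [rid for rid in cand_ids if res.x[cand_pos[rid]] > 0.5]


#: internal MILP growth targets, tried in order; each chosen set is verified
#: exactly by LP afterwards, so a firmer target only guards against the MIP
#: solver's feasibility tolerance absorbing a tiny growth floor
_MILP_GROWTH_TARGETS = (1e-3, 1e-4, 1e-5)


def gapfill(
    model: MetabolicModel,
    db: ReactionDatabase,
    allow_exchanges: bool = False,
    growth_eps: float = GROWTH_EPS,
) -> Tuple[MetabolicModel, GapReport]:
    """Restore positive biomass flux with a minimal-weight set of additions.

    Runs expanding-pool rounds: (1) database reactions touching blocked
    biomass precursors, (2) all database reactions connected to the network
    in the bipartite graph, (3) the whole database.  On success the filled
    model is returned together with a :class:`GapReport`; on failure the
    original model is returned with an empty addition list and a reason.
    """
    report = GapReport()
    base = solve_fba(model)
    if base.optimal and base.objective > growth_eps:
        report.success = True
        report.reason = "model already grows; nothing to fill"
        report.objective_after = base.objective
        return model, report

    report.blocked_metabolites = find_blocked_precursors(model, tol=growth_eps)
    ranked, unfillable = rank_candidates(report.blocked_metabolites, db, model)
    report.unfillable = unfillable

    dist = _bipartite_distances(model, db, exclude=report.blocked_metabolites)
    db_by_id = {r.rxn_id: r for r in db if r.rxn_id not in model}
    pool_blocked = [c["rxn_id"] for c in ranked]
    pool_reachable = sorted(
        (rid for rid, d in dist.items() if np.isfinite(d)),
        key=lambda rid: (dist[rid], rid),
    )
    pool_all = sorted(db_by_id, key=lambda rid: (dist.get(rid, np.inf), rid))

    exchange_cands = _dead_end_exchange_candidates(model) if allow_exchanges else []

    seen_pools = set()
    for pool in (pool_blocked, pool_reachable, pool_all):
        key = tuple(pool)
        if key in seen_pools:
            continue
        seen_pools.add(key)
        report.iterations += 1
        cand_meta = [{"rxn_id": rid, "distance": dist.get(rid, np.inf)} for rid in pool]
        for ex in exchange_cands:
            cand_meta.append({"rxn_id": ex.rxn_id, "distance": 1.0})
        # keep the report's candidate list cumulative and deduplicated
        known = {c["rxn_id"] for c in report.candidate_reactions}
        report.candidate_reactions += [
            {**c, "distance": (None if not np.isfinite(c["distance"]) else c["distance"])}
            for c in cand_meta if c["rxn_id"] not in known
        ]
        if not cand_meta:
            continue
        weights = _candidate_weights(cand_meta)
        cand_rxns = [db_by_id[rid].copy() for rid in pool] + [e.copy() for e in exchange_cands]
        by_id = {r.rxn_id: r for r in cand_rxns}
        for target in _MILP_GROWTH_TARGETS:
            chosen = _solve_selection_milp(model, cand_rxns, weights,
                                           max(target, growth_eps))
            if chosen is None:
                continue
            filled = model.copy()
            for rid in sorted(chosen):
                filled.add_reaction(by_id[rid].copy())
            after = solve_fba(filled)
            if after.optimal and after.objective > growth_eps:
                report.added_reactions = [
                    {"rxn_id": rid,
                     "provenance": "exchange" if rid.startswith("EX_GF_") else "db",
                     "weight": weights[rid]}
                    for rid in sorted(chosen)
                ]
                report.success = True
                report.objective_after = after.objective
                report.reason = f"growth restored with {len(chosen)} addition(s)"
                return filled, report

    report.reason = "no candidate subset restores growth"
    return model, report
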