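"""Pathway-level analytics over reconstructed models.

Four analyses live here:

* **Completeness scoring** — how much of a KEGG reference pathway a model
  covers, as ``round(100 * matched / reference)`` with half-away-from-zero
  rounding; pathways at or above a 20% presence threshold are called
  present/active.
* **Model comparison** — pairwise and joint reaction intersections between
  models built by different methods, with reactions identified by KEGG
  R-number where available and by a canonical stoichiometry hash otherwise.
* **Hub connectivity** — per-hub counts of significant-flux reactions
  around the seven TCA-cycle carbon-exchange hubs (pyruvate, acetoacetyl-
  CoA, acetyl-CoA, alpha-ketoglutarate, succinyl-CoA, fumarate,
  oxaloacetate).
* **Terpenoid backbone (TBB) feasibility** — inject the 16 curated
  mevalonate / non-mevalonate (DXP) route reactions (15 unique; the IPP
  isomerase is shared) and test whether flux can reach isopentenyl
  pyrophosphate.  The curated equations omit cofactors on purpose and are
  used verbatim for feasibility testing, not mass balance.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .fba import FluxResult, solve_fba
from .model_core import (
    DEFAULT_MAX_FLUX,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_reaction_equation,
)

__all__ = [
    "PathwayDefinition",
    "TCA_HUBS",
    "PRESENCE_THRESHOLD",
    "completeness_percent",
    "pathway_completeness",
    "presence_call",
    "compare_models",
    "hub_connectivity",
    "load_completeness_reference",
    "load_tbb_rows",
    "tbb_reactions",
    "add_tbb_pathway",
    "test_pathway_flux",
]

#: the seven TCA-cycle carbon-exchange hub compounds
TCA_HUBS = ("C00022", "C00332", "C00024", "C00026", "C00091", "C00122", "C00036")

#: pathway presence threshold in percent (inclusive)
PRESENCE_THRESHOLD = 20

#: IPP and DMAPP, the isoprenoid precursors the TBB pathway produces
IPP, DMAPP = "C00129", "C00235"


@dataclass(frozen=True)
class PathwayDefinition:
    """A reference pathway: its size in KEGG plus membership criteria."""

    pathway_id: str
    name: str
    reference_count: int
    member_ecs: FrozenSet[str] = frozenset()
    reaction_ids: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if self.reference_count < 1:
            raise ValueError(f"{self.pathway_id}: reference count must be >= 1")


def completeness_percent(count: int, reference_count: int) -> int:
    """``round(100 * count / reference)``, halves away from zero."""
    if reference_count < 1:
        raise ValueError("reference_count must be >= 1")
    return int(math.floor(100.0 * count / reference_count + 0.5))


def pathway_completeness(
    model: MetabolicModel, pdef: PathwayDefinition
) -> Tuple[int, int]:
    """(matched reaction count, completeness percent) of a pathway in a model.

    A model reaction matches when its id is in the pathway's reaction list
    or its EC annotation intersects the pathway's EC membership.
    """
    count = sum(
        1
        for rxn in model
        if rxn.rxn_id in pdef.reaction_ids or (rxn.ec_numbers & pdef.member_ecs)
    )
    return count, completeness_percent(count, pdef.reference_count)


def presence_call(percent: int, threshold: int = PRESENCE_THRESHOLD) -> bool:
    """Present/active iff completeness is at or above the threshold."""
    if not 0 <= percent <= 100:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    return percent >= threshold


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def compare_models(models: Sequence[MetabolicModel]) -> Dict:
    """Pairwise/full reaction intersections and per-model exclusive counts.

    Deterministic and symmetric; reactions are normalized via
    :meth:`Reaction.identity_key` so heterogeneous id schemes compare.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    keysets = {m.model_id: {r.identity_key() for r in m} for m in models}
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("model ids must be unique for comparison")
    pairwise = {
        (a, b): len(keysets[a] & keysets[b]) for a, b in combinations(ids, 2)
    }
    common_all = len(set.intersection(*keysets.values()))
    exclusive = {}
    for mid in ids:
        others: Set = set().union(*(keysets[o] for o in ids if o != mid))
        exclusive[mid] = len(keysets[mid] - others)
    return {
        "models": ids,
        "sizes": {mid: len(keysets[mid]) for mid in ids},
        "pairwise": pairwise,
        "common_all": common_all,
        "exclusive": exclusive,
    }


def hub_connectivity(
    model: MetabolicModel,
    flux: FluxResult,
    hubs: Sequence[str] = TCA_HUBS,
    significant: float = 0.01,
) -> Tuple[Dict[str, int], int]:
    """Significant-flux reaction counts around hub metabolites.

    Per hub: reactions with |v| > ``significant`` whose stoichiometry
    involves the hub (any compartment).  Also returns the deduplicated
    union count across hubs.
    """
    if not flux.optimal:
        raise ValueError("hub connectivity requires an optimal flux result")
    active = {r for r, v in flux.fluxes.items() if abs(v) > significant}
    per_hub: Dict[str, int] = {}
    union: Set[str] = set()
    for hub in hubs:
        touching = {
            rxn.rxn_id
            for rxn in model
            if rxn.rxn_id in active
            and any(m.kegg_id == hub for m in rxn.stoichiometry)
        }
        per_hub[hub] = len(touching)
        union |= touching
    return per_hub, len(union)


# ---------------------------------------------------------------------------
# Packaged pathway tables
# ---------------------------------------------------------------------------

def load_completeness_reference() -> List[Dict]:
    """The packaged pathway-completeness table (27 pathways x 3 models).

    Each row carries the KEGG reference reaction count and, per model
    version, the matched count and the published percentage.
    """
    path = resources.files("proteogem.data").joinpath("pathway_completeness_reference.tsv")
    with path.open() as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    for row in rows:
        for key in row:
            if key.endswith(("_count", "_pct")) or key == "reference_count":
                row[key] = int(row[key])
    return rows


def load_tbb_rows() -> List[Dict]:
    """The 16 curated terpenoid-backbone reaction rows (as published)."""
    path = resources.files("proteogem.data").joinpath("tbb_reactions.tsv")
    with path.open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def tbb_reactions() -> List[Reaction]:
    """The unique TBB reactions (the shared IPP isomerase collapses to one)."""
    out: Dict[str, Reaction] = {}
    for row in load_tbb_rows():
        if row["rxn_id"] in out:
            continue
        rxn = parse_reaction_equation(row["equation"], row["rxn_id"])
        rxn.ec_numbers = frozenset([row["ec"]])
        rxn.name = row["enzyme"]
        rxn.subsystem = "Terpenoid backbone biosynthesis"
        out[row["rxn_id"]] = rxn
    return list(out.values())


def add_tbb_pathway(model: MetabolicModel) -> Tuple[MetabolicModel, Dict]:
    """Merge the TBB reaction set into a model.

    Reactions already present are skipped.  The report flags whether the
    entry precursors of the two routes (acetyl-CoA for mevalonate;
    glyceraldehyde-3-phosphate + pyruvate for DXP) exist in the network, so
    an unconnected injection is visible rather than silent.
    """
    new = model.copy()
    added, skipped = [], []
    for rxn in tbb_reactions():
        if rxn.rxn_id in new:
            skipped.append(rxn.rxn_id)
            continue
        new.add_reaction(rxn.copy())
        added.append(rxn.rxn_id)
    have = {m.kegg_id for m in model.metabolites}
    missing = sorted({"C00024", "C00118", "C00022"} - have)
    return new, {"added": added, "skipped": skipped, "missing_precursors": missing}


def test_pathway_flux(
    model: MetabolicModel,
    target: str,
    min_flux: float = 1e-6,
    biomass_fraction: Optional[float] = None,
    compartment: str = "c",
) -> Tuple[bool, FluxResult]:
    """Can the network sustain flux to ``target``?

    Adds a temporary drain for the target metabolite and maximizes it,
    optionally holding biomass at a fraction of its unconstrained optimum.
    Feasible iff the drain optimum reaches ``min_flux``.
    """
    met = Metabolite(target, compartment)
    if met.key not in {m.key for m in model.metabolites}:
        raise ValueError(f"target metabolite {met.key} not in model")
    probe = model.copy()
    drain_id = f"DM_{target}_{compartment}"
    if drain_id not in probe:
        probe.add_reaction(Reaction(drain_id, {met: -1.0}, 0.0, DEFAULT_MAX_FLUX))
    if biomass_fraction is not None:
        base = solve_fba(model)
        if base.optimal:
            bio = probe.biomass_reaction()
            bio.lower_bound = biomass_fraction * base.objective
    res = solve_fba(probe, maximize=drain_id)
    feasible = res.optimal and res.objective >= min_flux
    return feasible, res


# not a test despite the name (pytest collection guard)
test_pathway_flux.__test__ = False
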