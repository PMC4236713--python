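"""Synthetic networks and evidence tables with known ground truth.

Every pipeline stage is testable offline against generated data whose
correct answer is known in closed form:

* a growing toy model of parallel linear pathways whose FBA optimum is
  analytic (``uptake / sum_j 1/yield_j``),
* knockout experiments that remove verified-essential reactions so
  gap-filling has an exact recovery target,
* protein-evidence and annotation tables with tunable coverage and decoy
  noise, emulating a shotgun-proteomics protein list with confident
  identifications below the log(e) < -10 cutoff.

All generators are deterministic in their seed, and defaults mirror the
study conditions of the modeled organism: cellobiose-limited growth with a
substrate uptake rate of 0.25 mmol/gDW/h, and a proteome table of 2101
identified proteins of which 1700 clear the confidence cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fba import solve_fba
from .model_core import (
    DEFAULT_MAX_FLUX,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from .reconstruction import (
    AnnotationTable,
    ProteinEvidence,
    ReactionDatabase,
    write_annotation,
    write_evidence,
)

__all__ = [
    "SyntheticSpec",
    "EvidenceTruth",
    "generate_toy_model",
    "essential_reactions",
    "knock_out",
    "generate_evidence",
    "make_proteomics_table",
    "toy_reaction_database",
    "BIOMASS_PSEUDO_COMPOUND",
]

#: pseudo-compound produced by the toy biomass reaction (drained by a sink)
BIOMASS_PSEUDO_COMPOUND = "C99999"

#: substrate compound id of the toy network
TOY_SUBSTRATE = "C90000"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``uptake_rate`` defaults to 0.25 mmol/gDW/h (the experimentally
    measured cellobiose uptake used for all growth simulations).  Yields
    default to 1 per pathway; the analytic growth optimum is
    ``uptake_rate / sum_j (1 / yield_j)``.
    """

    n_linear_pathways: int = 3
    pathway_length: int = 4
    uptake_rate: float = 0.25
    seed: int = 0
    evidence_coverage: float = 1.0
    evidence_noise: float = 0.0
    knockout_count: int = 1
    yields: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.n_linear_pathways < 1:
            raise ValueError("need at least one pathway")
        if self.pathway_length < 1:
            raise ValueError("pathway length must be >= 1")
        if not (0 <= self.evidence_coverage <= 1 and 0 <= self.evidence_noise <= 1):
            raise ValueError("coverage and noise must be fractions in [0, 1]")
        if self.uptake_rate < 0:
            raise ValueError("uptake rate must be non-negative")
        if self.yields is not None and len(self.yields) != self.n_linear_pathways:
            raise ValueError("one yield per pathway required")

    @property
    def pathway_yields(self) -> Tuple[float, ...]:
        return self.yields or tuple([1.0] * self.n_linear_pathways)


def _met(j: int, i: int) -> Metabolite:
    # C9<j><iii>: synthetic ids inside the KEGG C-number pattern
    return Metabolite(f"C9{j}{i:03d}", "c")


def generate_toy_model(spec: SyntheticSpec) -> Tuple[MetabolicModel, float]:
    """Toy network of parallel linear pathways with an analytic optimum.

    One substrate exchange feeds ``n_linear_pathways`` chains of
    ``pathway_length`` reactions each; the first reaction of chain *j*
    converts one substrate into ``yield_j`` of the chain's first
    intermediate.  Biomass consumes one unit of every chain's end product
    and emits a pseudo-compound removed by a sink, so the model file
    round-trips through the reaction-TSV dialect.
    """
    model = MetabolicModel(f"toy_seed{spec.seed}")
    substrate = Metabolite(TOY_SUBSTRATE, "c")
    model.add_reaction(
        Reaction("EX_SUBSTRATE", {substrate: -1.0}, -spec.uptake_rate,
                 DEFAULT_MAX_FLUX, subsystem="Exchange")
    )
    precursors = []
    for j, y in enumerate(spec.pathway_yields):
        prev = substrate
        for i in range(spec.pathway_length):
            nxt = _met(j, i + 1)
            coef_in = -1.0
            coef_out = y if i == 0 else 1.0
            rid = f"P{j}R{i:02d}"
            model.add_reaction(
                Reaction(
                    rid,
                    {prev: coef_in, nxt: coef_out},
                    0.0,
                    DEFAULT_MAX_FLUX,
                    ec_numbers=frozenset([f"9.9.{j + 1}.{i + 1}"]),
                    gene_ids=frozenset([f"G{j}{i:03d}"]),
                    subsystem=f"Pathway {j}",
                )
            )
            prev = nxt
        precursors.append(prev)
    biomass_stoich: Dict[Metabolite, float] = {m: -1.0 for m in precursors}
    biomass_stoich[Metabolite(BIOMASS_PSEUDO_COMPOUND, "c")] = 1.0
    model.add_reaction(
        Reaction("BIOMASS", biomass_stoich, 0.0, DEFAULT_MAX_FLUX, subsystem="Biomass")
    )
    model.add_reaction(
        Reaction("SINK_BIOMASS", {Metabolite(BIOMASS_PSEUDO_COMPOUND, "c"): -1.0},
                 0.0, DEFAULT_MAX_FLUX, subsystem="Exchange")
    )
    model.biomass_id = "BIOMASS"
    analytic = spec.uptake_rate / sum(1.0 / y for y in spec.pathway_yields)
    return model, analytic


def toy_reaction_database(model: MetabolicModel) -> ReactionDatabase:
    """Reference database holding the model's enzymatic (EC-tagged) reactions."""
    return ReactionDatabase([r.copy() for r in model if r.ec_numbers])


def essential_reactions(model: MetabolicModel, eps: float = 1e-9) -> List[str]:
    """Single-deletion scan: enzymatic reactions whose removal kills growth."""
    base = solve_fba(model)
    if not base.optimal or base.objective <= eps:
        raise ValueError("base model does not grow; essentiality scan is undefined")
    out = []
    for rxn in model:
        if not rxn.ec_numbers:
            continue
        probe = model.copy()
        probe.remove_reaction(rxn.rxn_id)
        res = solve_fba(probe)
        if not res.optimal or res.objective <= eps:
            out.append(rxn.rxn_id)
    return out


def knock_out(
    model: MetabolicModel, k: int, seed: int = 0
) -> Tuple[MetabolicModel, List[Reaction]]:
    """Remove ``k`` verified-essential reactions; returns (gapped model, truth).

    The gapped model has zero growth by construction.  Raises when fewer
    than ``k`` essential reactions exist.
    """
    rng = np.random.default_rng(seed)
    essentials = essential_reactions(model)
    if k > len(essentials):
        raise ValueError(f"requested {k} knockouts but only {len(essentials)} "
                         "essential reactions exist")
    chosen = sorted(rng.choice(essentials, size=k, replace=False).tolist())
    gapped = model.copy(model_id=f"{model.model_id}_ko{k}s{seed}")
    removed = [gapped.remove_reaction(rid) for rid in chosen]
    return gapped, removed


@dataclass
class EvidenceTruth:
    """Ground truth behind a generated evidence table."""

    covered_genes: List[str]
    missed_genes: List[str]
    decoy_proteins: List[str]


def generate_evidence(
    model: MetabolicModel,
    coverage: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
    out_dir: Optional[Path] = None,
) -> Tuple[List[ProteinEvidence], AnnotationTable, EvidenceTruth]:
    """Evidence + annotation tables for a model's genes, with ground truth.

    A ``coverage`` fraction of the model's genes is emitted with confident
    scores (log(e) uniform in [-40, -11]); the remaining genes are emitted
    as measured but sub-threshold (log(e) in [-9, 0]), as a shotgun run
    reports low-confidence identifications too.  ``noise`` adds decoy
    proteins, confidently scored but annotated with ECs absent from the
    model — false evidence a reconstruction should be robust to.  If
    ``out_dir`` is given, ``evidence.tsv`` and ``annotation.tsv`` are
    written there.
    """
    rng = np.random.default_rng(seed)
    gene_to_ecs: Dict[str, set] = {}
    for rxn in model:
        for g in rxn.gene_ids:
            gene_to_ecs.setdefault(g, set()).update(rxn.ec_numbers)
    genes = sorted(gene_to_ecs)
    n_cov = int(round(coverage * len(genes)))
    covered = sorted(rng.choice(genes, size=n_cov, replace=False).tolist())
    missed = sorted(set(genes) - set(covered))

    evidence = [
        ProteinEvidence(g, float(rng.uniform(-40.0, -11.0)), int(rng.integers(2, 40)))
        for g in covered
    ]
    evidence += [
        ProteinEvidence(g, float(rng.uniform(-9.0, 0.0)), 1) for g in missed
    ]
    n_decoys = int(round(noise * len(genes)))
    decoys = [f"DECOY_{i:03d}" for i in range(n_decoys)]
    annot_map = {g: sorted(gene_to_ecs[g]) for g in genes}
    for i, d in enumerate(decoys):
        evidence.append(ProteinEvidence(d, float(rng.uniform(-40.0, -11.0)), 2))
        annot_map[d] = [f"8.8.8.{i + 1}"]

    annot = AnnotationTable(annot_map)
    truth = EvidenceTruth(covered, missed, decoys)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_evidence(evidence, out_dir / "evidence.tsv")
        write_annotation(annot, out_dir / "annotation.tsv")
    return evidence, annot, truth


def make_proteomics_table(
    n_total: int = 2101,
    n_confident: int = 1700,
    seed: int = 0,
) -> List[ProteinEvidence]:
    """A proteome-scale evidence table with a fixed confident fraction.

    Emulates the published protein list: ``n_total`` identified proteins of
    which exactly ``n_confident`` score log(e) < -10 (drawn uniform in
    [-40, -11]); the remainder sit above the cutoff in [-9.99, 0].
    """
    if n_confident > n_total:
        raise ValueError("n_confident cannot exceed n_total")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_total):
        if i < n_confident:
            log_e = float(rng.uniform(-40.0, -11.0))
        else:
            log_e = float(rng.uniform(-9.99, 0.0))
        records.append(
            ProteinEvidence(f"Tfu_{i:04d}", log_e, int(rng.integers(1, 120)))
        )
    order = rng.permutation(n_total)
    return [records[i] for i in order]
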