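"""Evidence-driven draft reconstruction.

The proteomics-first scheme starts from the proteins actually detected in
the cell (shotgun MS/MS protein identifications with a log10 expectation
score; more negative = more confident), keeps the high-confidence ones
(log(e) strictly below -10 by default), maps them to EC numbers through an
annotation table, and pulls every reaction carrying one of those ECs from a
reference reaction database.  Manual curation rows (e.g. cellobiose
hydrolysis by the expressed beta-glucosidase) are then layered on top with
their evidence recorded.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .model_core import (
    MetabolicModel,
    ModelValidationError,
    Reaction,
    ReactionParseError,
    parse_reaction_equation,
    format_equation,
)

__all__ = [
    "ProteinEvidence",
    "AnnotationTable",
    "ReactionDatabase",
    "CurationRow",
    "filter_evidence",
    "map_evidence_to_ec",
    "draft_from_ec",
    "apply_curation",
    "default_curation",
    "read_evidence",
    "write_evidence",
    "read_annotation",
    "write_annotation",
    "read_curation",
    "DEFAULT_LOG_E_THRESHOLD",
]

#: confidence cutoff on the protein log10 expectation value (strict <)
DEFAULT_LOG_E_THRESHOLD = -10.0

EC_RE = re.compile(r"\d+\.\d+\.\d+\.(\d+|-)")


@dataclass(frozen=True)
class ProteinEvidence:
    """One identified protein: locus tag, log10 expectation, peptide count."""

    protein_id: str
    log_e: float
    n_peptides: int = 1

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError(f"{self.protein_id}: n_peptides must be >= 1")


class AnnotationTable:
    """Mapping of protein/gene locus tags to their EC numbers."""

    def __init__(self, mapping: Mapping[str, Iterable[str]] = ()):
        self._map: Dict[str, frozenset] = {}
        for pid, ecs in dict(mapping).items():
            ecs = frozenset(ecs)
            for ec in ecs:
                if not EC_RE.fullmatch(ec):
                    raise ValueError(f"{pid}: malformed EC number '{ec}'")
            self._map[pid] = ecs

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def get(self, protein_id: str) -> frozenset:
        return self._map.get(protein_id, frozenset())

    def items(self):
        return self._map.items()


@dataclass
class ReactionDatabase:
    """Reference reaction database: (rxn_id, equation, ECs, subsystem) records.

    Every record must be parseable; parsing happens eagerly on construction
    so malformed databases fail loudly, not mid-pipeline.
    """

    reactions: List[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rxn in self.reactions:
            if rxn.rxn_id in seen:
                raise ModelValidationError(f"duplicate database reaction id '{rxn.rxn_id}'")
            seen.add(rxn.rxn_id)

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)

    def __contains__(self, rxn_id: str) -> bool:
        return any(r.rxn_id == rxn_id for r in self.reactions)

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, str, Iterable[str], str]]
    ) -> "ReactionDatabase":
        """Build from (rxn_id, equation, ec_numbers, subsystem) tuples."""
        rxns = []
        for rid, eq, ecs, subsystem in records:
            rxn = parse_reaction_equation(eq, rid)
            rxn.ec_numbers = frozenset(ecs)
            rxn.subsystem = subsystem
            rxns.append(rxn)
        return cls(rxns)

    @classmethod
    def from_tsv(cls, path) -> "ReactionDatabase":
        from .model_core import read_model

        model = read_model(path)
        return cls([r.copy() for r in model])

    def by_ec(self, ec: str) -> List[Reaction]:
        return [r for r in self.reactions if ec in r.ec_numbers]


@dataclass(frozen=True)
class CurationRow:
    """A manually curated reaction addition with its supporting evidence."""

    reaction: Reaction
    evidence_note: str = ""


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_evidence(
    evidence: Sequence[ProteinEvidence],
    threshold_log_e: float = DEFAULT_LOG_E_THRESHOLD,
) -> List[ProteinEvidence]:
    """Keep proteins with log(e) strictly below the confidence threshold.

    Order-preserving and idempotent; a record sitting exactly at the
    threshold is dropped (the cutoff is a strict inequality).
    """
    return [e for e in evidence if e.log_e < threshold_log_e]


def map_evidence_to_ec(
    evidence: Sequence[ProteinEvidence],
    annot: AnnotationTable,
) -> Tuple[Set[str], List[str]]:
    """Union of EC numbers over evidenced proteins.

    Proteins with multiple ECs contribute all of them.  Proteins without an
    EC annotation are returned as the second element (``unmapped``) rather
    than silently dropped — they are candidate targets for curation.
    """
    ecs: Set[str] = set()
    unmapped: List[str] = []
    for ev in evidence:
        protein_ecs = annot.get(ev.protein_id)
        if protein_ecs:
            ecs |= protein_ecs
        else:
            unmapped.append(ev.protein_id)
    return ecs, unmapped


def draft_from_ec(
    ec_set: Set[str],
    db: ReactionDatabase,
    model_id: str = "draft",
) -> MetabolicModel:
    """Draft model: every database reaction whose EC set meets ``ec_set``.

    Database reactions lacking EC annotation are never pulled in here; they
    remain reachable only through curation.  No biomass or exchange
    reactions are added at this stage.
    """
    model = MetabolicModel(model_id)
    for rxn in db:
        if rxn.ec_numbers & ec_set:
            model.add_reaction(rxn.copy())
    if len(model) == 0:
        warnings.warn(f"draft '{model_id}' is empty: no database reaction matched "
                      f"{len(ec_set)} evidenced EC numbers")
    return model


def apply_curation(
    model: MetabolicModel,
    curation: Iterable[CurationRow],
) -> Tuple[MetabolicModel, List[Dict[str, str]]]:
    """Apply curated reaction rows; returns (model, provenance log).

    A row duplicating an existing reaction verbatim is a warned no-op; a row
    colliding with an existing id but different stoichiometry is a conflict
    error.  Bounds of an existing reaction are overridden when only bounds
    differ.
    """
    new = model.copy()
    log: List[Dict[str, str]] = []
    for row in curation:
        rxn = row.reaction
        if rxn.rxn_id in new:
            existing = new[rxn.rxn_id]
            if existing.stoichiometry != rxn.stoichiometry:
                raise ModelValidationError(
                    f"curation conflict: '{rxn.rxn_id}' exists with different stoichiometry"
                )
            if (existing.lower_bound, existing.upper_bound) == (
                rxn.lower_bound, rxn.upper_bound
            ):
                warnings.warn(f"curation row '{rxn.rxn_id}' duplicates the model verbatim")
                log.append({"rxn_id": rxn.rxn_id, "action": "noop", "note": row.evidence_note})
                continue
            existing.lower_bound = rxn.lower_bound
            existing.upper_bound = rxn.upper_bound
            log.append({"rxn_id": rxn.rxn_id, "action": "bounds", "note": row.evidence_note})
            continue
        new.add_reaction(rxn.copy())
        log.append({"rxn_id": rxn.rxn_id, "action": "added", "note": row.evidence_note})
    return new, log


def default_curation() -> List[CurationRow]:
    """The shipped cellobiose curation.

    Adds beta-glucosidase hydrolysis (cellobiose + H2O -> 2 glucose,
    EC 3.2.1.21, expressed on cellobiose-grown cells) and a cellobiose
    exchange, so that a glucose-consuming model can grow on cellobiose.
    """
    path = resources.files("proteogem.data").joinpath("curation_cellobiose.tsv")
    return read_curation(path)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_evidence(path) -> List[ProteinEvidence]:
    """Read an evidence TSV: ``protein_id  log_e  n_peptides``."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ProteinEvidence(row["protein_id"], float(row["log_e"]),
                                int(row.get("n_peptides", 1) or 1))
            )
    return out


def write_evidence(evidence: Sequence[ProteinEvidence], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein_id", "log_e", "n_peptides"])
        for ev in evidence:
            w.writerow([ev.protein_id, f"{ev.log_e:.10g}", ev.n_peptides])


def read_annotation(path) -> AnnotationTable:
    """Read an annotation TSV: ``protein_id  ec_list`` (;-separated ECs)."""
    mapping: Dict[str, List[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ecs = [x for x in (row.get("ec_list") or "").split(";") if x]
            mapping[row["protein_id"]] = ecs
    return AnnotationTable(mapping)


def write_annotation(annot: AnnotationTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein_id", "ec_list"])
        for pid, ecs in sorted(annot.items()):
            w.writerow([pid, ";".join(sorted(ecs))])


def read_curation(path) -> List[CurationRow]:
    """Read a curation TSV: reaction-TSV columns plus ``evidence_note``."""
    rows = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                rxn = parse_reaction_equation(row["equation"], row["rxn_id"])
            except ReactionParseError as exc:
                raise ReactionParseError(f"{path}:{lineno}: {exc}") from exc
            rxn.lower_bound = float(row["lb"])
            rxn.upper_bound = float(row["ub"])
            rxn.ec_numbers = frozenset(x for x in (row.get("ec") or "").split(";") if x)
            rxn.gene_ids = frozenset(x for x in (row.get("genes") or "").split(";") if x)
            rxn.subsystem = row.get("subsystem", "") or ""
            rows.append(CurationRow(rxn, row.get("evidence_note", "") or ""))
    return rows
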