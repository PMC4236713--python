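"""End-to-end orchestration: reconstruct -> gapfill -> FBA -> integrate -> report.

A single JSON config drives the run; every stage logs its reaction and
metabolite counts so the provenance of the final model is auditable, and
all thresholds are echoed into the summary.  Stages can be toggled — for
example, disabling gap-filling on a gapped draft still completes the run
and reports zero growth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from . import reconstruction as rec
from .expression_integration import call_states, imat
from .fba import classify_fluxes, set_uptake, solve_fba
from .gapfill import gapfill
from .model_core import MetabolicModel, read_model, write_model
from .pathway_analysis import (
    PRESENCE_THRESHOLD,
    PathwayDefinition,
    pathway_completeness,
    presence_call,
)

__all__ = ["RunConfig", "ModelSummary", "run_pipeline", "summarize_subsystems",
           "load_supplementary_models", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the audit trail."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, thresholds, and stage toggles for one pipeline run.

    Thresholds default to the study's values: confidence cutoff
    log(e) < -10, cellobiose uptake 0.25 mmol/gDW/h, high-flux threshold
    100, significant-flux threshold 0.01, pathway presence 20%.
    """

    evidence_path: Optional[str] = None
    annotation_path: Optional[str] = None
    db_path: Optional[str] = None
    curation_path: Optional[str] = None
    pathways_path: Optional[str] = None
    model_path: Optional[str] = None  # alternative entry: skip reconstruction
    out_dir: str = "proteogem_out"
    uptake: Dict[str, float] = field(default_factory=dict)
    log_e_threshold: float = -10.0
    high_flux: float = 100.0
    significant_flux: float = 0.01
    presence_percent: int = PRESENCE_THRESHOLD
    allow_exchanges: bool = False
    biomass_id: str = "BIOMASS"
    stages: Dict[str, bool] = field(
        default_factory=lambda: {
            "reconstruct": True, "curation": True, "gapfill": True,
            "fba": True, "integrate": False, "pathways": False,
        }
    )
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        for key in ("evidence_path", "annotation_path", "db_path",
                    "curation_path", "pathways_path", "model_path"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        return cfg


@dataclass
class ModelSummary:
    """Headline statistics of a finished run."""

    model_id: str
    n_reactions: int
    n_metabolites: int
    n_ec: int
    n_genes: int
    growth_rate: float
    fba_status: str
    subsystems: Dict[str, int]
    n_highly_active: int = 0
    n_significant: int = 0
    gap_report: Optional[Dict] = None
    agreement: Optional[int] = None
    thresholds: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return asdict(self)


def summarize_subsystems(model: MetabolicModel) -> Tuple[Dict[str, int], int]:
    """Reaction tally per subsystem tag plus the untagged count."""
    tally: Dict[str, int] = {}
    untagged = 0
    for rxn in model:
        if rxn.subsystem:
            tally[rxn.subsystem] = tally.get(rxn.subsystem, 0) + 1
        else:
            untagged += 1
    return tally, untagged


def _summary_counts(model: MetabolicModel) -> Tuple[int, int, int, int]:
    ecs = set().union(*(r.ec_numbers for r in model)) if len(model) else set()
    genes = set().union(*(r.gene_ids for r in model)) if len(model) else set()
    return len(model), len(model.metabolites), len(ecs), len(genes)


def run_pipeline(config: RunConfig) -> ModelSummary:
    """Execute the enabled stages in order and write artifacts to disk.

    Outputs under ``config.out_dir``: ``model.tsv``, ``fluxes.tsv``,
    ``gaps.json``, ``agreement.json``, ``pathways.tsv``, ``summary.json``
    and a structured ``stages.log``.  Any stage failure aborts with the
    stage name; artifacts produced so far are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: List[str] = []

    def note(stage: str, msg: str) -> None:
        log.append(f"[{stage}] {msg}")

    # --- entry model -------------------------------------------------------
    evidence = annot = None
    if config.stages.get("reconstruct", True) and config.evidence_path:
        try:
            evidence = rec.read_evidence(config.evidence_path)
            annot = rec.read_annotation(config.annotation_path)
            db = rec.ReactionDatabase.from_tsv(config.db_path)
            confident = rec.filter_evidence(evidence, config.log_e_threshold)
            ecs, unmapped = rec.map_evidence_to_ec(confident, annot)
            model = rec.draft_from_ec(ecs, db, model_id="draft")
            note("reconstruct",
                 f"{len(confident)}/{len(evidence)} confident proteins, "
                 f"{len(ecs)} ECs, {len(unmapped)} unmapped -> "
                 f"{len(model)} reactions / {len(model.metabolites)} metabolites")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("reconstruct", str(exc)) from exc
    elif config.model_path:
        model = read_model(config.model_path, biomass_id=config.biomass_id
                           if config.biomass_id else None)
        note("load", f"{len(model)} reactions from {config.model_path}")
    else:
        raise PipelineError("reconstruct",
                            "no evidence_path and no model_path configured")

    # --- curation ----------------------------------------------------------
    if config.stages.get("curation", True) and config.curation_path:
        try:
            rows = rec.read_curation(config.curation_path)
            model, curation_log = rec.apply_curation(model, rows)
            note("curation", f"{len(curation_log)} curated rows applied -> "
                             f"{len(model)} reactions")
        except Exception as exc:
            raise PipelineError("curation", str(exc)) from exc
    if config.biomass_id in model:
        model.biomass_id = config.biomass_id

    # --- uptake constraints ------------------------------------------------
    for kegg_id, rate in sorted(config.uptake.items()):
        model = set_uptake(model, kegg_id, rate)
        note("uptake", f"{kegg_id} uptake set to {rate} mmol/gDW/h")

    gap_digest = None
    if config.stages.get("gapfill", True):
        try:
            db = rec.ReactionDatabase.from_tsv(config.db_path) if config.db_path \
                else rec.ReactionDatabase([])
            model, gap_report = gapfill(model, db,
                                        allow_exchanges=config.allow_exchanges)
            gap_digest = gap_report.to_dict()
            (out / "gaps.json").write_text(json.dumps(gap_digest, indent=2))
            note("gapfill", gap_report.reason)
        except Exception as exc:
            raise PipelineError("gapfill", str(exc)) from exc

    write_model(model, out / "model.tsv")

    # --- FBA ----------------------------------------------------------------
    growth, status, n_high, n_sig = 0.0, "skipped", 0, 0
    if config.stages.get("fba", True):
        try:
            result = solve_fba(model)
            status = result.status
            growth = result.objective if result.optimal else 0.0
            if result.optimal:
                classes = classify_fluxes(result, config.high_flux,
                                          config.significant_flux)
                n_high = len(classes["highly_active"])
                n_sig = len(classes["significant"])
                lines = ["rxn_id\tflux\tclass"]
                for rid in sorted(result.fluxes):
                    v = result.fluxes[rid]
                    cls = ("highly_active" if rid in classes["highly_active"]
                           else "significant" if rid in classes["significant"]
                           else "zero")
                    lines.append(f"{rid}\t{v:.10g}\t{cls}")
                (out / "fluxes.tsv").write_text("\n".join(lines) + "\n")
            note("fba", f"status={status} growth={growth:.6g} doublings/h")
        except Exception as exc:
            raise PipelineError("fba", str(exc)) from exc

    # --- expression integration ---------------------------------------------
    agreement = None
    if config.stages.get("integrate", False) and evidence is not None:
        try:
            states = call_states(model, evidence, annot, config.log_e_threshold)
            _, agreement = imat(model, states)
            counts = states.counts()
            (out / "agreement.json").write_text(json.dumps(
                {"agreement": agreement, "calls": counts}, indent=2))
            note("integrate", f"agreement={agreement} over "
                              f"{counts['present'] + counts['absent']} called reactions")
        except Exception as exc:
            raise PipelineError("integrate", str(exc)) from exc

    # --- pathway completeness ------------------------------------------------
    if config.stages.get("pathways", False) and config.pathways_path:
        try:
            lines = ["pathway_id\tname\tcount\tpercent\tpresent"]
            import csv as _csv

            with open(config.pathways_path, newline="") as fh:
                for row in _csv.DictReader(fh, delimiter="\t"):
                    pdef = PathwayDefinition(
                        row["pathway_id"], row["name"], int(row["reference_count"]),
                        member_ecs=frozenset(
                            x for x in (row.get("ec_list") or "").split(";") if x),
                        reaction_ids=frozenset(
                            x for x in (row.get("rxn_list") or "").split(";") if x),
                    )
                    count, pct = pathway_completeness(model, pdef)
                    lines.append(f"{pdef.pathway_id}\t{pdef.name}\t{count}\t{pct}\t"
                                 f"{presence_call(pct, config.presence_percent)}")
            (out / "pathways.tsv").write_text("\n".join(lines) + "\n")
            note("pathways", f"{len(lines) - 1} pathways scored")
        except Exception as exc:
            raise PipelineError("pathways", str(exc)) from exc

    n_rxn, n_met, n_ec, n_genes = _summary_counts(model)
    subsystems, untagged = summarize_subsystems(model)
    if untagged:
        subsystems["(untagged)"] = untagged
    summary = ModelSummary(
        model_id=model.model_id,
        n_reactions=n_rxn, n_metabolites=n_met, n_ec=n_ec, n_genes=n_genes,
        growth_rate=growth, fba_status=status, subsystems=subsystems,
        n_highly_active=n_high, n_significant=n_sig,
        gap_report=gap_digest, agreement=agreement,
        thresholds={
            "log_e": config.log_e_threshold, "high_flux": config.high_flux,
            "significant_flux": config.significant_flux,
            "presence_percent": config.presence_percent,
        },
    )
    (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    (out / "stages.log").write_text("\n".join(log) + "\n")
    return summary


def load_supplementary_models(path) -> Dict[str, MetabolicModel]:
    """Import the three published model versions from a local copy.

    ``path`` may be a directory of reaction-TSVs named ``tfu_v1.tsv``,
    ``tfu_v2.tsv``, ``tfu_v3.tsv``, or a spreadsheet (.xls/.xlsx) with one
    sheet per version in which the first columns are reaction id and
    equation (optionally bounds).  The supplementary spreadsheet is not
    redistributed with this package; drop a copy under
    ``data/supplementary/`` to reproduce the published growth rates and
    model intersections.
    """
    path = Path(path)
    models: Dict[str, MetabolicModel] = {}
    if path.is_dir():
        for name in ("tfu_v1", "tfu_v2", "tfu_v3"):
            f = path / f"{name}.tsv"
            if f.exists():
                models[name] = read_model(f, model_id=name)
    elif path.suffix in (".xls", ".xlsx"):
        import pandas as pd

        from .model_core import parse_reaction_equation

        sheets = pd.read_excel(path, sheet_name=None, header=0)
        for sheet, df in sheets.items():
            model = MetabolicModel(sheet.strip().lower().replace(" ", "_"))
            cols = list(df.columns)
            for _, row in df.iterrows():
                rid = str(row[cols[0]]).strip()
                eq = str(row[cols[1]]).strip()
                if not rid or rid == "nan" or "-" not in eq:
                    continue
                try:
                    rxn = parse_reaction_equation(eq, rid)
                except Exception:
                    continue
                if len(cols) >= 4:
                    try:
                        rxn.lower_bound = float(row[cols[2]])
                        rxn.upper_bound = float(row[cols[3]])
                    except (TypeError, ValueError):
                        pass
                if rid not in model:
                    model.add_reaction(rxn)
            models[model.model_id] = model
    else:
        raise FileNotFoundError(f"no supplementary models at {path}")
    if not models:
        raise FileNotFoundError(f"no model sheets/files recognised in {path}")
    return models
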