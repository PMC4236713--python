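"""Core domain types for constraint-based metabolic models.

A metabolic network is represented as a collection of reactions over
KEGG-identified metabolites.  Each reaction carries a signed stoichiometry
(reactants negative, products positive), flux bounds in mmol/gDW/h, and
optional EC-number / gene annotations.  The stoichiometric matrix S used by
flux balance analysis (rows = metabolites, columns = reactions) is assembled
here with deterministic, lexicographic row/column ordering.

Reaction equations use a compartment-prefixed KEGG dialect, e.g.::

    [c]: C00024 --> C00332
    [c]: 34.7964805 C00001 + 40.1701382 C00002 --> 40 C00008

Coefficients may be glued to the compound identifier (``34.7964805C00001``)
or space-separated; ``-->`` marks an irreversible reaction and ``<-->`` a
reversible one.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BiomassEquation",
    "StoichiometricMatrix",
    "ReactionParseError",
    "ModelValidationError",
    "DEFAULT_MAX_FLUX",
    "COMPARTMENTS",
    "parse_reaction_equation",
    "format_equation",
    "build_stoichiometric_matrix",
    "biomass_equation_fixture",
    "make_biomass_reaction",
    "read_model",
    "write_model",
]

DEFAULT_MAX_FLUX = 1000.0
COMPARTMENTS = ("c", "e")

_COMPOUND_RE = re.compile(r"C\d{5}")
_TERM_RE = re.compile(
    r"^\s*(?P<coef>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)?\s*"
    r"(?P<cid>[A-Za-z]\w*)(?:\[(?P<comp>[a-z])\])?\s*$"
)
_GLUED_RE = re.compile(
    r"^\s*(?P<coef>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"
    r"(?P<cid>C\d{5})(?:\[(?P<comp>[a-z])\])?\s*$"
)
_ARROW_RE = re.compile(r"<\s*-+\s*>|-+\s*>")
_PREFIX_RE = re.compile(r"^\s*\[(?P<comp>[a-z])\]\s*:\s*")


class ReactionParseError(ValueError):
    """Raised when a reaction equation string cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A compound in a compartment, keyed by (KEGG id, compartment)."""

    kegg_id: str
    compartment: str = "c"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ReactionParseError(
                f"unknown compartment tag '{self.compartment}' for {self.kegg_id}"
            )

    @property
    def is_standard(self) -> bool:
        """Whether the identifier is a KEGG C-number."""
        return bool(_COMPOUND_RE.fullmatch(self.kegg_id))

    @property
    def key(self) -> str:
        return f"{self.kegg_id}[{self.compartment}]"

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.key


@dataclass
class Reaction:
    """A stoichiometric reaction with bounds and annotations.

    ``stoichiometry`` maps :class:`Metabolite` to a signed coefficient;
    reactants are negative and products positive.  Bounds follow the COBRA
    convention: an uptake rate *u* on an exchange reaction is imposed as
    ``lower_bound = -u``.
    """

    rxn_id: str
    stoichiometry: Dict[Metabolite, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_MAX_FLUX
    ec_numbers: frozenset = frozenset()
    gene_ids: frozenset = frozenset()
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.ec_numbers = frozenset(self.ec_numbers)
        self.gene_ids = frozenset(self.gene_ids)
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"{self.rxn_id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"{self.rxn_id}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary reaction: a single metabolite crossing the system edge."""
        return len(self.stoichiometry) == 1

    @property
    def reactants(self) -> Dict[Metabolite, float]:
        return {m: c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> Dict[Metabolite, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))

    def identity_key(self) -> Tuple:
        """Canonical identity for cross-model comparison.

        KEGG R-numbers are authoritative where present; otherwise a
        normalized hash of the sorted (compound, coefficient) pairs is used
        so that structurally identical reactions match across models with
        heterogeneous naming schemes.
        """
        if re.fullmatch(r"R\d{5}", self.rxn_id):
            return ("kegg", self.rxn_id)
        pairs = tuple(
            sorted((m.key, round(c, 9)) for m, c in self.stoichiometry.items())
        )
        return ("stoich", pairs)


def _parse_term(term: str, default_comp: str, rxn_id: str) -> Tuple[float, Metabolite]:
    m = _GLUED_RE.match(term) or _TERM_RE.match(term)
    if not m or not m.group("cid"):
        raise ReactionParseError(f"{rxn_id}: malformed token '{term.strip()}'")
    coef = float(m.group("coef")) if m.group("coef") else 1.0
    comp = m.group("comp") or default_comp
    if comp not in COMPARTMENTS:
        raise ReactionParseError(f"{rxn_id}: unknown compartment tag '{comp}'")
    return coef, Metabolite(m.group("cid"), comp)


def _parse_side(side: str, default_comp: str, rxn_id: str) -> List[Tuple[float, Metabolite]]:
    side = side.strip()
    if not side:
        return []
    return [_parse_term(t, default_comp, rxn_id) for t in side.split("+")]


def parse_reaction_equation(
    equation: str,
    rxn_id: str = "R",
    default_max: float = DEFAULT_MAX_FLUX,
    **annotations,
) -> Reaction:
    """Parse a KEGG-dialect equation string into a :class:`Reaction`.

    ``-->`` yields bounds ``[0, default_max]``; ``<-->`` yields
    ``[-default_max, default_max]``.  A single side may be empty only for
    boundary reactions (one metabolite total), which is how exchange and
    sink reactions are written (``[e]: C00185 <-->``).  Reactions whose net
    stoichiometry cancels to zero are rejected as degenerate.
    """
    s = equation.strip()
    default_comp = "c"
    pm = _PREFIX_RE.match(s)
    if pm:
        comp = pm.group("comp")
        if comp not in COMPARTMENTS:
            raise ReactionParseError(f"{rxn_id}: unknown compartment tag '{comp}'")
        default_comp = comp
        s = s[pm.end():]

    arrows = list(_ARROW_RE.finditer(s))
    if len(arrows) != 1:
        raise ReactionParseError(f"{rxn_id}: expected exactly one reaction arrow in '{equation}'")
    arrow = arrows[0]
    reversible = arrow.group(0).lstrip().startswith("<")
    lhs, rhs = s[: arrow.start()], s[arrow.end():]

    terms = [(-c, m) for c, m in _parse_side(lhs, default_comp, rxn_id)]
    terms += _parse_side(rhs, default_comp, rxn_id)
    if not terms:
        raise ReactionParseError(f"{rxn_id}: both sides of the equation are empty")

    stoich: Dict[Metabolite, float] = {}
    for coef, met in terms:
        stoich[met] = stoich.get(met, 0.0) + coef
    stoich = {m: c for m, c in stoich.items() if abs(c) > 1e-12}
    if not stoich:
        raise ReactionParseError(f"{rxn_id}: degenerate reaction (net stoichiometry is zero)")
    if (not lhs.strip() or not rhs.strip()) and len(stoich) > 1:
        raise ReactionParseError(
            f"{rxn_id}: empty side in a multi-metabolite equation '{equation}'"
        )

    lb = -default_max if reversible else 0.0
    return Reaction(
        rxn_id=rxn_id,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=default_max,
        **annotations,
    )


def _fmt_coef(x: float) -> str:
    return f"{x:.10g}"


def format_equation(rxn: Reaction) -> str:
    """Serialize a reaction back to the KEGG dialect (parse round-trips)."""
    comps = {m.compartment for m in rxn.stoichiometry}
    prefix = f"[{next(iter(comps))}]: " if len(comps) == 1 else ""
    tag = len(comps) > 1

    def side(items: Mapping[Metabolite, float]) -> str:
        parts = []
        for met in sorted(items, key=lambda m: m.key):
            coef = abs(items[met])
            token = met.key if tag else met.kegg_id
            parts.append(token if coef == 1 else f"{_fmt_coef(coef)} {token}")
        return " + ".join(parts)

    arrow = "<-->" if rxn.reversible else "-->"
    return f"{prefix}{side(rxn.reactants)} {arrow} {side(rxn.products)}".strip()


class MetabolicModel:
    """An ordered collection of reactions with a designated biomass objective."""

    def __init__(
        self,
        model_id: str = "model",
        reactions: Iterable[Reaction] = (),
        biomass_id: Optional[str] = None,
    ) -> None:
        self.model_id = model_id
        self._reactions: Dict[str, Reaction] = {}
        for rxn in reactions:
            self.add_reaction(rxn)
        self.biomass_id = biomass_id

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._reactions)

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self._reactions

    def __iter__(self):
        return iter(self._reactions.values())

    def __getitem__(self, rxn_id: str) -> Reaction:
        return self._reactions[rxn_id]

    @property
    def reactions(self) -> List[Reaction]:
        return list(self._reactions.values())

    @property
    def reaction_ids(self) -> List[str]:
        return list(self._reactions)

    @property
    def metabolites(self) -> List[Metabolite]:
        seen: Dict[str, Metabolite] = {}
        for rxn in self:
            for met in rxn.stoichiometry:
                seen.setdefault(met.key, met)
        return [seen[k] for k in sorted(seen)]

    # -- editing ------------------------------------------------------------
    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.rxn_id in self._reactions:
            raise ModelValidationError(f"duplicate reaction id '{rxn.rxn_id}'")
        self._reactions[rxn.rxn_id] = rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        return self._reactions.pop(rxn_id)

    def copy(self, model_id: Optional[str] = None) -> "MetabolicModel":
        return MetabolicModel(
            model_id or self.model_id,
            (r.copy() for r in self),
            biomass_id=self.biomass_id,
        )

    def biomass_reaction(self) -> Reaction:
        if self.biomass_id is None or self.biomass_id not in self._reactions:
            raise ModelValidationError(
                f"model '{self.model_id}' has no biomass reaction "
                f"(biomass_id={self.biomass_id!r})"
            )
        return self._reactions[self.biomass_id]

    def exchanges(self) -> List[Reaction]:
        return [r for r in self if r.is_exchange]

    def find_exchange(self, kegg_id: str) -> Optional[Reaction]:
        for rxn in self:
            if rxn.is_exchange and next(iter(rxn.stoichiometry)).kegg_id == kegg_id:
                return rxn
        return None

    def validate(self) -> None:
        if self.biomass_id is not None:
            self.biomass_reaction()
        for rxn in self:
            if not rxn.stoichiometry:
                raise ModelValidationError(f"{rxn.rxn_id}: empty stoichiometry")


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Dense S matrix with its deterministic row/column labelling."""

    matrix: np.ndarray
    metabolite_keys: Tuple[str, ...]
    reaction_ids: Tuple[str, ...]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.matrix.shape


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S (rows = metabolites, cols = reactions), both lexicographic."""
    met_keys = [m.key for m in model.metabolites]
    rxn_ids = sorted(model.reaction_ids)
    met_index = {k: i for i, k in enumerate(met_keys)}
    S = np.zeros((len(met_keys), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for met, coef in model[rid].stoichiometry.items():
            S[met_index[met.key], j] = coef
    return StoichiometricMatrix(S, tuple(met_keys), tuple(rxn_ids))


# ---------------------------------------------------------------------------
# Biomass objective
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomassEquation:
    """Growth pseudo-reaction stoichiometry over KEGG compound ids.

    Precursors (ATP, amino acids, nucleotides, cofactors) carry negative
    coefficients; hydrolysis products (ADP, phosphate, pyrophosphate, H+)
    positive ones.  The flux through this pseudo-reaction is reported as the
    growth rate in doublings/h.
    """

    stoichiometry: Mapping[str, float]

    @property
    def reactants(self) -> Dict[str, float]:
        return {k: v for k, v in self.stoichiometry.items() if v < 0}

    @property
    def products(self) -> Dict[str, float]:
        return {k: v for k, v in self.stoichiometry.items() if v > 0}

    def to_reaction(
        self, rxn_id: str = "BIOMASS", compartment: str = "c",
        upper_bound: float = DEFAULT_MAX_FLUX,
    ) -> Reaction:
        stoich = {
            Metabolite(cid, compartment): coef
            for cid, coef in self.stoichiometry.items()
        }
        return Reaction(rxn_id, stoich, 0.0, upper_bound, subsystem="Biomass")


_GLUED_TERM = re.compile(
    r"^(?P<coef>\d+(?:\.\d+)?)(?P<cid>C\d{5})$"
)


def biomass_equation_fixture() -> BiomassEquation:
    """The packaged biomass equation used for all growth simulations.

    Coefficients are transcribed verbatim from the source stoichiometry
    (glued ``coefCxxxxx`` terms are split at the first C-number), including
    its idiosyncrasies: one compound listed out of numeric order and one
    coefficient (C00059, 0.00780931) differing in the last digit from the
    recurring trace value 0.00780937.  No mass/charge rebalancing is applied.
    """
    text = (
        resources.files("proteogem.data").joinpath("biomass_equation.txt").read_text()
    ).strip()
    lhs, rhs = text.split("-->")
    stoich: Dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, +1.0)):
        for term in side.split("+"):
            m = _GLUED_TERM.match(term.strip())
            if not m:
                raise ReactionParseError(f"bad biomass term '{term}'")
            stoich[m.group("cid")] = sign * float(m.group("coef"))
    return BiomassEquation(stoich)


def make_biomass_reaction(rxn_id: str = "BIOMASS") -> Reaction:
    """Biomass pseudo-reaction built from the packaged equation."""
    return biomass_equation_fixture().to_reaction(rxn_id)


# ---------------------------------------------------------------------------
# Model I/O
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("rxn_id", "equation", "lb", "ub", "ec", "genes", "subsystem")


def write_model(model: MetabolicModel, path, dialect: str = "tsv") -> None:
    """Write a model as reaction-TSV (byte-stable) or SBML L3+fbc."""
    path = Path(path)
    if dialect == "sbml":
        _write_sbml(model, path)
        return
    if dialect != "tsv":
        raise ValueError(f"unknown dialect '{dialect}'")
    lines = ["\t".join(TSV_COLUMNS)]
    for rxn in model:
        lines.append(
            "\t".join(
                [
                    rxn.rxn_id,
                    format_equation(rxn),
                    _fmt_coef(rxn.lower_bound),
                    _fmt_coef(rxn.upper_bound),
                    ";".join(sorted(rxn.ec_numbers)),
                    ";".join(sorted(rxn.gene_ids)),
                    rxn.subsystem,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_model(
    path, dialect: str = "tsv", model_id: Optional[str] = None,
    biomass_id: Optional[str] = None,
) -> MetabolicModel:
    """Read a model from reaction-TSV or SBML.

    TSV rows violating the dialect (unknown column, duplicate id,
    unparseable equation) raise an error naming the offending row.  If
    ``biomass_id`` is omitted, a reaction literally named ``BIOMASS`` is
    adopted as the objective when present.
    """
    path = Path(path)
    if dialect == "sbml":
        return _read_sbml(path, model_id=model_id, biomass_id=biomass_id)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect '{dialect}'")
    lines = path.read_text().splitlines()
    if not lines:
        raise ModelValidationError(f"{path}: empty model file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != TSV_COLUMNS:
        unknown = set(header) - set(TSV_COLUMNS)
        raise ModelValidationError(
            f"{path}: unexpected columns {sorted(unknown) or list(header)}"
        )
    model = MetabolicModel(model_id or path.stem)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(TSV_COLUMNS):
            raise ModelValidationError(f"{path}:{lineno}: expected {len(TSV_COLUMNS)} columns")
        rid, eq, lb, ub, ec, genes, subsystem = cells
        try:
            rxn = parse_reaction_equation(eq, rid)
        except ReactionParseError as exc:
            raise ReactionParseError(f"{path}:{lineno}: {exc}") from exc
        rxn.lower_bound = float(lb)
        rxn.upper_bound = float(ub)
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(f"{path}:{lineno}: lb > ub")
        rxn.ec_numbers = frozenset(x for x in ec.split(";") if x)
        rxn.gene_ids = frozenset(x for x in genes.split(";") if x)
        rxn.subsystem = subsystem
        try:
            model.add_reaction(rxn)
        except ModelValidationError as exc:
            raise ModelValidationError(f"{path}:{lineno}: {exc}") from exc
    model.biomass_id = biomass_id or ("BIOMASS" if "BIOMASS" in model else None)
    return model


# -- SBML via cobrapy (format plumbing only) --------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML I/O and cross-checks)."""
    import cobra

    cm = cobra.Model(model.model_id)
    mets: Dict[str, "cobra.Metabolite"] = {}
    for met in model.metabolites:
        m = cobra.Metabolite(
            f"{met.kegg_id}_{met.compartment}", compartment=met.compartment,
            name=met.name or met.kegg_id,
        )
        mets[met.key] = m
    rxns = []
    for rxn in model:
        r = cobra.Reaction(rxn.rxn_id, lower_bound=rxn.lower_bound,
                           upper_bound=rxn.upper_bound)
        rxns.append((r, {mets[m.key]: c for m, c in rxn.stoichiometry.items()}))
    cm.add_reactions([r for r, _ in rxns])
    for r, stoich in rxns:
        r.add_metabolites(stoich)
    if model.biomass_id:
        cm.objective = model.biomass_id
    return cm


def from_cobra(cm, biomass_id: Optional[str] = None) -> MetabolicModel:
    model = MetabolicModel(cm.id or "model")
    for r in cm.reactions:
        stoich = {}
        for m, c in r.metabolites.items():
            comp = m.compartment if m.compartment in COMPARTMENTS else "c"
            cid = m.id[: -len(m.compartment) - 1] if m.id.endswith(f"_{m.compartment}") else m.id
            stoich[Metabolite(cid, comp)] = c
        model.add_reaction(
            Reaction(r.id, stoich, r.lower_bound, r.upper_bound,
                     gene_ids=frozenset(g.id for g in r.genes))
        )
    model.biomass_id = biomass_id or ("BIOMASS" if "BIOMASS" in model else None)
    return model


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def _read_sbml(path: Path, model_id=None, biomass_id=None) -> MetabolicModel:
    from cobra.io import read_sbml_model

    model = from_cobra(read_sbml_model(str(path)), biomass_id=biomass_id)
    if model_id:
        model.model_id = model_id
    return model
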