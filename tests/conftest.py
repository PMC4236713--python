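"""Shared fixtures: small hand-built networks and synthetic study data."""

from __future__ import annotations

import pytest

from proteogem.model_core import (
    DEFAULT_MAX_FLUX,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_reaction_equation,
)
from proteogem.synthetic import SyntheticSpec, generate_toy_model


def build_chain_model(uptake: float = 2.0, length: int = 2) -> MetabolicModel:
    """EX_A (lb -uptake) -> A -> ... -> biomass(A): a single bound-limited path."""
    model = MetabolicModel("chain")
    a = Metabolite("C90000", "c")
    model.add_reaction(Reaction("EX_A", {a: -1.0}, -uptake, DEFAULT_MAX_FLUX,
                                subsystem="Exchange"))
    prev = a
    for i in range(length - 1):
        nxt = Metabolite(f"C9000{i + 1}", "c")
        model.add_reaction(Reaction(f"STEP{i}", {prev: -1.0, nxt: 1.0},
                                    0.0, DEFAULT_MAX_FLUX))
        prev = nxt
    model.add_reaction(Reaction("BIOMASS", {prev: -1.0}, 0.0, DEFAULT_MAX_FLUX,
                                subsystem="Biomass"))
    model.biomass_id = "BIOMASS"
    return model


def build_glucose_model(uptake: float = 1.0) -> MetabolicModel:
    """Minimal glucose-consuming grower with a water exchange.

    Glucose (C00031) is taken up and converted straight to biomass; water
    (C00001) is exchangeable so that curated hydrolysis reactions can run.
    """
    model = MetabolicModel("glucose_toy")
    glc = Metabolite("C00031", "c")
    h2o = Metabolite("C00001", "c")
    model.add_reaction(Reaction("EX_C00031", {glc: -1.0}, -uptake,
                                DEFAULT_MAX_FLUX, subsystem="Exchange"))
    model.add_reaction(Reaction("EX_C00001", {h2o: -1.0}, -DEFAULT_MAX_FLUX,
                                DEFAULT_MAX_FLUX, subsystem="Exchange"))
    model.add_reaction(Reaction("BIOMASS", {glc: -1.0}, 0.0, DEFAULT_MAX_FLUX,
                                subsystem="Biomass"))
    model.biomass_id = "BIOMASS"
    return model


@pytest.fixture(scope="session")
def toy3():
    """Default 3-pathway synthetic model with its analytic optimum."""
    spec = SyntheticSpec()
    model, analytic = generate_toy_model(spec)
    return spec, model, analytic


@pytest.fixture()
def chain_model():
    return build_chain_model()


@pytest.fixture()
def glucose_model():
    return build_glucose_model()
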