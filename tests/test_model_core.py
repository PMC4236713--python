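"""Equation parsing, matrix assembly, biomass fixture, model I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteogem.model_core import (
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    ReactionParseError,
    biomass_equation_fixture,
    build_stoichiometric_matrix,
    format_equation,
    make_biomass_reaction,
    parse_reaction_equation,
    read_model,
    write_model,
)


class TestParseReactionEquation:
    @pytest.mark.parametrize(
        "equation, rxn_id, expected, reversible",
        [
            ("[c]: C00024 -- > C00332", "R00238", {"C00024": -1, "C00332": 1}, False),
            ("[c]: C00332 + C00024 -- > C00356", "R01978",
             {"C00332": -1, "C00024": -1, "C00356": 1}, False),
            ("[c]: C00185 + C00001 --> 2 C00031", "CELB",
             {"C00185": -1, "C00001": -1, "C00031": 2}, False),
            ("34.7964805C00001+40.1701382C00002-->40.0000000C00008", "BIO",
             {"C00001": -34.7964805, "C00002": -40.1701382, "C00008": 40.0}, False),
            ("[c]: C00418 <--> C01107", "R", {"C00418": -1, "C01107": 1}, True),
            ("[e]: C00185 <-->", "EX", {"C00185": -1}, True),
        ],
    )
    def test_stoichiometry_and_direction(self, equation, rxn_id, expected, reversible):
        rxn = parse_reaction_equation(equation, rxn_id)
        assert {m.kegg_id: c for m, c in rxn.stoichiometry.items()} == pytest.approx(expected)
        assert rxn.reversible is reversible

    def test_arrow_sets_default_bounds(self):
        fwd = parse_reaction_equation("[c]: C00024 --> C00332", "R")
        rev = parse_reaction_equation("[c]: C00024 <--> C00332", "R")
        assert (fwd.lower_bound, fwd.upper_bound) == (0.0, 1000.0)
        assert (rev.lower_bound, rev.upper_bound) == (-1000.0, 1000.0)

    def test_compartment_tags(self):
        rxn = parse_reaction_equation("C00031[e] --> C00031[c]", "TRANS")
        comps = {m.compartment for m in rxn.stoichiometry}
        assert comps == {"c", "e"}

    @pytest.mark.parametrize(
        "equation, fragment",
        [
            ("[c]: C00001 <--> C00001", "degenerate"),
            ("[x]: C00001 --> C00002", "compartment"),
            ("[c]: C00001 + --> C00002", "malformed"),
            ("[c]: -->", "empty"),
            ("[c]: C00001 + C00002 -->", "empty side"),
            ("[c]: C00001 --> C00002 --> C00003", "arrow"),
        ],
    )
    def test_malformed_equations_rejected(self, equation, fragment):
        with pytest.raises(ReactionParseError, match=fragment):
            parse_reaction_equation(equation, "BAD")

    def test_exchange_flag_single_metabolite(self):
        ex = parse_reaction_equation("[e]: C00185 <-->", "EX")
        assert ex.is_exchange
        core = parse_reaction_equation("[c]: C00024 --> C00332", "R")
        assert not core.is_exchange

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        coefs=st.lists(
            st.floats(0.01, 50, allow_nan=False).map(lambda x: round(x, 6)),
            min_size=2, max_size=6,
        ),
        reversible=st.booleans(),
    )
    def test_format_parse_round_trip(self, coefs, reversible):
        """Serializing and re-parsing preserves signed stoichiometry and bounds."""
        mets = [Metabolite(f"C{10000 + i:05d}", "c") for i in range(len(coefs))]
        half = max(1, len(coefs) // 2)
        stoich = {m: -c for m, c in zip(mets[:half], coefs[:half])}
        stoich.update({m: c for m, c in zip(mets[half:], coefs[half:])})
        rxn = Reaction("R1", stoich, -1000.0 if reversible else 0.0, 1000.0)
        back = parse_reaction_equation(format_equation(rxn), "R1")
        assert {m.key: c for m, c in back.stoichiometry.items()} == pytest.approx(
            {m.key: c for m, c in rxn.stoichiometry.items()}
        )
        assert back.reversible == rxn.reversible


class TestStoichiometricMatrix:
    def test_single_reaction_matrix(self):
        rxn = parse_reaction_equation("[c]: C00001 --> C00002", "R1")
        sm = build_stoichiometric_matrix(MetabolicModel("m", [rxn]))
        assert sm.shape == (2, 1)
        assert sm.matrix[:, 0].tolist() == [-1.0, 1.0]
        assert sm.metabolite_keys == ("C00001[c]", "C00002[c]")

    def test_column_sums_match_reparsed_coefficients(self):
        """Matrix columns agree with an independent re-parse of each equation."""
        rng = np.random.default_rng(7)
        eqs = {}
        model = MetabolicModel("rand")
        for i in range(10):
            n_r, n_p = rng.integers(1, 3, size=2)
            subs = [f"{rng.integers(1, 4)} C{100 + i:05d}" for _ in range(n_r)]
            prods = [f"{rng.integers(1, 4)} C{200 + i:05d}" for _ in range(n_p)]
            eq = f"[c]: {' + '.join(subs)} --> {' + '.join(prods)}"
            eqs[f"R{i:02d}"] = eq
            model.add_reaction(parse_reaction_equation(eq, f"R{i:02d}"))
        sm = build_stoichiometric_matrix(model)
        for j, rid in enumerate(sm.reaction_ids):
            reparsed = parse_reaction_equation(eqs[rid], rid)
            expected = sum(reparsed.stoichiometry.values())
            assert sm.matrix[:, j].sum() == pytest.approx(expected)

    def test_reaction_order_only_permutes_columns(self):
        r1 = parse_reaction_equation("[c]: C00001 --> C00002", "A")
        r2 = parse_reaction_equation("[c]: C00002 --> C00003", "B")
        sm1 = build_stoichiometric_matrix(MetabolicModel("m", [r1, r2]))
        sm2 = build_stoichiometric_matrix(MetabolicModel("m", [r2, r1]))
        assert sm1.reaction_ids == sm2.reaction_ids
        assert np.array_equal(sm1.matrix, sm2.matrix)


class TestBiomassEquation:
    def test_spot_coefficients(self):
        be = biomass_equation_fixture()
        assert be.stoichiometry["C00002"] == -40.1701382  # ATP, reactant side
        assert be.stoichiometry["C00008"] == +40.0  # ADP, product side
        assert be.stoichiometry["C00059"] == -0.00780931  # the odd last digit
        assert be.stoichiometry["C00716"] == -0.20970184  # out-of-order entry

    def test_compound_count_and_sides(self):
        # 54 distinct compounds, frozen from an independent parse of the
        # equation string (49 reactants + 5 products)
        be = biomass_equation_fixture()
        assert len(be.stoichiometry) == 54
        assert len(be.reactants) == 49
        assert len(be.products) == 5

    def test_biomass_reaction_construction(self):
        rxn = make_biomass_reaction()
        assert rxn.rxn_id == "BIOMASS"
        assert not rxn.reversible
        assert len(rxn.stoichiometry) == 54


class TestModelIO:
    def _toy(self):
        model = MetabolicModel("io_toy")
        for rid, eq in [
            ("EX_A", "[e]: C00031 <-->"),
            ("T", "C00031[e] --> C00031[c]"),
            ("R1", "[c]: C00031 --> 2 C00022"),
            ("R2", "[c]: 0.5 C00022 <--> C00024"),
            ("BIOMASS", "[c]: C00024 -->"),
        ]:
            rxn = parse_reaction_equation(eq, rid)
            rxn.ec_numbers = frozenset({"1.1.1.1"}) if rid.startswith("R") else frozenset()
            rxn.gene_ids = frozenset({f"G_{rid}"}) if rid.startswith("R") else frozenset()
            rxn.subsystem = "Test"
            model.add_reaction(rxn)
        model.biomass_id = "BIOMASS"
        return model

    def test_tsv_round_trip_is_byte_stable(self, tmp_path):
        model = self._toy()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_model(model, p1)
        back = read_model(p1)
        write_model(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert back.biomass_id == "BIOMASS"
        assert sorted(back.reaction_ids) == sorted(model.reaction_ids)

    def test_duplicate_rxn_id_rejected_with_row(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "rxn_id\tequation\tlb\tub\tec\tgenes\tsubsystem\n"
            "R1\t[c]: C00001 --> C00002\t0\t1000\t\t\t\n"
            "R1\t[c]: C00002 --> C00003\t0\t1000\t\t\t\n"
        )
        with pytest.raises(ModelValidationError, match=r":3.*duplicate"):
            read_model(p)

    def test_unknown_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("rxn_id\tformula\tlb\tub\tec\tgenes\tsubsystem\nR\tx\t0\t1\t\t\t\n")
        with pytest.raises(ModelValidationError, match="column"):
            read_model(p)

    def test_sbml_round_trip_preserves_matrix(self, tmp_path):
        model = self._toy()
        path = tmp_path / "toy.xml"
        write_model(model, path, dialect="sbml")
        back = read_model(path, dialect="sbml")
        a = build_stoichiometric_matrix(model)
        b = build_stoichiometric_matrix(back)
        assert a.metabolite_keys == b.metabolite_keys
        assert a.reaction_ids == b.reaction_ids
        assert np.allclose(a.matrix, b.matrix)
        assert [back[r].lower_bound for r in a.reaction_ids] == [
            model[r].lower_bound for r in a.reaction_ids
        ]
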