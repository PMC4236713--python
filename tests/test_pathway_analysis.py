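"""Completeness scoring, model comparison, hubs, and TBB feasibility."""

import numpy as np
import pytest

from proteogem.fba import FluxResult, solve_fba
from proteogem.model_core import (
    DEFAULT_MAX_FLUX,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_reaction_equation,
)
from proteogem.pathway_analysis import (
    PathwayDefinition,
    add_tbb_pathway,
    compare_models,
    completeness_percent,
    hub_connectivity,
    load_completeness_reference,
    load_tbb_rows,
    pathway_completeness,
    presence_call,
    tbb_reactions,
    test_pathway_flux,
)


class TestCompleteness:
    @pytest.mark.parametrize(
        "count, reference, expected",
        [
            (13, 22, 59),  # TCA cycle, proteomics model
            (28, 45, 62),  # glycolysis, automated model
            (15, 22, 68),  # TCA cycle, automated model
            (13, 40, 33),  # half rounds away from zero, not to even
            (0, 10, 0),
        ],
    )
    def test_percent_rounding(self, count, reference, expected):
        assert completeness_percent(count, reference) == expected

    def test_every_published_cell_reproduced(self):
        """All 81 published completeness percentages follow from the counts."""
        rows = load_completeness_reference()
        assert len(rows) == 27
        for row in rows:
            for version in ("v1", "v2", "v3"):
                assert completeness_percent(
                    row[f"tfu_{version}_count"], row["reference_count"]
                ) == row[f"tfu_{version}_pct"], row["pathway"]

    def test_model_scoring_by_ec_and_id(self):
        model = MetabolicModel("m")
        for rid, eq, ec in [
            ("R00238", "[c]: C00024 --> C00332", "2.3.1.9"),
            ("R01978", "[c]: C00332 + C00024 --> C00356", "2.3.3.10"),
            ("X1", "[c]: C00001 --> C00002", "5.5.5.5"),
        ]:
            rxn = parse_reaction_equation(eq, rid)
            rxn.ec_numbers = frozenset([ec])
            model.add_reaction(rxn)
        pdef = PathwayDefinition("map00900", "TBB", 4,
                                 member_ecs=frozenset({"2.3.1.9"}),
                                 reaction_ids=frozenset({"R01978"}))
        count, pct = pathway_completeness(model, pdef)
        assert (count, pct) == (2, 50)

    def test_empty_model_scores_zero(self):
        pdef = PathwayDefinition("map", "p", 10, member_ecs=frozenset({"1.1.1.1"}))
        count, pct = pathway_completeness(MetabolicModel("empty"), pdef)
        assert (count, pct) == (0, 0)

    @pytest.mark.parametrize("percent, expected",
                             [(59, True), (19, False), (20, True), (0, False)])
    def test_presence_threshold_inclusive(self, percent, expected):
        assert presence_call(percent) is expected


class TestCompareModels:
    def _model_with(self, model_id, rxn_ids):
        model = MetabolicModel(model_id)
        for i, rid in enumerate(rxn_ids):
            model.add_reaction(parse_reaction_equation(
                f"[c]: C{i + 1:05d} --> C{i + 2:05d}", rid))
        return model

    def test_self_intersection_equals_size(self, toy3):
        _, toy, _ = toy3
        table = compare_models([toy, toy.copy("twin")])
        assert table["common_all"] == len(toy)
        assert table["exclusive"] == {"toy_seed0": 0, "twin": 0}

    def test_planted_overlaps_recovered(self):
        """Three models with constructed overlaps reproduce the planted counts."""
        ids_a = [f"R{i:05d}" for i in range(10)]
        ids_b = [f"R{i:05d}" for i in range(5, 17)]
        ids_c = [f"R{i:05d}" for i in range(8, 20)]
        a = self._model_with("a", ids_a)
        b = self._model_with("b", ids_b)
        c = self._model_with("c", ids_c)
        table = compare_models([a, b, c])
        assert table["pairwise"][("a", "b")] == 5
        assert table["pairwise"][("b", "c")] == 9
        assert table["pairwise"][("a", "c")] == 2
        assert table["common_all"] == 2
        assert table["exclusive"] == {"a": 5, "b": 0, "c": 3}

    def test_permutation_invariant(self):
        a = self._model_with("a", ["R00001", "R00002"])
        b = self._model_with("b", ["R00002", "R00003"])
        t1 = compare_models([a, b])
        t2 = compare_models([b, a])
        assert t1["common_all"] == t2["common_all"]
        assert t1["pairwise"][("a", "b")] == t2["pairwise"][("b", "a")]

    def test_stoichiometry_hash_matches_across_id_schemes(self):
        """Identical reactions under different non-KEGG ids still intersect."""
        m1 = MetabolicModel("m1", [parse_reaction_equation(
            "[c]: C00031 --> 2 C00022", "glycolysis_lump")])
        m2 = MetabolicModel("m2", [parse_reaction_equation(
            "[c]: C00031 --> 2 C00022", "GLYC")])
        assert compare_models([m1, m2])["common_all"] == 1


class TestHubConnectivity:
    def _hub_model(self):
        model = MetabolicModel("hubs")
        pyr, accoa, akg = (Metabolite(c, "c") for c in ("C00022", "C00024", "C00026"))
        other = Metabolite("C00999", "c")
        model.add_reaction(Reaction("R1", {pyr: -1.0, accoa: 1.0}, 0, 1000))
        model.add_reaction(Reaction("R2", {accoa: -1.0, akg: 1.0}, 0, 1000))
        model.add_reaction(Reaction("R3", {akg: -1.0, other: 1.0}, 0, 1000))
        model.add_reaction(Reaction("R4", {other: -1.0, pyr: 1.0}, 0, 1000))
        return model

    def test_zero_flux_gives_zero_counts(self):
        model = self._hub_model()
        flux = FluxResult(0.0, {r: 0.0 for r in model.reaction_ids}, "optimal")
        per_hub, union = hub_connectivity(model, flux)
        assert union == 0 and all(v == 0 for v in per_hub.values())

    def test_counts_match_hand_enumeration(self):
        model = self._hub_model()
        flux = FluxResult(0.0, {"R1": 5.0, "R2": 5.0, "R3": 0.001, "R4": 0.0},
                          "optimal")
        per_hub, union = hub_connectivity(model, flux)
        assert per_hub["C00022"] == 1  # R1 only (R4 has zero flux)
        assert per_hub["C00024"] == 2  # R1 and R2
        assert per_hub["C00026"] == 1  # R2 (R3 below threshold)
        assert union == 2  # {R1, R2}, deduplicated

    def test_union_deduplicates_shared_reactions(self):
        model = self._hub_model()
        flux = FluxResult(0.0, {"R1": 5.0, "R2": 5.0, "R3": 5.0, "R4": 5.0},
                          "optimal")
        per_hub, union = hub_connectivity(model, flux)
        assert union < sum(per_hub.values())


class TestTbb:
    # stoichiometries as published for the curated TBB set
    EXPECTED = {
        "R00238": {"C00024": -1, "C00332": 1},
        "R01978": {"C00332": -1, "C00024": -1, "C00356": 1},
        "R02082": {"C00356": -1, "C00418": 1},
        "R02245": {"C00418": -1, "C01107": 1},
        "R03245": {"C01107": -1, "C01143": 1},
        "R01121": {"C01143": -1, "C00129": 1},
        "R01123": {"C00129": -1, "C00235": 1},
        "R05636": {"C00118": -1, "C00022": -1, "C11437": 1},
        "R05688": {"C11437": -1, "C11434": 1},
        "R05633": {"C11434": -1, "C11435": 1},
        "R05634": {"C11435": -1, "C11436": 1},
        "R05637": {"C11436": -1, "C11453": 1},
        "R08689": {"C11453": -1, "C11811": 1},
        "R05884": {"C11811": -1, "C00129": 1},
        "R08209": {"C11811": -1, "C00129": 1},
    }

    def test_sixteen_rows_fifteen_unique(self):
        assert len(load_tbb_rows()) == 16
        rxns = tbb_reactions()
        assert len(rxns) == 15
        ids = [r.rxn_id for r in rxns]
        assert ids.count("R01123") == 1

    def test_published_stoichiometries(self):
        for rxn in tbb_reactions():
            got = {m.kegg_id: c for m, c in rxn.stoichiometry.items()}
            assert got == pytest.approx(self.EXPECTED[rxn.rxn_id]), rxn.rxn_id

    def test_merge_into_empty_and_existing_model(self):
        empty = MetabolicModel("empty_base")
        merged, report = add_tbb_pathway(empty)
        assert len(report["added"]) == 15
        assert set(report["missing_precursors"]) == {"C00022", "C00024", "C00118"}
        # a model already holding R00238 gains no duplicate
        base = MetabolicModel("has238",
                              [parse_reaction_equation("[c]: C00024 --> C00332",
                                                       "R00238")])
        merged2, report2 = add_tbb_pathway(base)
        assert "R00238" in report2["skipped"]
        assert len(merged2) == 15

    def test_mevalonate_route_carries_equal_flux_to_ipp(self):
        """With acetyl-CoA supplied and IPP drained, the linear mevalonate
        route carries one equal flux while the IPP isomerase can stay idle."""
        base = MetabolicModel("central")
        ex = parse_reaction_equation("[c]: C00024 <-->", "EX_ACCOA")
        ex.lower_bound = -1.0
        base.add_reaction(ex)
        merged, _ = add_tbb_pathway(base)
        feasible, res = test_pathway_flux(merged, "C00129")
        assert feasible
        route = ["R00238", "R01978", "R02082", "R02245", "R03245", "R01121"]
        fluxes = [res.fluxes[r] for r in route]
        assert all(f == pytest.approx(0.5, abs=1e-9) for f in fluxes)
        assert res.fluxes["R01123"] == pytest.approx(0.0, abs=1e-9)

    def test_unproducible_target_is_infeasible(self):
        merged, _ = add_tbb_pathway(MetabolicModel("empty"))
        feasible, res = test_pathway_flux(merged, "C00129")
        assert not feasible
        assert res.objective == pytest.approx(0.0, abs=1e-9)

    def test_feasibility_monotone_in_min_flux(self):
        base = MetabolicModel("central")
        ex = parse_reaction_equation("[c]: C00024 <-->", "EX_ACCOA")
        ex.lower_bound = -1.0
        base.add_reaction(ex)
        merged, _ = add_tbb_pathway(base)
        low, _ = test_pathway_flux(merged, "C00129", min_flux=0.1)
        high, _ = test_pathway_flux(merged, "C00129", min_flux=10.0)
        assert low and not high

    def test_missing_target_raises(self):
        with pytest.raises(ValueError, match="not in model"):
            test_pathway_flux(MetabolicModel("empty"), "C00129")
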