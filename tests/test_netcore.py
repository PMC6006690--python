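import math

import pytest

from gapfillkit import (
    Direction,
    DirectionWarning,
    MetaboliteSpec,
    MetabolicModel,
    ModelCondition,
    ModelFormatError,
    ModelValidationError,
    ReactionSpec,
    augmented,
    build_matrix,
    format_equation,
    parse_equation,
    read_condition,
    read_model,
    write_condition,
    write_model,
)

from conftest import mk_model


class TestEquationGrammar:
    @pytest.mark.parametrize(
        "text,stoich,reversible",
        [
            ("A -> B", {"A": -1.0, "B": 1.0}, False),
            ("A + B -> C", {"A": -1.0, "B": -1.0, "C": 1.0}, False),
            ("2 A -> 3 B", {"A": -2.0, "B": 3.0}, False),
            ("A <-> B", {"A": -1.0, "B": 1.0}, True),
            ("0.5 A + B -> C", {"A": -0.5, "B": -1.0, "C": 1.0}, False),
            ("FARNESYL-PP + 8 IPP -> UPP + 8 PPI",
             {"FARNESYL-PP": -1.0, "IPP": -8.0, "UPP": 1.0, "PPI": 8.0}, False),
        ],
    )
    def test_parse(self, text, stoich, reversible):
        got, rev = parse_equation(text)
        assert got == stoich and rev == reversible

    def test_no_arrow_rejected(self):
        with pytest.raises(ModelFormatError, match="arrow"):
            parse_equation("A + B")

    def test_cancellation_drops_zero_terms(self):
        stoich, _ = parse_equation("A + B -> A + C")
        assert stoich == {"B": -1.0, "C": 1.0}

    @pytest.mark.parametrize("direction", list(Direction))
    def test_format_parse_roundtrip(self, direction):
        rxn = ReactionSpec("R", {"A": -2.0, "B": -1.0, "C": 3.0}, direction)
        stoich, rev = parse_equation(format_equation(rxn))
        assert stoich == dict(rxn.stoichiometry)
        assert rev == (direction is Direction.REVERSIBLE)


class TestSpecInvariants:
    def test_one_sided_reaction_rejected(self):
        with pytest.raises(ModelValidationError, match="consume and produce"):
            ReactionSpec("R", {"A": -1.0}, Direction.L2R)

    def test_exchange_prefix_exempt(self):
        ReactionSpec("DM_A", {"A": -1.0}, Direction.L2R)  # no raise

    def test_duplicate_reaction_id_rejected(self):
        r = ReactionSpec("R", {"A": -1, "B": 1}, Direction.L2R)
        with pytest.raises(ModelValidationError, match="duplicate"):
            MetabolicModel([MetaboliteSpec("A"), MetaboliteSpec("B")], [r, r])

    def test_dangling_metabolite_rejected(self):
        r = ReactionSpec("R", {"A": -1, "B": 1}, Direction.L2R)
        with pytest.raises(ModelValidationError, match="unknown metabolites"):
            MetabolicModel([MetaboliteSpec("A")], [r])

    def test_condition_reference_checked(self):
        with pytest.raises(ModelValidationError, match="condition references"):
            MetabolicModel(
                [MetaboliteSpec("A")],
                [],
                ModelCondition([("A", 10.0)], [], [("Z", 1.0)]),
            )

    def test_negative_uptake_rejected(self):
        with pytest.raises(ModelValidationError, match="negative uptake"):
            ModelCondition([("A", -1.0)], [], [])


class TestTsvRoundTrip:
    def test_toy3_fixture_counts(self, tmp_path):
        p = tmp_path / "toy3.tsv"
        p.write_text(
            "id\tequation\tdirection\tin_taxon\tis_polymer\tgene_assoc\n"
            "R1\tA -> B\tL2R\ttrue\tfalse\ttrue\n"
        )
        cond = tmp_path / "cond.txt"
        cond.write_text("NUTRIENTS\nA 10\nBIOMASS\nZ\n")
        model = read_model(p, "tsv", condition=cond)
        assert len(model.reactions) == 1
        assert len(model.metabolites) == 3  # A, B plus condition-declared Z
        assert model.reactions["R1"].direction is Direction.L2R

    def test_round_trip_identity(self, tmp_path, toy3):
        rxns = [
            ReactionSpec("R1", {"A": -1, "B": 2}, Direction.L2R, gene_associated=True),
            ReactionSpec("R2", {"B": -1, "C": 1}, Direction.R2L, in_taxonomic_range=False),
            ReactionSpec("R3", {"C": -2.5, "D": 1}, Direction.REVERSIBLE,
                         is_polymerization=True),
        ]
        model = mk_model(rxns, nutrients=[("A", 10.0)], biomass=[("D", 1.0)])
        p = tmp_path / "m.tsv"
        write_model(model, p, "tsv")
        back = read_model(p, "tsv", condition=model.condition)
        assert back.reactions == model.reactions
        assert set(back.metabolites) == set(model.metabolites)

    def test_empty_direction_column_warns_reversible(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text("R9\tA -> B\t\tfalse\tfalse\tfalse\n")
        with pytest.warns(DirectionWarning):
            model = read_model(p, "tsv")
        assert model.reactions["R9"].direction is Direction.REVERSIBLE

    def test_reversible_arrow_needs_no_warning(self, tmp_path, recwarn):
        p = tmp_path / "one.tsv"
        p.write_text("R9\tA <-> B\t\tfalse\tfalse\tfalse\n")
        model = read_model(p, "tsv")
        assert model.reactions["R9"].direction is Direction.REVERSIBLE
        assert not [w for w in recwarn if issubclass(w.category, DirectionWarning)]

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("R1\tA -> B\tL2R\ttrue\tfalse\ttrue\nR2\tA B\tL2R\t\t\t\n")
        with pytest.raises(ModelFormatError, match=r"bad\.tsv:2"):
            read_model(p, "tsv")

    def test_empty_model(self, tmp_path):
        model = MetabolicModel([], [])
        p = tmp_path / "empty.tsv"
        write_model(model, p, "tsv")
        assert read_model(p, "tsv").reactions == {}

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_model("/nonexistent/path.tsv", "tsv")


class TestSbmlRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        rxns = [
            ReactionSpec("R1", {"A": -1.0, "B": 2.0}, Direction.L2R, gene_associated=True),
            ReactionSpec("R2", {"B": -1.0, "C": 1.0}, Direction.R2L,
                         in_taxonomic_range=False),
            ReactionSpec("R3", {"C": -1.0, "D": 1.0}, Direction.REVERSIBLE,
                         is_polymerization=True),
        ]
        model = mk_model(rxns, nutrients=[("A", 10.0)], biomass=[("D", 1.0)])
        p = tmp_path / "m.xml"
        write_model(model, p, "sbml")
        back = read_model(p, "sbml", condition=model.condition)
        assert back.reactions == model.reactions

    def test_reversible_reaction_encodes_negative_lower_bound(self, tmp_path):
        model = mk_model(
            [ReactionSpec("R1", {"A": -1.0, "B": 1.0}, Direction.REVERSIBLE)],
            nutrients=[("A", 10.0)],
            biomass=[("B", 1.0)],
        )
        p = tmp_path / "m.xml"
        write_model(model, p, "sbml")
        text = p.read_text()
        assert "-3000" in text  # reversible lower bound < 0
        back = read_model(p, "sbml")
        assert back.reactions["R1"].direction is Direction.REVERSIBLE


class TestConditionFile:
    def test_round_trip(self, tmp_path):
        cond = ModelCondition(
            [("GLC", 10.0), ("AMMONIUM", 5.0)], ["CO2"], [("ATP", 2.0), ("GLY", 1.0)]
        )
        p = tmp_path / "cond.txt"
        write_condition(cond, p)
        assert read_condition(p) == cond

    def test_default_uptake_and_coefficient(self, tmp_path):
        p = tmp_path / "cond.txt"
        p.write_text("NUTRIENTS\nGLC\nBIOMASS\nATP\n")
        cond = read_condition(p)
        assert cond.nutrients == (("GLC", 10.0),)
        assert cond.biomass_metabolites == (("ATP", 1.0),)

    def test_entry_before_section_rejected(self, tmp_path):
        p = tmp_path / "cond.txt"
        p.write_text("GLC 10\n")
        with pytest.raises(ModelFormatError, match="section"):
            read_condition(p)


class TestStoichiometricMatrix:
    def test_toy3_columns(self, toy3):
        smat = build_matrix(toy3)
        names = [c.name for c in smat.columns]
        assert names == ["R1__fwd", "EX_A__uptake", "DM_biomass"]
        assert smat.matrix.shape == (3, 3)

    def test_reversible_split_negates(self):
        model = mk_model(
            [ReactionSpec("R1", {"A": -1.0, "B": 1.0}, Direction.REVERSIBLE)],
            nutrients=[("A", 10.0)],
            biomass=[("B", 1.0)],
        )
        smat = build_matrix(model)
        dense = smat.matrix.toarray()
        i_f = smat.column_index["R1__fwd"]
        i_b = smat.column_index["R1__bwd"]
        assert (dense[:, i_f] == -dense[:, i_b]).all()

    def test_column_count_invariant(self):
        rxns = [
            ReactionSpec("R1", {"A": -1, "B": 1}, Direction.L2R),
            ReactionSpec("R2", {"B": -1, "C": 1}, Direction.REVERSIBLE),
            ReactionSpec("R3", {"C": -1, "D": 1}, Direction.R2L),
        ]
        model = mk_model(
            rxns, nutrients=[("A", 10.0)], biomass=[("D", 1.0)], secretions=["C"]
        )
        smat = build_matrix(model)
        # 2 irreversible + 2x1 reversible + (1 uptake + 1 export + 1 demand)
        assert len(smat.columns) == 2 + 2 + 3

    def test_internal_columns_match_stoichiometry(self, recycling):
        smat = build_matrix(recycling)
        dense = smat.matrix.toarray()
        for col_i, col in enumerate(smat.columns):
            if col.kind != "forward":
                continue
            rxn = recycling.reactions[col.reaction_id]
            for row_i, met in enumerate(smat.rows):
                assert dense[row_i, col_i] == rxn.stoichiometry.get(met, 0.0)

    def test_uptake_bound_propagates(self, toy3):
        smat = build_matrix(toy3)
        up = smat.columns[smat.column_index["EX_A__uptake"]]
        assert up.ub == 10.0

    def test_no_nutrients_no_uptake_columns(self):
        model = mk_model(
            [ReactionSpec("R1", {"A": -1, "B": 1}, Direction.L2R)],
            nutrients=[],
            biomass=[("B", 1.0)],
        )
        smat = build_matrix(model)
        assert not [c for c in smat.columns if c.kind == "uptake"]


class TestAugmented:
    def test_adds_missing_metabolites(self, toy3):
        new = ReactionSpec("CX", {"Q1": -1.0, "Q2": 1.0}, Direction.L2R)
        bigger = augmented(toy3, [new])
        assert {"Q1", "Q2"} <= set(bigger.metabolites)

    def test_relax_makes_reversible(self, toy3):
        relaxed = augmented(toy3, [], relax_directions=["R1"])
        assert relaxed.reactions["R1"].direction is Direction.REVERSIBLE

    def test_clashing_id_rejected(self, toy3):
        dup = ReactionSpec("R1", {"A": -1, "B": 1}, Direction.L2R)
        with pytest.raises(ModelValidationError, match="already in model"):
            augmented(toy3, [dup])
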