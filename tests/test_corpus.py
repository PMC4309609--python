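"""Fixture integrity, domain-type invariants and the substrate keyword map."""

import numpy as np
import pandas as pd
import pytest

from cazstarve.corpus import (
    CONDITION_LABELS,
    CONDITIONS,
    CompositionSample,
    ExpressionMatrix,
    GeneRecord,
    GrowthCurve,
    assign_substrate_class,
    load_composition_fixture,
    load_proteome_fixture,
    records_by_orf,
    write_composition_csv,
)

# Every ORF named in the narrative discussion of the expression results.
ORFS_NAMED_IN_TEXT = [
    "An02g07020", "An02g11720", "An01g12550", "An01g06500", "An07g07700",
    "An04g08730", "An14g04240", "An11g03120", "An02g10550", "An12g01850",
    "An01g10540", "An01g03750", "An07g03340", "An09g05730", "An14g05370",
    "An02g13580", "An09g05920", "An15g07370", "An06g01530", "An02g00850",
    "An02g09050", "An06g01140", "An15g02350", "An14g00660", "An16g02850",
    "An10g00400", "An01g12450", "An16g07040", "An08g09030", "An14g02180",
    "An02g07770", "An13g00400", "An04g09890", "An07g07530", "An07g01160",
    "An03g05530", "An16g06800", "An15g05370", "An02g04900", "An02g10310",
    "An14g04190", "An02g05260", "An09g06400", "An08g09610", "An18g00730",
    "An09g02240", "An01g03090", "An08g08370", "An16g02910", "An09g02160",
    "An09g01190", "An14g01770", "An03g00500", "An07g08640",
]


class TestExpressionFixture:
    def test_design_shape(self, expression_matrix):
        assert len(CONDITIONS) == 12
        assert list(expression_matrix.df.columns) == list(CONDITION_LABELS)
        assert (expression_matrix.df.values >= 0).all()

    def test_printed_values_preserved(self, expression_matrix):
        # the chitinase cfcA row, wild-type block
        wt = [expression_matrix.value("An02g07020", "wt", t)
              for t in ("exp", "d1", "d3", "d6")]
        assert wt == [1.3, 69.6, 75.9, 83.9]

    def test_sections_and_annotations(self, gene_records):
        by_orf = records_by_orf(gene_records)
        aa11 = by_orf["An15g02350"]
        assert aa11.table1_section == "B"
        assert aa11.cazy_family == ("AA11",)
        section_c = [r for r in gene_records if r.table1_section == "C"]
        assert len(section_c) == 8

    def test_contains_every_orf_named_in_text(self, expression_matrix):
        missing = set(ORFS_NAMED_IN_TEXT) - set(expression_matrix.genes)
        assert not missing

    def test_regulator_rows_have_no_cazy_family(self, gene_records):
        by_orf = records_by_orf(gene_records)
        for orf in ("An01g10540", "An01g03750", "An07g03340", "An09g05730", "An14g05370"):
            assert not by_orf[orf].is_cazyme

    def test_section_a_substrate_classes_known(self, gene_records):
        for r in gene_records:
            if r.table1_section == "A":
                assert r.substrate_class != "unknown"

    def test_round_trip(self, expression_matrix, tmp_path):
        p = tmp_path / "expr.tsv"
        expression_matrix.to_tsv(p)
        again = ExpressionMatrix.from_tsv(p)
        pd.testing.assert_frame_equal(expression_matrix.df, again.df)


class TestProteomeFixture:
    def test_bin_examples(self, proteome_table):
        assert proteome_table.bin("An03g06550", "wt", 1, "exp") == 6  # GlaA
        cfcA = [proteome_table.bin("An02g07020", "wt", 1, t)
                for t in ("exp", "d1", "d3", "d6")]
        assert cfcA == [0, 2, 0, 0]

    def test_bins_in_range_and_hv_only_when_detected(self, proteome_table):
        assert proteome_table.bins.values.min() >= 0
        assert proteome_table.bins.values.max() <= 6
        assert not (
            proteome_table.high_variance.values & (proteome_table.bins.values == 0)
        ).any()

    def test_empty_table_is_valid(self, tmp_path):
        from cazstarve.corpus import PROTEOME_COLUMNS

        cols = (["orf"] + list(PROTEOME_COLUMNS)
                + [f"{c}_hv" for c in PROTEOME_COLUMNS]
                + ["sp", "gpi", "cazy_family", "name", "function"])
        p = tmp_path / "empty.tsv"
        p.write_text("\t".join(cols) + "\n")
        empty = load_proteome_fixture(p)
        assert len(empty.genes) == 0


class TestSubstrateClass:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("chitobiosidase, group A", "chitin"),
            ("putative endo-beta-1,4-xylosidases", "plant_polysaccharide"),
            ("putative alpha-1,6-mannanase", "mannan"),
            ("class 2 ER alpha-mannosidase", "mannan"),
            ("beta-1,3-glucanotransferase", "beta_glucan"),
            ("alpha-glucan synthase", "alpha_glucan"),
            ("endo-polygalacturonase", "pectin"),
            ("trehalose-6-phosphate phosphatase", "storage"),
            ("beta-N-acetylhexosaminidase", "chitin"),
            ("transcription factor, role in sporulation", "unknown"),
        ],
    )
    def test_keyword_mapping(self, text, expected):
        assert assign_substrate_class(text) == expected

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            assign_substrate_class("")

    def test_deterministic(self, gene_records):
        for r in gene_records:
            if r.function_text:
                assert assign_substrate_class(r.function_text) == assign_substrate_class(
                    r.function_text
                )


class TestOtherTypes:
    def test_orf_pattern_enforced(self):
        with pytest.raises(ValueError):
            GeneRecord(orf_id="An2g0702")

    def test_composition_fixture_sums(self):
        samples = load_composition_fixture()
        for s in samples:
            assert abs(sum(s.fractions.values()) - 100.0) <= 0.5

    def test_composition_round_trip(self, tmp_path):
        samples = load_composition_fixture()
        p = tmp_path / "comp.csv"
        write_composition_csv(samples, p)
        again = load_composition_fixture(p)
        assert again == samples

    def test_composition_sum_invariant_enforced(self):
        with pytest.raises(ValueError):
            CompositionSample(
                "wt", 0.0, 1,
                {"glucosamine": 50, "galactose": 30, "glucose": 30, "mannose": 10},
            )

    def test_growth_curve_invariants(self):
        with pytest.raises(ValueError):
            GrowthCurve("wt", 1, (0.0, 0.0), (1.0, 2.0))
        with pytest.raises(ValueError):
            GrowthCurve("wt", 1, (0.0, 1.0), (1.0, -2.0))
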