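"""Filter cascades, rankings, flaw taxonomy and category screens."""

import pandas as pd
import pytest

from cecmarkers import reference
from cecmarkers.expression import (ExpressionError, GeneAnnotation,
                                   matrix_from_arrays)
from cecmarkers.markers import (FilterCriteria, build_record,
                                classify_flaws, extract_gene_set,
                                rank_top_expressed, select_category,
                                stable_cec_filter, stroma_absent_filter)


def matrix_of(rows: dict):
    """gene -> (young, old, culture, stroma) RPMs."""
    return matrix_from_arrays(list(rows), reference.reference_metadata().sample_ids,
                              list(rows.values()), unit="rpm")


class TestRankTopExpressed:
    def test_most_expressed_young_gene_is_eno1(self, core_meta):
        matrix, _ = reference.load_top50_stable()
        assert rank_top_expressed(matrix, core_meta, "cec_young", 1) == ["ENO1"]

    def test_n_equal_to_table_size_is_a_permutation(self, core_meta):
        matrix, _ = reference.load_top50_stable()
        ranked = rank_top_expressed(matrix, core_meta, "cec_young",
                                    len(matrix.gene_ids))
        assert sorted(ranked) == sorted(matrix.gene_ids)

    def test_ties_break_alphabetically(self, core_meta):
        matrix = matrix_of({"ZZZ": [50, 1, 1, 1], "AAA": [50, 2, 2, 2],
                            "MMM": [60, 3, 3, 3]})
        assert rank_top_expressed(matrix, core_meta, "cec_young", 3) \
            == ["MMM", "AAA", "ZZZ"]

    def test_oversized_n_warns_and_returns_all(self, core_meta):
        matrix = matrix_of({"A": [1, 1, 1, 1]})
        with pytest.warns(UserWarning):
            assert rank_top_expressed(matrix, core_meta, "cec_young", 10) == ["A"]


class TestStableCecFilter:
    def test_reference_pass_and_fail_genes(self, core_meta):
        matrix = matrix_of({
            "SLC4A11": [2312, 2940, 366, 90],   # passes, fold 25.7
            "AQP1": [233, 172, 4, 506],          # culture 4 < 10 and 0.5x stroma
            "ID3": [834, 1744, 1337, 133],       # age fold 0.478 rounds to 0.5
        })
        kept = stable_cec_filter(matrix, core_meta)
        assert [r.gene_id for r in kept] == ["SLC4A11", "ID3"]
        assert kept[0].fold_young_stroma.display == "25.7"

    def test_age_window_is_inclusive_on_rounded_fold(self, core_meta):
        matrix = matrix_of({
            "EDGE_LO": [100, 205, 50, 10],   # 0.488 -> 0.5, inside
            "EDGE_HI": [205, 100, 50, 10],   # 2.05 -> 2.1, outside
            "EDGE_OK": [204, 100, 50, 10],   # 2.04 -> 2.0, inside
        })
        kept = {r.gene_id for r in stable_cec_filter(matrix, core_meta)}
        assert kept == {"EDGE_LO", "EDGE_OK"}

    def test_undefined_stroma_fold_counts_as_maximal_contrast(self, core_meta):
        matrix = matrix_of({"ZEROSTROMA": [100, 100, 100, 0]})
        assert len(stable_cec_filter(matrix, core_meta)) == 1

    def test_missing_class_is_an_error_naming_it(self):
        matrix = matrix_of({"A": [1, 1, 1, 1]})
        from cecmarkers.expression import metadata_from_records
        meta = metadata_from_records(
            [(s, s, 1_000_000) for s in matrix.sample_ids])
        meta.table.loc["stroma", "class_label"] = "other"
        with pytest.raises(ExpressionError, match="stroma"):
            stable_cec_filter(matrix, meta)

    def test_printed_fold_columns_take_precedence(self, core_meta):
        # rounded RPMs recompute to an age fold of 2.5, but the published
        # unrounded fold (2.0) keeps the gene
        matrix = matrix_of({"P4HA2": [572, 231, 603, 104]})
        assert stable_cec_filter(matrix, core_meta) == []
        overrides = pd.DataFrame({"fold_young_old": [2.0],
                                  "fold_young_stroma": [5.5]},
                                 index=["P4HA2"])
        kept = stable_cec_filter(matrix, core_meta, fold_overrides=overrides)
        assert [r.gene_id for r in kept] == ["P4HA2"]

    def test_idempotent_over_gene_subsets(self, core_meta):
        matrix, folds = reference.load_top50_stable()
        kept = stable_cec_filter(matrix, core_meta, fold_overrides=folds)
        sub = matrix.subset_genes([r.gene_id for r in kept])
        again = stable_cec_filter(sub, core_meta, fold_overrides=folds)
        assert [r.gene_id for r in again] == [r.gene_id for r in kept]


class TestStromaAbsentFilter:
    def test_reference_pass_and_fail(self, core_meta):
        matrix = matrix_of({
            "CYYR1": [94.39, 15.68, 10.14, 0.00],
            "SLC4A11": [2312, 2940, 366, 90],
        })
        kept = stroma_absent_filter(matrix, core_meta)
        assert [r.gene_id for r in kept] == ["CYYR1"]

    def test_every_bound_is_strict(self, core_meta):
        matrix = matrix_of({"BOUNDARY": [10, 10, 10, 1]})
        assert stroma_absent_filter(matrix, core_meta) == []

    def test_has_no_age_criterion(self, core_meta):
        """The absence screen keeps genes whose young/old ratio would fail the
        stable screen's two-fold window (as the published candidate list does
        for CYYR1, young/old 6.0)."""
        matrix = reference.load_stroma_absent()
        kept = {r.gene_id for r in stroma_absent_filter(matrix, core_meta)}
        assert "CYYR1" in kept
        stable = {r.gene_id for r in stable_cec_filter(matrix, core_meta)}
        assert "CYYR1" not in stable


class TestClassifyFlaws:
    def test_all_four_flaws(self, core_meta):
        ann = GeneAnnotation(specificity={"ZO-1": "ubiquitous"})
        record = build_record("ZO-1", {"cec_young": 49, "cec_old": 42,
                                       "cec_culture": 8, "stroma": 72})
        assert classify_flaws(record, ann).flaws == frozenset({
            "low_in_young", "absent_in_culture", "no_stroma_contrast",
            "nonspecific"})

    def test_nonspecific_only(self):
        ann = GeneAnnotation(specificity={"NCAD": "ubiquitous"})
        record = build_record("NCAD", {"cec_young": 129, "cec_old": 67,
                                       "cec_culture": 94, "stroma": 4})
        assert classify_flaws(record, ann).flaws == frozenset({"nonspecific"})

    def test_restricted_site_noted_without_flag(self):
        ann = GeneAnnotation(specificity={"COL8A2": "restricted:retina"})
        record = build_record("COL8A2", {"cec_young": 1821, "cec_old": 1743,
                                         "cec_culture": 859, "stroma": 107})
        flagged = classify_flaws(record, ann)
        assert flagged.flaws == frozenset()
        assert flagged.specificity_note == "retina"

    def test_zero_stroma_is_not_a_contrast_flaw(self):
        ann = GeneAnnotation()
        record = build_record("X", {"cec_young": 200, "cec_old": 150,
                                    "cec_culture": 50, "stroma": 0})
        assert "no_stroma_contrast" not in classify_flaws(record, ann).flaws

    def test_idempotent(self):
        ann = GeneAnnotation(specificity={"G": "ubiquitous"})
        record = build_record("G", {"cec_young": 1, "cec_old": 1,
                                    "cec_culture": 1, "stroma": 1})
        once = classify_flaws(record, ann)
        assert classify_flaws(once, ann).flaws == once.flaws


class TestSelectCategory:
    def test_unknown_category_lists_known_ones(self, core_meta):
        matrix, annotation = reference.load_study_composite()
        with pytest.raises(ExpressionError, match="cytokine_receptor"):
            select_category(matrix, core_meta, annotation, "kinase")

    def test_category_with_no_gene_in_matrix_is_empty(self, core_meta):
        matrix = matrix_of({"A": [100, 100, 100, 1]})
        annotation = GeneAnnotation(categories={"OTHER": {"transporter"}})
        assert select_category(matrix, core_meta, annotation,
                               "transporter") == []

    def test_failing_category_members_are_rejected(self, core_meta):
        matrix = matrix_of({
            "TGFBR3": [135, 130, 11, 44],
            "FAKE_RECEPTOR": [135, 130, 5, 44],   # silent in culture
        })
        annotation = GeneAnnotation(categories={
            "TGFBR3": {"cytokine_receptor"},
            "FAKE_RECEPTOR": {"cytokine_receptor"}})
        kept = select_category(matrix, core_meta, annotation,
                               "cytokine_receptor")
        assert [r.gene_id for r in kept] == ["TGFBR3"]

    def test_transporter_screen_top_gene(self, core_meta):
        matrix, annotation = reference.load_study_composite()
        kept = select_category(matrix, core_meta, annotation, "transporter")
        assert kept[0].gene_id == "SLC2A1"
        assert len(kept) == 43


class TestExtractGeneSet:
    def test_smad_family_ranked_by_young_expression(self, core_meta):
        matrix = reference.load_smads()
        records, missing = extract_gene_set(
            matrix, core_meta, [f"SMAD{i}" for i in range(1, 10)])
        assert records[0].gene_id == "SMAD3"
        assert records[0].rpm["cec_young"] == 180
        assert missing == ["SMAD8"]

    def test_singleton_list(self, core_meta):
        matrix = reference.load_smads()
        records, missing = extract_gene_set(matrix, core_meta, ["smad4"])
        assert len(records) == 1 and records[0].gene_id == "SMAD4"
        assert missing == []

    def test_empty_list_rejected(self, core_meta):
        with pytest.raises(ExpressionError):
            extract_gene_set(reference.load_smads(), core_meta, [])


def test_criteria_must_be_positive():
    with pytest.raises(ExpressionError):
        FilterCriteria(min_rpm_expressed=0)
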