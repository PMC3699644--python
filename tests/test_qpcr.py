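"""Comparative-Ct quantification and Welch group statistics."""

import numpy as np
import pandas as pd
import pytest

from cecmarkers.expression import ExpressionError
from cecmarkers.qpcr import (CtTable, delta_ct, group_stats, read_ct_long,
                             read_ct_wide, relative_expression,
                             significance_stars)


def ct_table(entries, housekeeping=("GAPDH",)):
    """entries: (assay, sample, replicate, ct) tuples."""
    frame = pd.DataFrame(entries,
                         columns=["assay_id", "sample_id", "replicate", "ct"])
    return CtTable(frame, frozenset(housekeeping))


def ddct_oracle(delta: dict, reference_sample: str) -> dict:
    """Independent brute-force 2^-ΔΔCt computation over all cells."""
    out = {}
    for (assay, sample), value in delta.items():
        out[(assay, sample)] = 100.0 * 2.0 ** -(value - delta[(assay,
                                                               reference_sample)])
    return out


class TestDeltaCt:
    def test_equal_to_housekeeping_gives_zero(self):
        table = ct_table([("G", "s1", 1, 20.0), ("GAPDH", "s1", 1, 20.0)])
        assert delta_ct(table).loc[("G", "s1"), "delta_ct"] == pytest.approx(0)

    def test_arithmetic_mean_over_housekeeping_trio(self):
        table = ct_table([("G", "s1", 1, 25.0), ("HK1", "s1", 1, 20.0),
                          ("HK2", "s1", 1, 22.0), ("HK3", "s1", 1, 24.0)],
                         housekeeping=("HK1", "HK2", "HK3"))
        assert delta_ct(table).loc[("G", "s1"), "delta_ct"] == pytest.approx(3.0)

    def test_single_housekeeping_reduces_to_pairwise_subtraction(self):
        table = ct_table([("G", "s1", 1, 27.5), ("GAPDH", "s1", 1, 21.0)])
        assert delta_ct(table).loc[("G", "s1"), "delta_ct"] == pytest.approx(6.5)

    def test_replicates_average_before_normalization(self):
        table = ct_table([("G", "s1", 1, 24.0), ("G", "s1", 2, 26.0),
                          ("GAPDH", "s1", 1, 20.0)])
        result = delta_ct(table)
        assert result.loc[("G", "s1"), "delta_ct"] == pytest.approx(5.0)
        assert result.loc[("G", "s1"), "sd_ct"] == pytest.approx(np.sqrt(2))

    def test_undetected_housekeeping_is_an_error_naming_sample(self):
        table = ct_table([("G", "s1", 1, 24.0), ("GAPDH", "s1", 1, np.nan)])
        with pytest.raises(ExpressionError, match="s1"):
            delta_ct(table)

    def test_housekeeping_must_cover_every_sample(self):
        with pytest.raises(ExpressionError, match="GAPDH"):
            ct_table([("G", "s1", 1, 24.0), ("G", "s2", 1, 25.0),
                      ("GAPDH", "s1", 1, 20.0)])


class TestRelativeExpression:
    def test_reference_sample_is_exactly_100(self):
        table = ct_table([("G", "ref", 1, 24.0), ("G", "other", 1, 23.0),
                          ("GAPDH", "ref", 1, 20.0),
                          ("GAPDH", "other", 1, 20.0)])
        rel = relative_expression(delta_ct(table), "ref")
        assert rel.loc[("G", "ref"), "value"] == 100.0
        assert rel.loc[("G", "other"), "value"] == pytest.approx(200.0)

    def test_randomized_table_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2013)
        assays = [f"A{i}" for i in range(6)]
        samples = [f"s{j}" for j in range(5)]
        entries = [("GAPDH", s, 1, 20.0) for s in samples]
        for a in assays:
            for s in samples:
                entries.append((a, s, 1, float(rng.uniform(18, 32))))
        table = ct_table(entries)
        deltas = delta_ct(table)
        rel = relative_expression(deltas, "s0")
        oracle = ddct_oracle(
            {idx: row["delta_ct"] for idx, row in deltas.iterrows()}, "s0")
        for (assay, sample), expected in oracle.items():
            assert rel.loc[(assay, sample), "value"] == pytest.approx(expected)

    def test_sample_level_ct_offsets_cancel(self):
        base = [("G", "s1", 1, 24.0), ("G", "s2", 1, 27.0),
                ("GAPDH", "s1", 1, 20.0), ("GAPDH", "s2", 1, 21.0)]
        shifted = [(a, s, r, ct + (3.0 if s == "s2" else 0.0))
                   for a, s, r, ct in base]
        rel_a = relative_expression(delta_ct(ct_table(base)), "s1")
        rel_b = relative_expression(delta_ct(ct_table(shifted)), "s1")
        pd.testing.assert_frame_equal(rel_a, rel_b)

    def test_one_cycle_less_doubles_expression(self):
        base = [("G", "s1", 1, 24.0), ("G", "s2", 1, 24.0),
                ("GAPDH", "s1", 1, 20.0), ("GAPDH", "s2", 1, 20.0)]
        doubled = [(a, s, r, ct - (1.0 if (a, s) == ("G", "s2") else 0.0))
                   for a, s, r, ct in base]
        rel_a = relative_expression(delta_ct(ct_table(base)), "s1")
        rel_b = relative_expression(delta_ct(ct_table(doubled)), "s1")
        assert rel_b.loc[("G", "s2"), "value"] == pytest.approx(
            2 * rel_a.loc[("G", "s2"), "value"])

    def test_undetected_assay_reports_zero_with_flag(self):
        table = ct_table([("G", "ref", 1, 24.0), ("G", "other", 1, np.nan),
                          ("GAPDH", "ref", 1, 20.0),
                          ("GAPDH", "other", 1, 20.0)])
        rel = relative_expression(delta_ct(table), "ref")
        row = rel.loc[("G", "other")]
        assert row["value"] == 0.0 and not row["detected"]

    def test_missing_reference_is_an_error_naming_assay(self):
        table = ct_table([("G", "ref", 1, np.nan), ("G", "other", 1, 24.0),
                          ("GAPDH", "ref", 1, 20.0),
                          ("GAPDH", "other", 1, 20.0)])
        with pytest.raises(ExpressionError, match="'G'"):
            relative_expression(delta_ct(table), "ref")


class TestGroupStats:
    def test_identical_groups(self):
        stats = group_stats([1, 2, 3], [1, 2, 3])
        assert stats.fold.value == pytest.approx(1.0)
        assert stats.p_value == pytest.approx(1.0)
        assert stats.stars == ""

    def test_published_mean_sd_form(self):
        # three-donor replicate summary prints as 495 +/- 54
        stats = group_stats([441, 549, 495], [1, 1, 1.5])
        assert round(stats.mean_a) == 495
        assert round(stats.sd_a) == 54

    @pytest.mark.parametrize("p,stars", [(0.009, "**"), (0.04, "*"), (0.2, "")])
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars

    def test_welch_matches_permutation_approximation(self):
        rng = np.random.default_rng(7)
        a = list(rng.normal(10, 2, size=6))
        b = list(rng.normal(13, 4, size=6))
        observed = group_stats(a, b)
        pooled = np.array(a + b)
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            pa, pb = perm[:6], perm[6:]
            se = np.sqrt(pa.var(ddof=1) / 6 + pb.var(ddof=1) / 6)
            t = (pa.mean() - pb.mean()) / se
            count += abs(t) >= abs(observed.t_statistic)
        perm_p = count / n_perm
        assert observed.p_value == pytest.approx(perm_p, abs=0.03)

    def test_degenerate_zero_variance(self):
        equal = group_stats([5, 5], [5, 5])
        assert equal.p_value == 1.0 and equal.degenerate
        different = group_stats([5, 5], [7, 7])
        assert different.p_value == 0.0 and different.degenerate

    def test_zero_denominator_fold_is_undefined(self):
        stats = group_stats([5, 6], [0, 0])
        assert stats.fold.display == "n/a"

    def test_group_size_validation(self):
        with pytest.raises(ExpressionError):
            group_stats([1.0], [2.0, 3.0])


class TestReaders:
    def test_long_reader_handles_nd_sentinel(self, tmp_path):
        path = tmp_path / "ct.tsv"
        path.write_text("assay_id\tsample_id\treplicate\tct\n"
                        "G\ts1\t1\t24.5\nG\ts2\t1\tND\n"
                        "GAPDH\ts1\t1\t20\nGAPDH\ts2\t1\t20\n")
        table = read_ct_long(path, housekeeping=("GAPDH",))
        assert np.isnan(
            table.data.query("assay_id=='G' and sample_id=='s2'")["ct"]).all()

    def test_wide_reader_groups_repeated_sample_columns(self, tmp_path):
        path = tmp_path / "wide.tsv"
        path.write_text("assay\ts1\ts1\ts2\ts2\n"
                        "G\t24.0\t24.2\t26.0\t26.4\n"
                        "GAPDH\t20.0\t20.1\t20.0\t19.9\n")
        table = read_ct_wide(path, housekeeping=("GAPDH",))
        g_s1 = table.data.query("assay_id=='G' and sample_id=='s1'")
        assert sorted(g_s1["replicate"]) == [1, 2]
        assert g_s1["ct"].mean() == pytest.approx(24.1)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ExpressionError, match="positive"):
            ct_table([("G", "s1", 1, -1.0), ("GAPDH", "s1", 1, 20.0)])
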