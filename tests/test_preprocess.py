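import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plasmaprot as P
from plasmaprot.matrix import ScaleError

from conftest import make_matrix, make_table


def two_subject_sheet():
    return P.SampleSheet(pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4", "S5", "S6"],
        "subject_id": ["a"] * 3 + ["b"] * 3,
        "group": ["g1"] * 3 + ["g2"] * 3,
        "replicate_index": [1, 2, 3, 1, 2, 3],
    }))


class TestFilterFlags:
    def test_flagged_rows_removed_and_counted(self):
        vals = np.full((5, 2), 100.0)
        flags = {"reverse": [True, False, False, False, False],
                 "contaminant": [False, True, False, False, False]}
        table = make_table(vals, ["S1", "S2"], flags=flags)
        out, counts = P.filter_flags(table)
        assert out.n_proteins == 3
        assert counts == {"reverse": 1, "contaminant": 1, "site_only": 0}

    def test_no_flags_is_identity(self):
        table = make_table(np.full((4, 2), 10.0), ["S1", "S2"])
        out, _ = P.filter_flags(table)
        assert out.n_proteins == 4

    def test_multiply_flagged_row_counted_under_each_flag(self):
        flags = {"reverse": [True], "contaminant": [True], "site_only": [True]}
        table = make_table(np.full((1, 2), 10.0), ["S1", "S2"], flags=flags)
        out, counts = P.filter_flags(table)
        assert out.n_proteins == 0
        assert counts == {"reverse": 1, "contaminant": 1, "site_only": 1}


class TestReplicateValidity:
    def test_any_subject_with_two_valid_keeps_protein(self):
        vals = np.array([
            [100.0, 200.0, np.nan, np.nan, np.nan, np.nan],  # 2 valid for a
            [100.0, np.nan, np.nan, np.nan, 50.0, np.nan],   # 1 valid each
        ])
        out = P.filter_replicate_validity(
            make_table(vals, [f"S{i}" for i in range(1, 7)]), two_subject_sheet()
        )
        assert list(out.meta.index) == ["PG0"]

    def test_min_valid_above_replicate_count_errors(self):
        table = make_table(np.full((1, 6), 10.0), [f"S{i}" for i in range(1, 7)])
        with pytest.raises(P.ValidationError, match="min_valid"):
            P.filter_replicate_validity(table, two_subject_sheet(), min_valid=4)


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "triplicate,expected",
        [((1.0, 2.0, 4.0), 2.0), ((1.0, 2.0, np.nan), 1.5),
         ((np.nan, np.nan, np.nan), np.nan)],
    )
    def test_median_of_valid_replicates(self, triplicate, expected):
        vals = np.array([list(triplicate) + [10.0, 10.0, 10.0]])
        m = P.aggregate_replicates(
            make_table(vals, [f"S{i}" for i in range(1, 7)]), two_subject_sheet()
        )
        got = m.values.loc["PG0", "a"]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)


class TestCompleteness:
    def test_boundary_fraction_passes(self):
        # 7 of 10 valid in one group is exactly 0.7 -> kept
        vals = np.concatenate([np.full(7, 100.0), [np.nan] * 3])[None, :]
        m = make_matrix(vals, [f"c{i}" for i in range(10)], scale="linear")
        groups = pd.Series("g1", index=m.columns)
        out = P.filter_completeness(m, groups, frac=0.70, mode="any_group")
        assert out.n_proteins == 1

    def test_any_group_semantics_on_five_group_design(self):
        # per-group valid counts 6/10, 5/8, 6/10, 5/10, 7/10: max fraction 0.7 -> kept;
        # reducing the last group to 6/10 drops the protein
        sizes = [10, 8, 10, 10, 10]
        valid = [6, 5, 6, 5, 7]
        cols, labels, row = [], [], []
        for gi, (n, v) in enumerate(zip(sizes, valid)):
            for k in range(n):
                cols.append(f"g{gi}_{k}")
                labels.append(f"g{gi}")
                row.append(100.0 if k < v else np.nan)
        m = make_matrix(np.array([row]), cols, scale="linear")
        groups = pd.Series(labels, index=cols)
        assert P.filter_completeness(m, groups, 0.70, "any_group").n_proteins == 1
        row2 = list(row)
        row2[38 + 6] = np.nan  # drop one valid value of the last group: 6/10
        m2 = make_matrix(np.array([row2]), cols, scale="linear")
        assert P.filter_completeness(m2, groups, 0.70, "any_group").n_proteins == 0

    def test_monotone_in_frac(self, preprocessed):
        subj = preprocessed["subjects"]
        groups = preprocessed["sheet"].subject_group()
        kept = None
        for frac in (0.5, 0.7, 0.9):
            out = set(P.filter_completeness(subj, groups, frac, "any_group").values.index)
            if kept is not None:
                assert out <= kept
            kept = out

    def test_unassigned_column_rejected(self):
        m = make_matrix(np.full((1, 3), 10.0), ["a", "b", "c"], scale="linear")
        with pytest.raises(P.ValidationError, match="group"):
            P.filter_completeness(m, pd.Series({"a": "g", "b": "g"}), mode="any_group")


class TestLog2:
    def test_values_and_missing(self):
        m = make_matrix(np.array([[8.0, 1.0, np.nan]]), list("abc"), scale="linear")
        out = P.log2_transform(m)
        assert out.values.iloc[0, 0] == 3.0
        assert out.values.iloc[0, 1] == 0.0
        assert np.isnan(out.values.iloc[0, 2])
        assert out.scale == "log2"

    def test_double_transform_rejected(self):
        m = make_matrix(np.array([[8.0]]), ["a"], scale="linear")
        with pytest.raises(ScaleError):
            P.log2_transform(P.log2_transform(m))


class TestImputeDownshift:
    def test_complete_matrix_unchanged(self):
        m = make_matrix(np.full((4, 5), 25.0), list("abcde"))
        out = P.impute_downshift(m, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_observed_cells_preserved_exactly(self, preprocessed):
        main_log2 = P.log2_transform(preprocessed["main"])
        out = P.impute_downshift(main_log2, seed=5)
        obs = main_log2.values.notna()
        assert out.values[obs].equals(main_log2.values[obs])
        assert not out.values.isna().any().any()

    def test_imputed_distribution_matches_downshifted_normal(self):
        # one column: 100 observed with mean 25, SD 2; 10k missing cells
        rng = np.random.default_rng(3)
        obs = rng.normal(0, 1, 100)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 25.0
        col = np.concatenate([obs, np.full(10_000, np.nan)])
        m = make_matrix(col[:, None], ["c0"])
        out = P.impute_downshift(m, shift=1.8, width=0.3, seed=9)
        imputed = out.values.to_numpy()[100:, 0]
        assert imputed.mean() == pytest.approx(25 - 1.8 * 2, abs=0.02)
        assert imputed.std(ddof=1) == pytest.approx(0.6, abs=0.02)
        ks = stats.kstest(imputed, stats.norm(loc=25 - 3.6, scale=0.6).cdf)
        assert ks.pvalue > 0.01

    def test_same_seed_bit_identical(self, preprocessed):
        main_log2 = P.log2_transform(preprocessed["main"])
        a = P.impute_downshift(main_log2, seed=42)
        b = P.impute_downshift(main_log2, seed=42)
        assert a.values.equals(b.values)

    def test_sparse_column_rejected(self):
        col = np.array([[25.0], [26.0], [np.nan], [np.nan]])
        m = make_matrix(col, ["c0"])
        with pytest.raises(P.ValidationError, match="fewer than 3"):
            P.impute_downshift(m, seed=0)


class TestZscore:
    def test_hand_example_and_row_moments(self):
        m = make_matrix(np.array([[1.0, 2.0, 3.0]]), list("abc"))
        out = P.zscore_rows(m)
        assert np.allclose(out.values.iloc[0], [-1.0, 0.0, 1.0])
        rng = np.random.default_rng(0)
        m2 = make_matrix(rng.normal(20, 3, (5, 8)), [f"c{i}" for i in range(8)])
        z = P.zscore_rows(m2).values
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0)

    def test_constant_row_errors_naming_protein(self):
        m = make_matrix(np.array([[5.0, 5.0, 5.0]]), list("abc"))
        with pytest.raises(P.ValidationError, match="PG0"):
            P.zscore_rows(m)


class TestProvenance:
    def test_provenance_grows_append_only(self, preprocessed):
        imputed = preprocessed["imputed"]
        ops = [rec["op"] for rec in imputed.provenance]
        assert ops == ["aggregate_replicates", "filter_completeness",
                       "log2_transform", "impute_downshift"]
        assert imputed.provenance[-1]["seed"] == 11
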