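import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import plasmaprot as P
from _oracles import brute_force_bh, brute_force_permutation_fdr

from conftest import make_matrix


class TestStudentT:
    def test_identical_samples(self):
        t, p, _ = P.student_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_separated_constant_groups_with_jitter(self):
        eps = 1e-9
        t, p, _ = P.student_t([0, eps, 0, eps], [1, 1 + eps, 1, 1 + eps])
        assert p < 1e-6

    def test_worked_example(self):
        # a=(1,2,3,4), b=(3,4,5,6): pooled SD 1.2910, se 0.9129, t=-2.1909
        t, p, se = P.student_t([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.1909, abs=1e-4)
        assert se == pytest.approx(0.9129, abs=1e-4)
        assert p == pytest.approx(0.0707, abs=1e-3)

    def test_zero_variance_unequal_means_degenerates(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p, _ = P.student_t([1, 1], [2, 2])
        assert p == 0.0


class TestS0Statistic:
    def test_reduces_to_t_at_zero(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]
        t, _, se = P.student_t(a, b)
        d = np.mean(a) - np.mean(b)
        assert P.s0_statistic(d, se, 0.0) == pytest.approx(t)

    def test_arithmetic(self):
        assert P.s0_statistic(1.0, 0.5, 0.5) == 1.0

    def test_strictly_decreasing_in_s0(self):
        vals = [P.s0_statistic(0.1, 0.2, s0) for s0 in np.linspace(0, 2, 20)]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_zero_denominator_rejected(self):
        with pytest.raises(P.ValidationError):
            P.s0_statistic(1.0, 0.0, 0.0)


class TestPermutationFdrOracle:
    @pytest.mark.parametrize("toy_seed", [0, 1, 2])
    def test_exhaustive_4v4_matches_brute_force(self, toy_seed):
        """All C(8,4)=70 relabelings; threshold, significant set and q must
        match an independent loop-based implementation."""
        rng = np.random.default_rng(toy_seed)
        X = rng.normal(25, 1, size=(20, 8))
        X[0, :4] += 10.0  # one strongly shifted protein
        cols = [f"s{i}" for i in range(8)]
        m = make_matrix(X, cols)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=cols)
        contrast = P.Contrast(
            name="toy", groups_a=frozenset(["A"]), groups_b=frozenset(["B"]),
            s0=0.01, fdr=0.05, n_permutations=250, seed=0,
        )
        res = P.permutation_fdr(m, groups, contrast)
        assert res.metadata["exhaustive"]
        assert res.metadata["n_permutations_used"] == 70

        thr, sig, q = brute_force_permutation_fdr(
            [tuple(row) for row in X], n_a=4, s0=0.01, fdr=0.05
        )
        assert res.metadata["threshold_found"] == pytest.approx(thr, rel=1e-12)
        assert list(res.table["significant"]) == sig
        assert np.allclose(res.table["q_estimate"], q, rtol=1e-12)
        assert res.table["significant"].iloc[0]

    def test_s0_zero_exhaustive_matches_oracle_on_5v5(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, size=(12, 10))
        X[2, :5] += 6.0
        cols = [f"s{i}" for i in range(10)]
        m = make_matrix(X, cols)
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=cols)
        contrast = P.Contrast(
            name="toy", groups_a=frozenset(["A"]), groups_b=frozenset(["B"]),
            s0=0.0, fdr=0.05, n_permutations=300, seed=0,
        )
        res = P.permutation_fdr(m, groups, contrast)
        thr, sig, q = brute_force_permutation_fdr(
            [tuple(row) for row in X], n_a=5, s0=0.0, fdr=0.05
        )
        assert res.metadata["threshold_found"] == pytest.approx(thr, rel=1e-12)
        assert list(res.table["significant"]) == sig
        assert np.allclose(res.table["q_estimate"], q, rtol=1e-12)

    def test_constant_statistics_give_no_threshold(self):
        X = np.tile(np.array([20.0, 21.0, 20.0, 21.0, 20.0, 21.0, 20.0, 21.0]),
                    (5, 1))
        cols = [f"s{i}" for i in range(8)]
        m = make_matrix(X, cols)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=cols)
        contrast = P.Contrast(name="t", groups_a=frozenset(["A"]),
                              groups_b=frozenset(["B"]), seed=0)
        with pytest.warns(UserWarning, match="no threshold"):
            res = P.permutation_fdr(m, groups, contrast)
        assert not res.table["significant"].any()
        assert res.metadata["threshold_found"] == np.inf


class TestBH:
    def test_hand_example(self):
        q = P.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(P.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_matches_step_up_definition(self, p_values):
        assert np.allclose(P.bh_adjust(p_values), brute_force_bh(p_values))

    def test_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = P.bh_adjust(p)
        assert (q[np.argsort(p)] == np.sort(q)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(P.ValidationError):
            P.bh_adjust([0.5, 1.5])


class TestMouseCriteria:
    @pytest.mark.parametrize(
        "q,log2fc,expected",
        [(0.01, 0.8, False), (0.01, -1.2, True), (0.2, 3.0, False)],
    )
    def test_joint_rule(self, q, log2fc, expected):
        table = pd.DataFrame(
            {"gene": ["g"], "log2_diff": [log2fc], "q_estimate": [q],
             "significant": [False], "direction": ["up"]},
            index=["PG0"],
        )
        res = P.mouse_criteria(P.DiffResult(table=table), fdr=0.05, min_abs_log2fc=1.0)
        assert bool(res.table["significant"].iloc[0]) is expected
        if expected:
            assert res.table["direction"].iloc[0] == "down"

    def test_direction_consistent_with_sign(self):
        table = pd.DataFrame(
            {"gene": list("ab"), "log2_diff": [1.5, -1.5],
             "q_estimate": [0.001, 0.001], "significant": [False, False],
             "direction": ["up", "down"]},
            index=["PG0", "PG1"],
        )
        res = P.mouse_criteria(P.DiffResult(table=table))
        assert list(res.table["direction"]) == ["up", "down"]
        assert res.table["significant"].all()


class TestAnova:
    def test_identical_groups_fail(self):
        # every group holds the same pair of values -> zero between-group SS
        X = np.tile(np.array([20.0, 21.0] * 5), (3, 1))
        cols = [f"s{i}" for i in range(10)]
        m = make_matrix(X, cols)
        groups = pd.Series(["a"] * 2 + ["b"] * 2 + ["c"] * 2 + ["d"] * 2 + ["e"] * 2,
                           index=cols)
        res = P.anova_screen(m, groups)
        assert not res.table["passed"].any()

    def test_shifted_group_passes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(20, 0.1, size=(4, 25))
        X[1, :5] += 1.0  # 10 sigma shift in the first group
        cols = [f"s{i}" for i in range(25)]
        groups = pd.Series(np.repeat(list("abcde"), 5), index=cols)
        res = P.anova_screen(make_matrix(X, cols), groups)
        assert res.table["p_value"].iloc[1] < 1e-6
        assert res.table["passed"].iloc[1]

    def test_screen_flags_but_keeps_pairwise_hit(self):
        table = pd.DataFrame(
            {"gene": list("ab"), "significant": [True, True],
             "direction": ["up", "up"]},
            index=["PG0", "PG1"],
        )
        anova_table = pd.DataFrame(
            {"F_stat": [10.0, 0.1], "p_value": [1e-5, 0.9],
             "passed": [True, False]},
            index=["PG0", "PG1"],
        )
        out = P.apply_anova_screen(
            P.DiffResult(table=table), P.AnovaResult(anova_table, alpha=0.05)
        )
        assert list(out.table["in_panel"]) == [True, False]
        assert list(out.table["anova_excluded"]) == [False, True]
        assert len(out.table) == 2  # flagged, not deleted


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected",
        [([2.0, 2.0], [1.0, 1.0], 100.0),
         ([1.5, 1.5], [2.0, 2.0], -25.0),
         ([3.0, 4.0], [3.0, 4.0], 0.0)],
    )
    def test_percent_convention(self, a, b, expected):
        assert P.fold_change_pct(a, b) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(P.ValidationError):
            P.fold_change_pct([1.0], [0.0])

    @pytest.mark.parametrize("shift", [-1.0, -0.5, 0.5, 1.0])
    def test_sign_agrees_with_log2_difference(self, shift):
        rng = np.random.default_rng(4)
        a = rng.normal(20 + shift, 0.3, 10)
        b = rng.normal(20, 0.3, 10)
        pct = P.fold_change_pct(2.0 ** a, 2.0 ** b, center=np.mean)
        assert np.sign(pct) == np.sign(a.mean() - b.mean())

    def test_planted_effect_recovered_exactly_without_noise(self):
        base = np.full(10, 1e6)
        assert P.fold_change_pct(base * 4.41, base) == pytest.approx(341.0)


class TestAssumptionChecks:
    def test_equal_variance_normals_mostly_pass_levene(self):
        rng = np.random.default_rng(12)
        X = rng.normal(25, 1, size=(1000, 20))
        cols = [f"s{i}" for i in range(20)]
        m = make_matrix(X, cols)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=cols)
        con = P.Contrast(name="ab", groups_a=frozenset(["A"]),
                         groups_b=frozenset(["B"]))
        res = P.assumption_checks(m, groups, [con])
        frac = res["levene"]["ab"]["pass_fraction"]
        assert abs(frac - 0.95) <= 0.021  # 3 binomial MC SDs

    def test_unlogged_lognormal_fails_shapiro(self):
        rng = np.random.default_rng(13)
        X = np.exp(rng.normal(0, 1.5, size=(300, 20)))
        cols = [f"s{i}" for i in range(20)]
        m = make_matrix(X, cols, scale="linear")
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=cols)
        res = P.assumption_checks(m, groups)
        assert res["shapiro_pass_fraction"] < 0.5

    def test_tenfold_variance_ratio_fails_levene(self):
        rng = np.random.default_rng(14)
        X = np.concatenate(
            [rng.normal(25, 1, size=(200, 10)),
             rng.normal(25, np.sqrt(10), size=(200, 10))], axis=1
        )
        cols = [f"s{i}" for i in range(20)]
        m = make_matrix(X, cols)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=cols)
        con = P.Contrast(name="ab", groups_a=frozenset(["A"]),
                         groups_b=frozenset(["B"]))
        res = P.assumption_checks(m, groups, [con])
        # Levene's power at a 10-fold variance ratio with n=10+10 is ~0.7
        assert res["levene"]["ab"]["pass_fraction"] < 0.4


class TestContrastValidation:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(P.ValidationError, match="overlap"):
            P.Contrast(name="x", groups_a=frozenset(["a", "b"]),
                       groups_b=frozenset(["b"]))

    def test_empty_side_rejected(self):
        with pytest.raises(P.ValidationError, match="nonempty"):
            P.Contrast(name="x", groups_a=frozenset(), groups_b=frozenset(["b"]))
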