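"""The permutation DEG engine: statistics, nulls, p-values, combination,
cutoff and the full call."""

import itertools
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from permdeg import (
    DegCallParams,
    GroupDesign,
    build_null,
    call_degs,
    empirical_pvalue,
    fold_change_cutoff,
    log2_median_ratio,
    stouffer_combine,
    t_statistic,
)
from permdeg.errors import DesignError, ParameterError, StateError

from conftest import make_qnorm_matrix


# --- independent oracles ---------------------------------------------------


def pure_t(a, b):
    """Pooled-variance t computed with the statistics module only."""
    na, nb = len(a), len(b)
    va = statistics.variance(a)
    vb = statistics.variance(b)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = statistics.fmean(a) - statistics.fmean(b)
    if sp2 == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / math.sqrt(sp2 * (1 / na + 1 / nb))


def pure_fc(a, b):
    return statistics.median(a) - statistics.median(b)


def enumerate_null(X, n_test):
    """All C(n, n_test) label assignments; returns per-gene stat lists."""
    n = X.shape[1]
    t_null, fc_null = [], []
    for row in X:
        ts, fcs = [], []
        for combo in itertools.combinations(range(n), n_test):
            a = [row[i] for i in combo]
            b = [row[i] for i in range(n) if i not in combo]
            ts.append(pure_t(a, b))
            fcs.append(pure_fc(a, b))
        t_null.append(ts)
        fc_null.append(fcs)
    return t_null, fc_null


def phi(x):
    return 0.5 * math.erfc(-x / math.sqrt(2))


def phi_inv(p, lo=-12.0, hi=12.0):
    for _ in range(200):
        mid = (lo + hi) / 2
        if phi(mid) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def stouffer_oracle(p_t, p_fc, s_t, s_fc):
    z_t = max(phi_inv(1 - p_t), 0.0) * s_t
    z_fc = max(phi_inv(1 - p_fc), 0.0) * s_fc
    z_c = (z_t + z_fc) / math.sqrt(2)
    return min(1.0, 2 * (1 - phi(abs(z_c))))


# --- per-operation tests ---------------------------------------------------


class TestTStatistic:
    def test_identical_groups_zero(self):
        assert t_statistic([5, 6, 7], [5, 6, 7]) == 0.0

    def test_hand_value(self):
        # mean diff -3, pooled variance 1 -> t = -3 / sqrt(2/3)
        assert t_statistic([1, 2, 3], [4, 5, 6]) == pytest.approx(
            -3 / math.sqrt(2 / 3), abs=1e-10
        )

    def test_zero_variance_equal_means(self):
        assert t_statistic([2, 2, 2], [2, 2, 2]) == 0.0

    def test_zero_variance_unequal_means_is_signed_extreme(self):
        assert t_statistic([3, 3, 3], [2, 2, 2]) == math.inf
        assert t_statistic([2, 2, 2], [3, 3, 3]) == -math.inf

    def test_small_group_rejected(self):
        with pytest.raises(DesignError):
            t_statistic([1], [2, 3])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        st.lists(st.floats(-50, 50), min_size=2, max_size=6),
    )
    def test_matches_pure_python_oracle(self, a, b):
        expected = pure_t(a, b)
        got = t_statistic(a, b)
        if math.isinf(expected):
            assert got == expected
        else:
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestLog2MedianRatio:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 2, 3], [0, 0, 0], 2.0),
            ([0, 4], [1, 1], 1.0),  # even-length median is the midpoint
        ],
    )
    def test_values(self, a, b, expected):
        assert log2_median_ratio(a, b) == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(DesignError):
            log2_median_ratio([], [1])


class TestEmpiricalPvalue:
    def test_observed_zero_gives_one(self):
        assert empirical_pvalue(0.0, [0.5, -1, 2]) == 1.0

    def test_observed_beyond_all_nulls(self):
        null = np.linspace(-1, 1, 19)
        assert empirical_pvalue(5.0, null) == pytest.approx(1 / 20)

    def test_half_of_large_null_beyond(self):
        null = np.concatenate([np.full(500, 2.0), np.full(500, 0.5)])
        assert empirical_pvalue(1.0, null) == pytest.approx(501 / 1001)

    def test_empty_null_rejected(self):
        with pytest.raises(StateError):
            empirical_pvalue(1.0, [])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.floats(-100, 100),
        st.lists(st.floats(-100, 100), min_size=1, max_size=50),
    )
    def test_bounds_and_count_formula(self, obs, null):
        p = empirical_pvalue(obs, null)
        count = sum(1 for v in null if abs(v) >= abs(obs))
        assert p == (1 + count) / (1 + len(null))
        assert 0 < p <= 1


class TestStoufferCombine:
    def test_uninformative_inputs_give_one(self):
        assert stouffer_combine(1.0, 1.0, 1, 1) == 1.0
        assert stouffer_combine(1.0, 1.0, -1, 1) == 1.0

    def test_concordant_reinforcement(self):
        assert stouffer_combine(0.05, 0.05, 1, 1) == pytest.approx(
            0.0200, abs=1e-4
        )
        assert stouffer_combine(0.05, 0.05, -1, -1) == pytest.approx(
            0.0200, abs=1e-4
        )

    def test_discordant_cancellation(self):
        for p in (0.01, 0.05, 0.3):
            assert stouffer_combine(p, p, 1, -1) == 1.0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ParameterError):
            stouffer_combine(0.0, 0.5, 1, 1)
        with pytest.raises(ParameterError):
            stouffer_combine(0.5, 1.5, 1, 1)

    def test_matches_independent_normal_oracle_on_grid(self):
        grid = np.linspace(0.005, 1.0, 10)
        for p_t in grid:
            for p_fc in grid:
                for s_t, s_fc in [(1, 1), (1, -1)]:
                    got = stouffer_combine(p_t, p_fc, s_t, s_fc)
                    want = stouffer_oracle(p_t, p_fc, s_t, s_fc)
                    assert got == pytest.approx(want, abs=1e-9)


class TestFoldChangeCutoff:
    def test_symmetric_null(self):
        null = np.concatenate([np.linspace(-1, 1, 1001)])
        q_hi = np.percentile(null, 97.5)
        assert fold_change_cutoff(null) == pytest.approx(q_hi)

    def test_two_point_null(self):
        null = np.array([-0.5, 0.5] * 500)
        assert fold_change_cutoff(null) == pytest.approx(0.5)

    def test_normal_null_matches_quantile(self):
        rng = np.random.default_rng(42)
        null = rng.normal(0, 0.2, size=1000)
        assert fold_change_cutoff(null) == pytest.approx(0.2 * 1.96, abs=0.03)

    def test_alternative_reading(self):
        null = np.array([-0.2, -0.1, 0.0, 0.1, 0.6])
        q_lo, q_hi = np.percentile(null, [2.5, 97.5])
        assert fold_change_cutoff(null, "abs_of_mean") == pytest.approx(
            abs((q_lo + q_hi) / 2)
        )

    def test_empty_rejected(self):
        with pytest.raises(StateError):
            fold_change_cutoff([])


class TestBuildNull:
    def test_exhaustive_3v3_has_20_assignments(self, design_3v3):
        rng = np.random.default_rng(1)
        m = make_qnorm_matrix(rng.normal(size=(10, 6)))
        null = build_null(m, design_3v3, DegCallParams(null_mode="exhaustive"))
        assert null.t_null.shape == (10, 20)
        assert null.fc_null.shape == (10, 20)

    def test_constant_matrix_null_is_zero(self, design_3v3):
        m = make_qnorm_matrix(np.full((5, 6), 3.0))
        null = build_null(m, design_3v3, DegCallParams(n_perm=50))
        assert (null.t_null == 0).all()
        assert (null.fc_null == 0).all()

    def test_same_seed_identical_null(self, design_3v3):
        rng = np.random.default_rng(2)
        m = make_qnorm_matrix(rng.normal(size=(8, 6)))
        p = DegCallParams(n_perm=100, seed=5)
        a = build_null(m, design_3v3, p)
        b = build_null(m, design_3v3, p)
        np.testing.assert_array_equal(a.t_null, b.t_null)
        np.testing.assert_array_equal(a.fc_null, b.fc_null)

    def test_exhaustive_matches_enumeration_oracle(self, design_3v3):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 6))
        m = make_qnorm_matrix(X)
        null = build_null(m, design_3v3, DegCallParams(null_mode="exhaustive"))
        t_oracle, fc_oracle = enumerate_null(X, 3)
        # same multiset of permuted statistics per gene
        for g in range(6):
            np.testing.assert_allclose(
                np.sort(null.t_null[g]), np.sort(t_oracle[g]), atol=1e-10
            )
            np.testing.assert_allclose(
                np.sort(null.fc_null[g]), np.sort(fc_oracle[g]), atol=1e-10
            )


class TestCallDegs:
    def test_group_swap_negates_stats_keeps_pvalues(self, design_3v3):
        rng = np.random.default_rng(4)
        m = make_qnorm_matrix(rng.normal(size=(30, 6)))
        swapped = GroupDesign(groups=design_3v3.groups, reference="knockout")
        params = DegCallParams(n_perm=100, seed=2, null_mode="exhaustive")
        t1, _, _ = call_degs(m, design_3v3, params)
        t2, _, _ = call_degs(m, swapped, params)
        np.testing.assert_allclose(t1["t_stat"], -t2["t_stat"], atol=1e-10)
        np.testing.assert_allclose(t1["log2_fc"], -t2["log2_fc"], atol=1e-10)
        np.testing.assert_allclose(t1["p_t"], t2["p_t"])
        np.testing.assert_allclose(t1["p_fc"], t2["p_fc"])
        np.testing.assert_allclose(t1["p_combined"], t2["p_combined"])

    def test_fixed_cutoff_strict_inequality(self, design_3v3):
        # one strong gene; with the cutoff set exactly to its |fc| it must
        # not be called (strict "larger than the cutoff")
        X = np.zeros((40, 6))
        rng = np.random.default_rng(5)
        X += rng.normal(0, 0.3, size=X.shape)
        X[0, 3:] += 3.0
        m = make_qnorm_matrix(X)
        fc0 = float(np.median(X[0, 3:]) - np.median(X[0, :3]))
        params = DegCallParams(
            n_perm=200,
            seed=1,
            fc_cutoff_mode="fixed",
            fixed_cutoff_log2=abs(fc0),
        )
        table, _, _ = call_degs(m, design_3v3, params)
        assert not table.iloc[0]["is_deg"]
        below = DegCallParams(
            n_perm=200,
            seed=1,
            fc_cutoff_mode="fixed",
            fixed_cutoff_log2=abs(fc0) / 2,
        )
        table2, _, _ = call_degs(m, design_3v3, below)
        assert table2.iloc[0]["is_deg"]
        assert table2.iloc[0]["direction"] == "up"

    def test_bookkeeping_and_direction(self, small_processed, small_study):
        table, summary, _ = call_degs(
            small_processed, small_study.design, DegCallParams(n_perm=300, seed=3)
        )
        assert summary["n_deg"] == summary["n_up"] + summary["n_down"]
        assert summary["n_deg"] == int(table["is_deg"].sum())
        deg = table[table["is_deg"]]
        assert (deg.loc[deg["direction"] == "up", "log2_fc"] > 0).all()
        assert (deg.loc[deg["direction"] == "down", "log2_fc"] < 0).all()
        assert (table.loc[~table["is_deg"], "direction"] == "none").all()
        assert ((table["p_combined"] > 0) & (table["p_combined"] <= 1)).all()

    def test_bh_flag_adds_q_column(self, small_processed, small_study):
        table, _, _ = call_degs(
            small_processed,
            small_study.design,
            DegCallParams(n_perm=100, seed=3, bh_fdr=True),
        )
        assert "q_combined" in table.columns
        assert (table["q_combined"] >= table["p_combined"] - 1e-12).all()

    def test_wrong_scale_rejected(self, small_study, design_3v3):
        with pytest.raises(StateError):
            call_degs(small_study.matrix, small_study.design, DegCallParams(n_perm=10))

    def test_per_gene_mode_resolution_floor(self, design_3v3):
        # per-gene nulls from 20 exhaustive splits cannot go below 1/21
        rng = np.random.default_rng(6)
        m = make_qnorm_matrix(rng.normal(size=(12, 6)))
        params = DegCallParams(null_mode="exhaustive", seed=1)
        table, _, _ = call_degs(m, design_3v3, params)
        assert (table["p_t"] >= 1 / 21 - 1e-12).all()
        assert (table["p_fc"] >= 1 / 21 - 1e-12).all()
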