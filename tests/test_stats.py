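"""Two-way ANOVA, paired t-tests and the signed significance matrix."""

import numpy as np
import pandas as pd
import pytest

from flexbench.exceptions import DesignError, UndefinedStatisticError
from flexbench.stats import (
    NEGATIVE,
    NOT_SIG,
    POSITIVE,
    pairwise_t,
    significance_matrix,
    two_way_anova,
)


def long_table(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "expt_method", "ss_class", "method", "r_p", "r_s"]
    )


def balanced_2x2(values):
    """2 methods x 2 classes x 2 replicates; values in method-major order."""
    rows = []
    i = 0
    for method in ("m1", "m2"):
        for ss in ("alpha", "beta"):
            for rep in range(2):
                rows.append((f"p{i}", "nmr", ss, method, values[i], values[i]))
                i += 1
    return long_table(rows)


class TestTwoWayAnova:
    def test_balanced_design_matches_closed_form(self):
        """Balanced 2x2 with 2 replicates: sums of squares decompose in
        closed form from cell means, and Type II equals the classical
        decomposition."""
        values = np.array([3.0, 5.0, 2.0, 4.0, 7.0, 9.0, 4.0, 6.0])
        table = balanced_2x2(values)
        res = two_way_anova(table, response="r_p")
        grand = values.mean()
        cells = values.reshape(2, 2, 2).mean(axis=2)
        a_means = cells.mean(axis=1)
        b_means = cells.mean(axis=0)
        ss_a = 4 * np.sum((a_means - grand) ** 2)
        ss_b = 4 * np.sum((b_means - grand) ** 2)
        ss_ab = 2 * np.sum(
            (cells - a_means[:, None] - b_means[None, :] + grand) ** 2
        )
        ss_err = np.sum((values.reshape(2, 2, 2) - cells[..., None]) ** 2)
        assert res.loc["method", "sum_sq"] == pytest.approx(ss_a, abs=1e-10)
        assert res.loc["ss_class", "sum_sq"] == pytest.approx(ss_b, abs=1e-10)
        assert res.loc["interaction", "sum_sq"] == pytest.approx(ss_ab, abs=1e-10)
        assert res.loc["residual", "sum_sq"] == pytest.approx(ss_err, abs=1e-10)
        ms_err = ss_err / 4
        assert res.loc["method", "F"] == pytest.approx(ss_a / ms_err, rel=1e-10)

    def test_matches_statsmodels_type2_on_unbalanced_data(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rows = []
        i = 0
        for method in ("m1", "m2", "m3"):
            for ss in ("alpha", "beta", "alpha_beta"):
                for _ in range(int(rng.integers(2, 6))):
                    rows.append(
                        (f"p{i}", "nmr", ss, method, rng.normal(), rng.normal())
                    )
                    i += 1
        table = long_table(rows)
        ours = two_way_anova(table, response="r_p")
        model = ols("r_p ~ C(method) * C(ss_class)", data=table).fit()
        ref = sm.stats.anova_lm(model, typ=2)
        assert ours.loc["method", "sum_sq"] == pytest.approx(
            ref.loc["C(method)", "sum_sq"], rel=1e-8
        )
        assert ours.loc["ss_class", "sum_sq"] == pytest.approx(
            ref.loc["C(ss_class)", "sum_sq"], rel=1e-8
        )
        assert ours.loc["interaction", "F"] == pytest.approx(
            ref.loc["C(method):C(ss_class)", "F"], rel=1e-8
        )
        assert ours.loc["method", "p"] == pytest.approx(
            ref.loc["C(method)", "PR(>F)"], rel=1e-8
        )

    def test_constant_response_rejected(self):
        table = balanced_2x2(np.ones(8))
        with pytest.raises(DesignError):
            two_way_anova(table, response="r_p")

    def test_single_level_factor_rejected(self):
        rows = [(f"p{i}", "nmr", "alpha", m, v, v)
                for i, (m, v) in enumerate([("m1", 1.0), ("m1", 2.0), ("m2", 3.0), ("m2", 4.0)])]
        with pytest.raises(DesignError):
            two_way_anova(long_table(rows), response="r_p")

    def test_f_nonnegative_p_in_unit_interval(self, rng):
        table = balanced_2x2(rng.normal(size=8))
        res = two_way_anova(table, response="r_p")
        f = res.loc[["method", "ss_class", "interaction"], "F"]
        p = res.loc[["method", "ss_class", "interaction"], "p"]
        assert (f >= 0).all() and ((p > 0) & (p <= 1)).all()


def paired_table(a_vals, b_vals, expt="nmr", ss="alpha"):
    rows = []
    for i, (a, b) in enumerate(zip(a_vals, b_vals)):
        rows.append((f"p{i}", expt, ss, "A", a, a))
        rows.append((f"p{i}", expt, ss, "B", b, b))
    return long_table(rows)


class TestPairwiseT:
    def test_identical_methods_give_t_zero_p_one(self):
        table = paired_table([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        t, df, p = pairwise_t(table, "A", "B")
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_hand_computed_differences(self):
        # differences (1, 2, 3): mean 2, SD 1 -> t = 2*sqrt(3), df = 2
        table = paired_table([1.2, 2.5, 3.1], [0.2, 0.5, 0.1])
        t, df, p = pairwise_t(table, "A", "B")
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert df == 2

    def test_antisymmetric_under_swap(self, rng):
        a = rng.uniform(0, 1, size=8)
        b = rng.uniform(0, 1, size=8)
        table = paired_table(a, b)
        t1, _, p1 = pairwise_t(table, "A", "B")
        t2, _, p2 = pairwise_t(table, "B", "A")
        assert t2 == pytest.approx(-t1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_constant_offset_sign(self, rng):
        a = rng.uniform(0, 1, size=10)
        jitter = rng.normal(scale=1e-3, size=10)
        table = paired_table(a + 0.2 + jitter, a)
        t, _, _ = pairwise_t(table, "A", "B")
        assert t > 0

    def test_constant_nonzero_difference_degenerate(self):
        table = paired_table([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        with pytest.raises(UndefinedStatisticError):
            pairwise_t(table, "A", "B")

    def test_requires_three_shared_proteins(self):
        table = paired_table([1.0, 2.0], [0.5, 1.5])
        with pytest.raises(UndefinedStatisticError):
            pairwise_t(table, "A", "B")

    def test_unpaired_fallback_matches_scipy(self, rng):
        import scipy.stats

        a = rng.uniform(size=6)
        b = rng.uniform(size=6)
        table = paired_table(a, b)
        t, df, p = pairwise_t(table, "A", "B", paired=False)
        ref = scipy.stats.ttest_ind(a, b)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert df == 10


class TestSignificanceMatrix:
    def test_identical_methods_not_significant(self):
        table = paired_table([0.5, 0.6, 0.7, 0.8], [0.5, 0.6, 0.7, 0.8])
        mat = significance_matrix(table, methods=["A", "B"])
        assert mat.labels[0, 1] == NOT_SIG and mat.labels[1, 0] == NOT_SIG

    def test_constructed_separation(self):
        rng = np.random.default_rng(42)
        good = 0.9 + rng.normal(scale=0.02, size=12)
        bad = -0.5 + rng.normal(scale=0.02, size=12)
        mat = significance_matrix(paired_table(good, bad), methods=["A", "B"])
        # row minus column: A - B positive on r_p (upper) and r_s (lower
        # cell B,A is B - A, hence negative)
        assert mat.labels[0, 1] == POSITIVE
        assert mat.labels[1, 0] == NEGATIVE
        assert mat.cell("A", "B")[1] < 0.05

    def test_sign_antisymmetry_between_triangles(self, rng):
        a = rng.uniform(0, 1, size=10)
        b = a + 0.3 + rng.normal(scale=0.05, size=10)
        mat = significance_matrix(paired_table(a, np.clip(b, 0, 1)), methods=["A", "B"])
        sign = {POSITIVE: 1, NEGATIVE: -1, NOT_SIG: 0}
        assert sign[mat.labels[0, 1]] == -sign[mat.labels[1, 0]]
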