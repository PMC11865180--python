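"""Paired t, JZS Bayes factor, rm-ANOVAs and Tukey against independent oracles."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import integrate, stats
from statsmodels.stats.anova import AnovaRM

from ensembleyn import inference as inf


class TestPairedT:
    def test_identical_vectors(self):
        r = inf.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.statistic, r.effect_size, r.p_value) == (0.0, 0.0, 1.0)

    def test_hand_computed_t(self):
        # differences (1, 2, 3): t = 2 / (1 / sqrt(3)) = 3.464, df = 2
        r = inf.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(2 * math.sqrt(3), abs=1e-3)
        assert r.df == 2

    def test_sign_flip_symmetry(self):
        x, y = np.array([0.1, 0.5, 0.3, 0.9]), np.array([0.2, 0.3, 0.1, 0.6])
        r1, r2 = inf.paired_t(x, y), inf.paired_t(y, x)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_cohens_d_is_t_over_sqrt_n(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(24), rng.random(24)
        r = inf.paired_t(x, y)
        assert r.effect_size == pytest.approx(r.statistic / math.sqrt(24))

    def test_zero_variance_nonzero_differences(self):
        with pytest.raises(ValueError, match="zero variance"):
            inf.paired_t([1.0, 1.0], [0.0, 0.0])


class TestJZSBayesFactor:
    def test_null_favored_at_t_zero(self):
        assert inf.jzs_bf_paired(0.0, 24) < 1

    def test_monotone_in_t(self):
        bfs = [inf.jzs_bf_paired(t, 20) for t in (0.0, 1.0, 2.0, 3.0, 5.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize(
        "t,n,r",
        [(2.0, 12, 0.707), (4.87, 24, 0.707), (-1.5, 30, 1.0), (3.603, 22, 0.5)],
    )
    def test_matches_dense_grid_quadrature(self, t, n, r):
        """Independent oracle: trapezoid rule on a wide dense delta grid."""
        grid = np.linspace(-60, 60, 200_001)
        num = np.trapezoid(
            stats.nct.pdf(t, n - 1, grid * math.sqrt(n))
            * stats.cauchy.pdf(grid, 0, r),
            grid,
        )
        oracle = num / stats.t.pdf(t, n - 1)
        assert inf.jzs_bf_paired(t, n, r) == pytest.approx(oracle, rel=1e-4)

    def test_matches_pingouin(self):
        ours = inf.jzs_bf_paired(4.87, 24)
        theirs = float(pg.bayesfactor_ttest(4.87, 24, paired=True, r=inf.DEFAULT_R_SCALE))
        assert ours == pytest.approx(theirs, rel=1e-6)


def brute_force_oneway(y):
    """Loop-based within-subjects SS decomposition (independent oracle)."""
    n, k = y.shape
    grand = y.mean()
    ss_total = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_subj = sum(k * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_cond = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_subj - ss_cond
    return (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


class TestOneWay:
    def wide(self, y):
        return pd.DataFrame(y, columns=list("ABC")[: y.shape[1]])

    def test_null_case(self):
        y = np.tile(np.array([[0.2], [0.5], [0.4], [0.7]]), (1, 3))
        res = inf.rm_anova_oneway(self.wide(y), tukey_posthoc=False)
        assert res.effects["condition"].statistic == pytest.approx(0.0)

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(8)
        y = rng.random((4, 3))
        res = inf.rm_anova_oneway(self.wide(y))
        assert res.effects["condition"].statistic == pytest.approx(brute_force_oneway(y))
        long = self.wide(y).reset_index().melt(id_vars="index")
        sm = AnovaRM(long, "value", "index", within=["variable"]).fit()
        assert res.effects["condition"].statistic == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0])
        )
        assert res.effects["condition"].df == (2.0, 6.0)

    def test_participant_shift_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.random((6, 3))
        shifted = y + rng.random((6, 1))
        f1 = inf.rm_anova_oneway(self.wide(y), tukey_posthoc=False)
        f2 = inf.rm_anova_oneway(self.wide(shifted), tukey_posthoc=False)
        assert f1.effects["condition"].statistic == pytest.approx(
            f2.effects["condition"].statistic
        )

    def test_two_conditions_f_equals_t_squared(self):
        rng = np.random.default_rng(10)
        x, y = rng.random(12), rng.random(12)
        f = inf.rm_anova_oneway(
            pd.DataFrame({"A": x, "B": y}), tukey_posthoc=False
        ).effects["condition"]
        t = inf.paired_t(x, y)
        assert f.statistic == pytest.approx(t.statistic**2)
        assert f.p_value == pytest.approx(t.p_value)


def tidy_3x3(y):
    rows = []
    for i in range(y.shape[0]):
        for a in range(3):
            for b in range(3):
                rows.append(
                    {
                        "participant_id": f"P{i}",
                        "relevant": f"a{a}",
                        "irrelevant": f"b{b}",
                        "p_no": y[i, a, b],
                    }
                )
    return pd.DataFrame(rows)


class Test3x3:
    def test_additive_data_has_zero_interaction(self):
        subj = np.array([0.1, 0.3, 0.5])[:, None, None]
        a_eff = np.array([0.0, 0.1, 0.2])[None, :, None]
        b_eff = np.array([0.0, 0.05, 0.1])[None, None, :]
        y = subj + a_eff + b_eff
        res = inf.rm_anova_3x3(tidy_3x3(y))
        assert res.effects["interaction"].statistic == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(11)
        y = rng.random((3, 3, 3))
        res = inf.rm_anova_3x3(tidy_3x3(y))
        sm = AnovaRM(
            tidy_3x3(y), "p_no", "participant_id", within=["relevant", "irrelevant"]
        ).fit()
        table = sm.anova_table
        assert res.effects["relevant"].statistic == pytest.approx(
            float(table.loc["relevant", "F Value"])
        )
        assert res.effects["irrelevant"].statistic == pytest.approx(
            float(table.loc["irrelevant", "F Value"])
        )
        assert res.effects["interaction"].statistic == pytest.approx(
            float(table.loc["relevant:irrelevant", "F Value"])
        )
        assert res.effects["relevant"].df == (2.0, 4.0)
        assert res.effects["interaction"].df == (4.0, 8.0)

    def test_factor_permutation_symmetry(self):
        rng = np.random.default_rng(12)
        y = rng.random((4, 3, 3))
        res = inf.rm_anova_3x3(tidy_3x3(y))
        swapped = inf.rm_anova_3x3(
            tidy_3x3(y).rename(columns={"relevant": "irrelevant", "irrelevant": "relevant"})
        )
        assert res.effects["relevant"].statistic == pytest.approx(
            swapped.effects["irrelevant"].statistic
        )


class TestTukey:
    def test_equal_means_not_separated(self):
        out = inf.tukey({"A": 0.4, "B": 0.4}, error_ms=0.01, error_df=10, n_per_mean=8)
        assert out["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_p_monotone_in_difference(self):
        means = {"A": 0.0, "B": 0.1, "C": 0.5}
        out = inf.tukey(means, error_ms=0.02, error_df=20, n_per_mean=10)
        out = out.set_index("pair")
        assert out.loc["A - C", "p_adj"] < out.loc["A - B", "p_adj"]

    def test_matches_numerical_integration_oracle(self):
        """Studentized-range tail by direct integration (large error df)."""
        means = {"A": 0.30, "B": 0.38, "C": 0.52}
        k, n, ms = 3, 12, 0.015
        out = inf.tukey(means, error_ms=ms, error_df=1e6, n_per_mean=n).set_index("pair")
        z = np.linspace(-12, 12, 40_001)
        phi, Phi = stats.norm.pdf(z), stats.norm.cdf(z)

        def sf(q):
            cdf = k * np.trapezoid(phi * (Phi - stats.norm.cdf(z - q)) ** (k - 1), z)
            return 1 - cdf

        for (la, ma), (lb, mb) in [(("A", 0.30), ("B", 0.38)), (("A", 0.30), ("C", 0.52))]:
            q = abs(ma - mb) / math.sqrt(ms / n)
            assert out.loc[f"{la} - {lb}", "p_adj"] == pytest.approx(sf(q), abs=1e-5)

    def test_chain_orders_significant_means(self):
        means = {"M": 0.2, "Old": 0.3, "N1": 0.6}
        out = inf.tukey(means, error_ms=0.001, error_df=40, n_per_mean=20)
        assert out.attrs["chain"] == "N1 > Old > M"

    def test_bad_error_df_rejected(self):
        with pytest.raises(ValueError):
            inf.tukey({"A": 0.1, "B": 0.2}, 0.01, 0, 5)
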