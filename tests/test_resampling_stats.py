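"""Resampling inference vs independent oracles: exhaustive enumeration,
definitional sums of squares, pingouin, and scipy's BCa bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from choicedyn.resampling_stats import (
    bonferroni,
    ks_two_sample,
    paired_permutation_test,
    ranksum,
    rm_anova,
    rm_corr,
    spearman_pairwise,
)


class TestPairedPermutation:
    def test_all_zero_differences(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_permutation_test(x, x)
        assert res.mean_diff == 0.0
        assert res.p_value == 1.0

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 4)
        y = x + rng.normal(0.5, 1, 4)
        res = paired_permutation_test(x, y, n_perm=5000, seed=1)
        assert res.exact
        d = y - x
        stat = d.mean()
        count = sum(
            abs(np.mean(s * d)) >= abs(stat) - 1e-12
            for s in itertools.product((-1, 1), repeat=4)
        )
        assert res.p_value == pytest.approx(count / 16)

    def test_monte_carlo_p_valid_and_seeded(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 20)
        y = x + rng.normal(0.8, 0.5, 20)
        a = paired_permutation_test(x, y, n_perm=2000, seed=4)
        b = paired_permutation_test(x, y, n_perm=2000, seed=4)
        assert a.p_value == b.p_value and a.ci_low == b.ci_low
        assert a.p_value >= 1.0 / 2001

    def test_bca_interval_matches_scipy(self):
        """Independent BCa oracle: scipy.stats.bootstrap on the same data."""
        rng = np.random.default_rng(17)
        d = rng.normal(0.3, 1.0, 30)
        res = paired_permutation_test(np.zeros(30), d, n_boot=20_000, seed=2)
        ref = sps.bootstrap(
            (d,), np.mean, confidence_level=0.95, n_resamples=20_000,
            method="BCa", random_state=np.random.default_rng(99),
        ).confidence_interval
        assert res.ci_low == pytest.approx(ref.low, abs=0.03)
        assert res.ci_high == pytest.approx(ref.high, abs=0.03)
        assert res.ci_low <= res.mean_diff <= res.ci_high

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            paired_permutation_test(np.ones(2), np.ones(2))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=9),
)
def test_permutation_p_is_valid_and_symmetric(diffs):
    """p is in (0, 1], and swapping the two paired samples (a pure sign flip
    of every difference) leaves the two-sided p unchanged."""
    d = np.asarray(diffs)
    x = np.zeros_like(d)
    res = paired_permutation_test(x, d, n_perm=600, n_boot=50, seed=0)
    res_swapped = paired_permutation_test(d, x, n_perm=600, n_boot=50, seed=0)
    assert 0 < res.p_value <= 1
    assert res.p_value == pytest.approx(res_swapped.p_value)


def test_bonferroni_cap_and_monotonicity():
    np.testing.assert_allclose(bonferroni([0.01, 0.5], m=5), [0.05, 1.0])
    p = np.array([0.001, 0.01, 0.02, 0.3])
    adj = bonferroni(p, m=4)
    assert (np.diff(adj) >= 0).all()
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], m=1)


def _toy_one_factor(effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(5):
        base = rng.normal(0, 1)
        for i, lvl in enumerate(["a", "b", "c"]):
            rows.append(dict(subject=f"s{s}", cond=lvl,
                             y=base + effect * i + rng.normal(0, 0.3)))
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_null_effect_f_small(self):
        df = _toy_one_factor(0.0, seed=1)
        # make all condition means identical per subject
        df = df.copy()
        df["y"] = df.groupby("subject")["y"].transform("mean")
        res = rm_anova(df, dv="y", within="cond", subject="subject")
        assert res["cond"]["F"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_definitional_partition(self):
        """Brute-force SS partition computed from raw cell deviations."""
        df = _toy_one_factor(0.7, seed=2)
        res = rm_anova(df, dv="y", within="cond", subject="subject")
        y = df.set_index(["subject", "cond"]).y
        grand = y.mean()
        ss_a = 5 * sum((y.groupby(level="cond").mean() - grand) ** 2)
        ss_s = 3 * sum((y.groupby(level="subject").mean() - grand) ** 2)
        ss_tot = sum((y - grand) ** 2)
        ss_err = ss_tot - ss_a - ss_s
        F = (ss_a / 2) / (ss_err / 8)
        assert res["cond"]["F"] == pytest.approx(F, rel=1e-10)
        assert res["cond"]["df_effect"] == 2
        assert res["cond"]["df_error"] == 8

    def test_matches_pingouin_one_and_two_factor(self):
        pingouin = pytest.importorskip("pingouin")
        df = _toy_one_factor(0.5, seed=3)
        res = rm_anova(df, dv="y", within="cond", subject="subject")
        ref = pingouin.rm_anova(data=df, dv="y", within="cond", subject="subject")
        pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert res["cond"]["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res["cond"]["p"] == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

        rng = np.random.default_rng(4)
        rows = []
        for s in range(6):
            for a in ("a1", "a2"):
                for b in ("b1", "b2", "b3"):
                    rows.append(dict(subject=s, A=a, B=b, y=rng.normal()))
        df2 = pd.DataFrame(rows)
        res2 = rm_anova(df2, dv="y", within=["A", "B"], subject="subject")
        ref2 = pingouin.rm_anova(data=df2, dv="y", within=["A", "B"],
                                 subject="subject").set_index("Source")
        assert res2["A"]["F"] == pytest.approx(float(ref2.loc["A", "F"]), rel=1e-6)
        assert res2["B"]["F"] == pytest.approx(float(ref2.loc["B", "F"]), rel=1e-6)
        assert res2["A*B"]["F"] == pytest.approx(float(ref2.loc["A * B", "F"]), rel=1e-6)

    def test_location_invariance(self):
        df = _toy_one_factor(0.5, seed=5)
        res1 = rm_anova(df, dv="y", within="cond", subject="subject")
        df2 = df.assign(y=df.y + 100.0)
        res2 = rm_anova(df2, dv="y", within="cond", subject="subject")
        assert res1["cond"]["F"] == pytest.approx(res2["cond"]["F"], rel=1e-9)

    def test_unbalanced_design_raises(self):
        df = _toy_one_factor(0.5, seed=6).iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(df, dv="y", within="cond", subject="subject")


class TestRmCorr:
    def test_perfect_within_subject_line(self):
        rows = []
        for s, off in enumerate([0.0, 5.0, -3.0]):
            for x in (1.0, 2.0, 3.0, 4.0):
                rows.append(dict(subject=s, x=x, y=x + off))
        res = rm_corr(pd.DataFrame(rows), "x", "y", "subject")
        assert res.r == pytest.approx(1.0)
        assert res.df == 12 - 3 - 1

    def test_matches_normal_equations_oracle(self):
        """Brute-force ANCOVA: solve [x, subject dummies] by least squares."""
        rng = np.random.default_rng(11)
        rows = []
        for s in range(4):
            for _ in range(5):
                x = rng.normal()
                rows.append(dict(subject=s, x=x, y=0.6 * x + s + rng.normal(0, 0.5)))
        df = pd.DataFrame(rows)
        res = rm_corr(df, "x", "y", "subject")
        X = np.column_stack(
            [df.x, *(np.asarray(df.subject == s, float) for s in range(4))]
        )
        beta, rss, *_ = np.linalg.lstsq(X, df.y, rcond=None)
        assert res.slope == pytest.approx(beta[0], rel=1e-9)
        null_X = X[:, 1:]
        _, rss0, *_ = np.linalg.lstsq(null_X, df.y, rcond=None)
        r_expected = np.sign(beta[0]) * np.sqrt((rss0[0] - rss[0]) / rss0[0])
        assert res.r == pytest.approx(r_expected, rel=1e-9)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        rows = []
        for s in range(6):
            for _ in range(5):
                x = rng.normal()
                rows.append(dict(subject=f"s{s}", x=x, y=0.4 * x + rng.normal(0, 1)))
        df = pd.DataFrame(rows)
        res = rm_corr(df, "x", "y", "subject")
        ref = pingouin.rm_corr(data=df, x="x", y="y", subject="subject")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), rel=1e-6)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_independent_data_r_near_zero(self):
        rng = np.random.default_rng(13)
        ps = []
        for rep in range(400):
            rows = [dict(subject=s, x=rng.normal(), y=rng.normal())
                    for s in range(8) for _ in range(6)]
            ps.append(rm_corr(pd.DataFrame(rows), "x", "y", "subject").p)
        # calibration: rejection rate at alpha=0.05 within 3 SE of nominal
        rej = np.mean(np.asarray(ps) < 0.05)
        assert abs(rej - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(ps))
        # and the p-values roughly uniform overall
        assert sps.kstest(ps, "uniform").pvalue > 1e-4

    def test_subject_guard(self):
        df = pd.DataFrame(dict(subject=[1, 1, 2, 2], x=[1, 2, 1, 2], y=[1, 2, 2, 1]))
        with pytest.raises(ValueError):
            rm_corr(df, "x", "y", "subject")


class TestTwoSampleTests:
    def test_ks_identical_and_disjoint(self):
        a = np.arange(10.0)
        stat, p = ks_two_sample(a, a)
        assert stat == 0.0 and p == pytest.approx(1.0)
        stat2, _ = ks_two_sample(a, a + 100.0)
        assert stat2 == 1.0

    def test_ks_matches_brute_force_sup(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        stat, _ = ks_two_sample(a, b)
        pooled = np.r_[a, b]
        sup = max(
            abs(np.mean(a <= t) - np.mean(b <= t)) for t in pooled
        )
        assert stat == pytest.approx(sup)

    def test_ranksum_identical(self):
        a = np.arange(8.0)
        _, p = ranksum(a, a)
        assert p > 0.9

    def test_ranksum_matches_exact_enumeration(self):
        """4-vs-4 exact null via all label assignments."""
        a = np.array([0.1, 0.4, 0.2, 0.9])
        b = np.array([1.3, 0.8, 1.7, 0.3])
        u_stat, p_asym = ranksum(a, b)
        u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert u_stat == u_obs
        pooled = np.r_[a, b]
        us = []
        for comb in itertools.combinations(range(8), 4):
            ga = pooled[list(comb)]
            gb = pooled[[i for i in range(8) if i not in comb]]
            us.append(sum((x > y) + 0.5 * (x == y) for x in ga for y in gb))
        p_exact = np.mean([min(u, 16 - u) <= min(u_obs, 16 - u_obs) for u in us])
        # normal approximation agrees with the enumerated null at small n
        assert p_asym == pytest.approx(p_exact, abs=0.12)

    def test_ranksum_shift_detected(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 50)
        _, p = ranksum(a, a + 1.5)
        assert p < 1e-6


class TestSpearman:
    def test_monotone_invariance_and_perfect_rank(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5, 6.0]})
        df["y"] = df.x**3
        df["z"] = np.exp(df.x)
        rho, _ = spearman_pairwise(df)
        assert rho.loc["x", "y"] == pytest.approx(1.0)
        assert rho.loc["y", "z"] == pytest.approx(1.0)

    def test_matches_manual_rank_computation(self):
        df = pd.DataFrame({"x": [3.0, 1.0, 4.0, 1.0, 5.0, 9.0],
                           "y": [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]})
        rho, _ = spearman_pairwise(df)
        rx = sps.rankdata(df.x)
        ry = sps.rankdata(df.y)
        manual = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(manual)

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        rho, p = spearman_pairwise(df)
        assert np.isnan(rho.loc["x", "c"]) and np.isnan(p.loc["x", "c"])
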