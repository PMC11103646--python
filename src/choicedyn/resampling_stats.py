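"""Resampling and repeated-measures inference.

The workhorse is the two-sided paired permutation test: the observed statistic
is the mean paired difference, the null distribution comes from sign-flipping
each pair's difference (every subject keeps its own magnitude), and the effect
size is accompanied by a bias-corrected and accelerated (BCa) bootstrap
confidence interval.  When the sign-flip space is small enough the p-value is
computed by exhaustive enumeration; otherwise by Monte Carlo with the add-one
(Phipson-Smyth) correction, which keeps the p-value valid (never zero, and
super-uniform under the null).

Also here: Bonferroni adjustment, balanced within-subject (repeated-measures)
ANOVA computed from the definitional sums-of-squares partition, the
repeated-measures correlation (common-slope ANCOVA with subject intercepts),
and thin wrappers over the standard two-sample tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "RmAnovaResult",
    "RmCorrResult",
    "paired_permutation_test",
    "bonferroni",
    "rm_anova",
    "rm_corr",
    "ks_two_sample",
    "ranksum",
    "spearman_pairwise",
]


@dataclass
class PermutationResult:
    mean_diff: float
    p_value: float
    ci_low: float
    ci_high: float
    n_perm: int
    n_boot: int
    seed: int
    exact: bool = False
    ci_violated: bool = False  # BCa interval does not cover the point estimate

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "p_value": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_perm": self.n_perm,
            "n_boot": self.n_boot,
            "exact": self.exact,
        }


def paired_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    n_boot: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided paired permutation test of mean(y - x) = 0, with a BCa CI.

    If ``2**n <= n_perm`` all sign patterns are enumerated and the p-value is
    exact; otherwise ``n_perm`` random sign flips are drawn and
    p = (1 + #{|stat*| >= |stat|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = y - x
    stat = float(np.mean(d))
    rng = np.random.default_rng(seed)

    tol = 1e-12 * max(1.0, abs(stat))
    if 2**n <= n_perm:
        signs = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
        null = signs @ d / n
        p = float(np.mean(np.abs(null) >= abs(stat) - tol))
        exact = True
        n_perm_used = 2**n
    else:
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
        null = signs @ d / n
        hits = int(np.sum(np.abs(null) >= abs(stat) - tol))
        p = (1.0 + hits) / (n_perm + 1.0)
        exact = False
        n_perm_used = n_perm

    ci_low, ci_high = _bca_interval(d, stat, n_boot, rng)
    return PermutationResult(
        mean_diff=stat,
        p_value=p,
        ci_low=ci_low,
        ci_high=ci_high,
        n_perm=n_perm_used,
        n_boot=n_boot,
        seed=seed,
        exact=exact,
        ci_violated=not (ci_low <= stat <= ci_high),
    )


def _bca_interval(
    d: np.ndarray, stat: float, n_boot: int, rng: np.random.Generator,
    level: float = 0.95,
) -> tuple[float, float]:
    """BCa bootstrap interval for the mean of the paired differences."""
    n = d.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = d[idx].mean(axis=1)

    # bias correction from the bootstrap distribution's position vs the estimate
    prop = (np.sum(boot < stat) + 0.5 * np.sum(boot == stat)) / n_boot
    prop = min(max(prop, 1.0 / (n_boot + 1)), 1.0 - 1.0 / (n_boot + 1))
    z0 = sps.norm.ppf(prop)

    # acceleration from the jackknife
    jack = (d.sum() - d) / (n - 1)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    out = []
    for q in (alpha, 1.0 - alpha):
        zq = sps.norm.ppf(q)
        adj = z0 + (z0 + zq) / (1.0 - a * (z0 + zq))
        out.append(float(np.percentile(boot, 100.0 * sps.norm.cdf(adj))))
    return out[0], out[1]


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, m * p)


def _f_ratio(ss_eff: float, df_eff: int, ss_err: float, df_err: int,
             ss_tot: float) -> float:
    """F with guards for rounding residue in degenerate (zero-SS) designs."""
    tiny = 1e-14 * max(ss_tot, 1.0)
    if ss_err <= tiny:
        return 0.0 if ss_eff <= tiny else np.inf
    return max((ss_eff / df_eff) / (ss_err / df_err), 0.0)


@dataclass
class RmAnovaResult:
    effects: dict = field(default_factory=dict)
    # each entry: {"F": float, "df_effect": int, "df_error": int, "p": float,
    #             "ss_effect": float, "ss_error": float}

    def __getitem__(self, key: str) -> dict:
        return self.effects[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"effect": k, **v} for k, v in self.effects.items()]
        ).set_index("effect")


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: str | list[str],
    subject: str,
) -> RmAnovaResult:
    """Repeated-measures ANOVA on a balanced complete within-subject design.

    One or two within-subject factors.  Each effect is tested against its own
    interaction with subjects: F = MS_effect / MS_(effect x subject), the
    standard fully-within partition.  Replicates inside a subject x cell are
    averaged first.  Missing cells raise a design error naming them.
    """
    factors = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(factors) <= 2:
        raise ValueError("within must name one or two factors")
    df = table[[subject, *factors, dv]].copy()
    cell = df.groupby([subject, *factors], observed=True)[dv].mean().reset_index()

    subjects = cell[subject].unique()
    levels = [cell[f].unique() for f in factors]
    expected = len(subjects) * int(np.prod([len(l) for l in levels]))
    if len(cell) != expected:
        counts = cell.groupby([subject], observed=True).size()
        missing = counts[counts != int(np.prod([len(l) for l in levels]))]
        raise ValueError(
            "design is not balanced/complete; offending subject(s): "
            + ", ".join(map(str, missing.index.tolist() or ["<cell mismatch>"]))
        )

    y = cell.set_index([subject, *factors])[dv]
    grand = y.mean()
    n_s = len(subjects)
    res = RmAnovaResult()

    if len(factors) == 1:
        f1 = factors[0]
        a = len(levels[0])
        m_a = y.groupby(level=f1).mean()
        m_s = y.groupby(level=subject).mean()
        ss_a = n_s * float(((m_a - grand) ** 2).sum())
        ss_s = a * float(((m_s - grand) ** 2).sum())
        ss_tot = float(((y - grand) ** 2).sum())
        ss_err = ss_tot - ss_a - ss_s
        df_a, df_e = a - 1, (a - 1) * (n_s - 1)
        F = _f_ratio(ss_a, df_a, ss_err, df_e, ss_tot)
        res.effects[f1] = {
            "F": F, "df_effect": df_a, "df_error": df_e,
            "p": float(sps.f.sf(F, df_a, df_e)),
            "ss_effect": ss_a, "ss_error": ss_err,
        }
        return res

    f1, f2 = factors
    a, b = len(levels[0]), len(levels[1])
    m_a = y.groupby(level=f1).mean()
    m_b = y.groupby(level=f2).mean()
    m_ab = y.groupby(level=[f1, f2]).mean()
    m_s = y.groupby(level=subject).mean()
    m_as = y.groupby(level=[subject, f1]).mean()
    m_bs = y.groupby(level=[subject, f2]).mean()

    ss_a = n_s * b * float(((m_a - grand) ** 2).sum())
    ss_b = n_s * a * float(((m_b - grand) ** 2).sum())
    ss_s = a * b * float(((m_s - grand) ** 2).sum())
    ss_ab = n_s * float(((m_ab - grand) ** 2).sum()) - ss_a - ss_b
    ss_as = b * float(((m_as - grand) ** 2).sum()) - ss_a - ss_s
    ss_bs = a * float(((m_bs - grand) ** 2).sum()) - ss_b - ss_s
    ss_tot = float(((y - grand) ** 2).sum())
    ss_abs = ss_tot - ss_a - ss_b - ss_s - ss_ab - ss_as - ss_bs

    for name, ss_eff, df_eff, ss_err, df_err in (
        (f1, ss_a, a - 1, ss_as, (a - 1) * (n_s - 1)),
        (f2, ss_b, b - 1, ss_bs, (b - 1) * (n_s - 1)),
        (f"{f1}*{f2}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n_s - 1)),
    ):
        F = _f_ratio(ss_eff, df_eff, ss_err, df_err, ss_tot)
        res.effects[name] = {
            "F": F, "df_effect": df_eff, "df_error": df_err,
            "p": float(sps.f.sf(F, df_eff, df_err)),
            "ss_effect": ss_eff, "ss_error": ss_err,
        }
    return res


@dataclass
class RmCorrResult:
    r: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    slope: float
    n_obs: int
    n_subjects: int


def rm_corr(table: pd.DataFrame, x: str, y: str, subject: str) -> RmCorrResult:
    """Repeated-measures correlation: the common within-subject association.

    ANCOVA with subject-specific intercepts and a shared slope, equivalent to
    regressing within-subject-centered y on within-subject-centered x with
    df = n_obs - n_subjects - 1.  r carries the slope's sign and magnitude
    sqrt(SS_slope / (SS_slope + SS_residual)); the CI is a Fisher-z interval.

    Subjects contributing fewer than 2 complete observations are dropped.
    """
    df = table[[subject, x, y]].dropna()
    counts = df.groupby(subject, observed=True).size()
    keep = counts[counts >= 2].index
    df = df[df[subject].isin(keep)]
    n_subj = df[subject].nunique()
    if n_subj < 3:
        raise ValueError(f"need at least 3 subjects with >=2 observations, got {n_subj}")

    xc = df[x] - df.groupby(subject, observed=True)[x].transform("mean")
    yc = df[y] - df.groupby(subject, observed=True)[y].transform("mean")
    sxx = float((xc**2).sum())
    if sxx == 0:
        raise ValueError("x has no within-subject variance")
    slope = float((xc * yc).sum()) / sxx
    ss_effect = slope**2 * sxx
    ss_error = float(((yc - slope * xc) ** 2).sum())

    n_obs = len(df)
    dof = n_obs - n_subj - 1
    r = float(np.sign(slope) * np.sqrt(ss_effect / (ss_effect + ss_error)))
    F = (ss_effect / 1.0) / (ss_error / dof) if ss_error > 0 else np.inf
    p = float(sps.f.sf(F, 1, dof))

    # Fisher z interval with the ANCOVA degrees of freedom
    se = 1.0 / np.sqrt(max(dof - 1, 1))
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zcrit = sps.norm.ppf(0.975)
    ci_low, ci_high = np.tanh(zr - zcrit * se), np.tanh(zr + zcrit * se)
    return RmCorrResult(
        r=r, df=dof, p=p,
        ci_low=float(ci_low), ci_high=float(ci_high),
        slope=slope, n_obs=n_obs, n_subjects=n_subj,
    )


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum test (normal approximation with tie correction)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def spearman_pairwise(table: pd.DataFrame, columns: list[str] | None = None):
    """Spearman rank correlations for every column pair, pairwise-complete.

    Returns ``(rho, pvals)`` DataFrames.  Pairs with fewer than 3 complete
    rows, or with a constant column, get NaN entries.
    """
    cols = columns or [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pvals = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    np.fill_diagonal(pvals.values, np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[cols[i], cols[j]]].dropna()
            if len(sub) < 3 or sub[cols[i]].nunique() == 1 or sub[cols[j]].nunique() == 1:
                r = p = np.nan
            else:
                r, p = sps.spearmanr(sub[cols[i]], sub[cols[j]])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    return rho, pvals
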