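"""Inferential statistics for within-subject p(No) comparisons.

Paired t-tests with Cohen's d and a default-prior (JZS) Bayes factor,
balanced repeated-measures ANOVAs (one-way and 3x3) with each effect
tested against its own participant-by-effect interaction, and Tukey HSD
post hocs on the studentized-range distribution.

Cohen's d for paired data is the mean difference divided by the standard
deviation of the differences (so |d| = |t| / sqrt(n)).  The Bayes factor
integrates a Cauchy prior with scale ``r`` (default sqrt(2)/2) over the
standardized effect size of the one-sample t on the paired differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import integrate, stats

DEFAULT_R_SCALE = math.sqrt(2) / 2


@dataclass
class TestResult:
    """One statistical comparison: statistic, df, p, effect size, BF10."""

    statistic: float
    df: Union[float, Tuple[float, float]]
    p_value: float
    effect_size: Optional[float] = None
    bf10: Optional[float] = None
    label: str = ""


def paired_t(
    x: Sequence[float],
    y: Sequence[float],
    label: str = "",
    bayes_factor: bool = False,
    r_scale: float = DEFAULT_R_SCALE,
) -> TestResult:
    """Two-sided paired-sample t-test with Cohen's d on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if diff.mean() != 0.0:
            raise ValueError("zero variance of non-zero differences")
        t, p, d = 0.0, 1.0, 0.0
    else:
        t = float(diff.mean() / (sd / math.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t), n - 1))
        d = float(diff.mean() / sd)
    bf = jzs_bf_paired(t, n, r_scale) if bayes_factor else None
    return TestResult(t, float(n - 1), p, effect_size=d, bf10=bf, label=label)


def jzs_bf_paired(t: float, n: int, r_scale: float = DEFAULT_R_SCALE) -> float:
    """JZS Bayes factor (BF10) for a one-sample / paired t statistic.

    Marginal likelihood under H1 integrates the noncentral-t density over a
    Cauchy(0, r) prior on the standardized effect size delta (ncp =
    delta * sqrt(n)); H0 is the central t.  Computed by adaptive quadrature.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if r_scale <= 0:
        raise ValueError("r_scale must be positive")
    df = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(delta, 0.0, r_scale)

    num, err = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    if num <= 0 or not math.isfinite(num) or err > max(1e-8, 1e-4 * num):
        raise RuntimeError("Bayes factor quadrature failed to converge")
    den = stats.t.pdf(t, df)
    return float(num / den)


@dataclass
class AnovaResult:
    """Effects, marginal means, and Tukey tables of one rm-ANOVA."""

    effects: Dict[str, TestResult]
    marginal_means: pd.DataFrame
    tukey: Dict[str, pd.DataFrame]
    error_terms: Dict[str, Tuple[float, float]] = field(default_factory=dict)


def _check_complete(wide: pd.DataFrame) -> None:
    if wide.isna().any().any():
        missing = wide.stack(dropna=False)
        raise ValueError(
            f"incomplete design: missing cells {list(missing[missing.isna()].index)[:10]}"
        )


def rm_anova_oneway(
    wide: pd.DataFrame, alpha: float = 0.05, tukey_posthoc: bool = True
) -> AnovaResult:
    """Balanced one-way within-subjects ANOVA on a participant x condition frame.

    F tests the condition effect against the participant-by-condition
    interaction: df = (k-1, (k-1)(n-1)).  Tukey post hocs use that same
    error term.
    """
    _check_complete(wide)
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    grand = y.mean()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df_cond, max(ss_err, 0.0) / df_err
    f = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0 else math.inf)
    p = float(stats.f.sf(f, df_cond, df_err)) if math.isfinite(f) else 0.0

    means = pd.DataFrame(
        {
            "condition": wide.columns,
            "mean": y.mean(axis=0),
            "se": y.std(axis=0, ddof=1) / math.sqrt(n),
        }
    )
    effect = TestResult(float(f), (float(df_cond), float(df_err)), p, label="condition")
    tuk = {}
    if tukey_posthoc:
        tuk["condition"] = tukey(
            dict(zip(wide.columns, y.mean(axis=0))), ms_err, df_err, n, alpha=alpha
        )
    return AnovaResult(
        effects={"condition": effect},
        marginal_means=means,
        tukey=tuk,
        error_terms={"condition": (ms_err, float(df_err))},
    )


def rm_anova_3x3(
    cells: pd.DataFrame,
    factor_a: str = "relevant",
    factor_b: str = "irrelevant",
    value: str = "p_no",
    alpha: float = 0.05,
) -> AnovaResult:
    """Balanced two-factor within-subjects ANOVA (any k x m, typically 3x3).

    ``cells`` is tidy: one row per participant x A-level x B-level with the
    cell mean in ``value``.  Each effect is tested against its own
    participant interaction: A against AxS, B against BxS, AxB against
    AxBxS.  Tukey post hocs on both main effects use the corresponding
    error terms.
    """
    wide = cells.pivot_table(
        index="participant_id", columns=[factor_a, factor_b], values=value
    )
    _check_complete(wide)
    a_levels = sorted(wide.columns.get_level_values(0).unique())
    b_levels = sorted(wide.columns.get_level_values(1).unique())
    n = len(wide)
    ka, kb = len(a_levels), len(b_levels)
    y = np.empty((n, ka, kb))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            y[:, i, j] = wide[(a, b)].to_numpy(dtype=float)

    grand = y.mean()
    mean_s = y.mean(axis=(1, 2))
    mean_a = y.mean(axis=(0, 2))
    mean_b = y.mean(axis=(0, 1))
    mean_ab = y.mean(axis=0)
    mean_as = y.mean(axis=2)
    mean_bs = y.mean(axis=1)

    ss_a = n * kb * ((mean_a - grand) ** 2).sum()
    ss_b = n * ka * ((mean_b - grand) ** 2).sum()
    ss_s = ka * kb * ((mean_s - grand) ** 2).sum()
    ss_ab = n * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_as = kb * ((mean_as - mean_s[:, None] - mean_a[None, :] + grand) ** 2).sum()
    ss_bs = ka * ((mean_bs - mean_s[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_abs = ss_total - ss_a - ss_b - ss_s - ss_ab - ss_as - ss_bs

    def effect(ss_eff, df_eff, ss_err, df_err, label) -> TestResult:
        ms_eff = ss_eff / df_eff
        ms_err = max(ss_err, 0.0) / df_err
        f = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else math.inf)
        p = float(stats.f.sf(f, df_eff, df_err)) if math.isfinite(f) else 0.0
        return TestResult(float(f), (float(df_eff), float(df_err)), p, label=label)

    df_a, df_b, df_ab = ka - 1, kb - 1, (ka - 1) * (kb - 1)
    df_as, df_bs, df_abs = df_a * (n - 1), df_b * (n - 1), df_ab * (n - 1)
    effects = {
        factor_a: effect(ss_a, df_a, ss_as, df_as, factor_a),
        factor_b: effect(ss_b, df_b, ss_bs, df_bs, factor_b),
        "interaction": effect(ss_ab, df_ab, ss_abs, df_abs, f"{factor_a} x {factor_b}"),
    }
    error_terms = {
        factor_a: (max(ss_as, 0.0) / df_as, float(df_as)),
        factor_b: (max(ss_bs, 0.0) / df_bs, float(df_bs)),
        "interaction": (max(ss_abs, 0.0) / df_abs, float(df_abs)),
    }

    mm = []
    for a, m in zip(a_levels, mean_a):
        mm.append({"factor": factor_a, "level": a, "mean": m})
    for b, m in zip(b_levels, mean_b):
        mm.append({"factor": factor_b, "level": b, "mean": m})
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            mm.append({"factor": "cell", "level": f"{a}/{b}", "mean": mean_ab[i, j]})
    mm_df = pd.DataFrame(mm)
    se_a = [wide.xs(a, axis=1, level=0).mean(axis=1).std(ddof=1) / math.sqrt(n) for a in a_levels]
    se_b = [wide.xs(b, axis=1, level=1).mean(axis=1).std(ddof=1) / math.sqrt(n) for b in b_levels]
    se_cells = [
        wide[(a, b)].std(ddof=1) / math.sqrt(n) for a in a_levels for b in b_levels
    ]
    mm_df["se"] = list(se_a) + list(se_b) + se_cells

    tuk = {
        factor_a: tukey(
            dict(zip(a_levels, mean_a)), *error_terms[factor_a], n * kb, alpha=alpha
        ),
        factor_b: tukey(
            dict(zip(b_levels, mean_b)), *error_terms[factor_b], n * ka, alpha=alpha
        ),
    }
    return AnovaResult(effects=effects, marginal_means=mm_df, tukey=tuk,
                       error_terms=error_terms)


def tukey(
    means: Dict[str, float],
    error_ms: float,
    error_df: float,
    n_per_mean: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons via the studentized-range distribution.

    ``q = |m_i - m_j| / sqrt(MS_err / n)`` with the adjusted p from the
    studentized range with ``k`` means and ``error_df`` degrees of freedom.
    The result frame carries a ``chain`` attribute summarizing the ordering
    of the means with ``>`` (adjusted p < alpha) or ``=`` links.
    """
    if error_df <= 0:
        raise ValueError("error_df must be positive")
    if len(means) < 2:
        raise ValueError("need at least two means")
    k = len(means)
    se = math.sqrt(max(error_ms, 0.0) / n_per_mean)
    rows = []
    sig: Dict[frozenset, bool] = {}
    for (la, ma), (lb, mb) in combinations(means.items(), 2):
        if se == 0.0:
            p_adj = 1.0 if ma == mb else 0.0
            q = math.inf if ma != mb else 0.0
        else:
            q = abs(ma - mb) / se
            p_adj = float(stats.studentized_range.sf(q, k, error_df))
        rows.append(
            {"pair": f"{la} - {lb}", "diff": ma - mb, "q": q, "p_adj": p_adj}
        )
        sig[frozenset((la, lb))] = p_adj < alpha
    out = pd.DataFrame(rows)
    ordered = sorted(means, key=means.get, reverse=True)
    links = [
        " > " if sig[frozenset((a, b))] else " = "
        for a, b in zip(ordered, ordered[1:])
    ]
    chain = str(ordered[0]) + "".join(
        l + str(lab) for l, lab in zip(links, ordered[1:])
    )
    out.attrs["chain"] = chain
    return out
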