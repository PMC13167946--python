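"""Trial statistics for the clinical scales.

Implements the analysis plan of a two-arm pre/post trial: Shapiro-Wilk
normality gating, paired t / Wilcoxon signed-rank within groups,
independent t / Mann-Whitney U between groups, Cohen's d (parametric)
or the rank effect size r = |Z|/sqrt(N) (nonparametric), Pearson
chi-square for 2x2 tables without continuity correction, and the
noncentral-t power analysis with multiplicative dropout inflation.

A "reproduction mode" recovers change-score standard deviations from
printed 95% confidence intervals, so published effect sizes can be
re-derived from summary tables alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PairedResult",
    "BetweenResult",
    "normality_gate",
    "paired_change",
    "between_group_change",
    "between_group_change_from_ci",
    "sd_from_ci",
    "cohens_d_ci",
    "chi_square_2x2",
    "power_two_sample_t",
    "sample_size_two_t",
    "inflate_dropout",
    "proportion_pct",
]


@dataclass(frozen=True)
class PairedResult:
    n: int
    mean_change: float
    ci: tuple[float, float]
    test: str  # "paired-t" | "wilcoxon"
    statistic: float
    p: float
    effect_size: float  # d_z for paired-t, |Z|/sqrt(n) for wilcoxon
    flagged: str | None = None


@dataclass(frozen=True)
class BetweenResult:
    n1: int
    n2: int
    mean_diff: float
    test: str  # "independent-t" | "mann-whitney"
    statistic: float
    p: float
    effect_size: float  # Cohen's d (signed) or r = |Z|/sqrt(N)
    effect_ci: tuple[float, float]


def normality_gate(x, alpha: float = 0.05) -> tuple[str, float]:
    """Shapiro-Wilk gate: 'parametric' iff p >= alpha."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality gate needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality undefined")
    _, p = stats.shapiro(x)
    return ("parametric" if p >= alpha else "nonparametric"), float(p)


def _t_ci(diff: np.ndarray, conf: float = 0.95) -> tuple[float, float]:
    n = diff.size
    se = diff.std(ddof=1) / math.sqrt(n)
    tcrit = stats.t.ppf(0.5 + conf / 2, n - 1)
    m = diff.mean()
    return (m - tcrit * se, m + tcrit * se)


def paired_change(pre, post, force: str | None = None, conf: float = 0.95) -> PairedResult:
    """Within-group change: mean, t-based 95% CI, gated paired test.

    The CI is always the t interval on the change scores (that is how
    the trial reports "Change mean (95% CI)"); the hypothesis test is a
    paired t or a Wilcoxon signed-rank depending on the Shapiro-Wilk
    gate (exact Wilcoxon for n <= 10 without ties, normal approximation
    with continuity correction otherwise). All-zero differences are
    returned flagged with t = 0, p = 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D and paired")
    if pre.size < 2:
        raise ValueError("need n >= 2 pairs")
    if np.any(np.isnan(pre)) or np.any(np.isnan(post)):
        raise ValueError("paired data must be complete")
    d = post - pre
    n = d.size
    mean = float(d.mean())
    if np.all(d == 0):
        return PairedResult(n, 0.0, (0.0, 0.0), "paired-t", 0.0, 1.0, 0.0,
                            flagged="all-zero differences")
    if force is None:
        try:
            gate, _ = normality_gate(d)
        except ValueError:
            gate = "parametric"
    else:
        gate = force
    sd = d.std(ddof=1)
    if sd == 0:  # constant nonzero differences: complete separation
        return PairedResult(n, mean, (mean, mean), "paired-t",
                            math.copysign(math.inf, mean), 0.0,
                            math.copysign(math.inf, mean),
                            flagged="constant differences")
    ci = _t_ci(d, conf)
    if gate == "parametric":
        t = mean / (sd / math.sqrt(n))
        p = 2 * stats.t.sf(abs(t), n - 1)
        return PairedResult(n, mean, ci, "paired-t", float(t), float(p), float(mean / sd))
    method = "exact" if (n <= 10 and np.unique(np.abs(d[d != 0])).size == np.sum(d != 0)) else "approx"
    res = stats.wilcoxon(d, method=method, correction=(method == "approx"))
    z = stats.norm.isf(res.pvalue / 2) * np.sign(mean)
    return PairedResult(n, mean, ci, "wilcoxon", float(res.statistic), float(res.pvalue),
                        float(abs(z) / math.sqrt(n)))


def sd_from_ci(ci_low: float, ci_high: float, n: int, conf: float = 0.95) -> float:
    """Invert a t-based mean CI to the underlying sample sd (df = n-1)."""
    tcrit = stats.t.ppf(0.5 + conf / 2, n - 1)
    return (ci_high - ci_low) / 2 * math.sqrt(n) / tcrit


def cohens_d_ci(d: float, n1: int, n2: int, conf: float = 0.95) -> tuple[float, float]:
    """CI for Cohen's d by noncentral-t inversion (pivot on the ncp)."""
    scale = math.sqrt(1 / n1 + 1 / n2)
    t_obs = d / scale
    df = n1 + n2 - 2
    lo_q, hi_q = 0.5 + conf / 2, 0.5 - conf / 2

    def bound(target_q: float) -> float:
        def f(ncp):
            val = stats.nct.cdf(t_obs, df, ncp)
            if np.isnan(val):  # far tails can underflow inside scipy
                val = 0.0 if ncp > t_obs else 1.0
            return val - target_q

        width = 20.0 + 2.0 * abs(t_obs)  # ncp CI grows with |t| for large effects
        return optimize.brentq(f, t_obs - width, t_obs + width)

    return (bound(lo_q) * scale, bound(hi_q) * scale)


def between_group_change(g1, g2, force: str | None = None) -> BetweenResult:
    """Between-group comparison of change scores.

    Parametric route (both samples pass the gate): pooled-variance
    independent t with signed Cohen's d = (m1-m2)/s_pooled and a
    noncentral-t CI for d. Nonparametric route: Mann-Whitney U with the
    tie-corrected normal approximation and r = |Z|/sqrt(N).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("need n >= 2 per group")
    n1, n2 = g1.size, g2.size
    mean_diff = float(g1.mean() - g2.mean())
    if force is None:
        try:
            gate = "parametric" if (
                normality_gate(g1)[0] == "parametric" and normality_gate(g2)[0] == "parametric"
            ) else "nonparametric"
        except ValueError:
            gate = "parametric"
    else:
        gate = force
    if gate == "parametric":
        v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0:
            if mean_diff == 0:
                return BetweenResult(n1, n2, 0.0, "independent-t", 0.0, 1.0, 0.0, (0.0, 0.0))
            raise ValueError("zero pooled variance with nonzero mean difference")
        sp = math.sqrt(sp2)
        t = mean_diff / (sp * math.sqrt(1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        d = mean_diff / sp
        return BetweenResult(n1, n2, mean_diff, "independent-t", float(t), float(p),
                             float(d), cohens_d_ci(d, n1, n2))
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    # report the (signed) normal-approximation Z, as in a "t/Z" column
    z = stats.norm.isf(min(res.pvalue, 1.0) / 2) * np.sign(mean_diff)
    if res.pvalue >= 1.0:
        z = 0.0
    r = abs(z) / math.sqrt(n1 + n2)
    return BetweenResult(n1, n2, mean_diff, "mann-whitney", float(z),
                         float(res.pvalue), float(r), (float("nan"), float("nan")))


def between_group_change_from_ci(
    mean1: float, ci1: tuple[float, float], n1: int,
    mean2: float, ci2: tuple[float, float], n2: int,
) -> BetweenResult:
    """Reproduction mode: effect size from printed change means and CIs.

    Change-score sds are recovered by inverting the t interval, then
    Cohen's d and its noncentral-t CI follow as in the raw-data route.
    """
    s1 = sd_from_ci(*ci1, n1)
    s2 = sd_from_ci(*ci2, n2)
    sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    mean_diff = mean1 - mean2
    d = mean_diff / sp
    t = mean_diff / (sp * math.sqrt(1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return BetweenResult(n1, n2, mean_diff, "independent-t", float(t), float(p),
                         float(d), cohens_d_ci(d, n1, n2))


def chi_square_2x2(table) -> tuple[float, float, int]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p from chi2(df=1).
    """
    tbl = np.asarray(table, dtype=float)
    if tbl.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(tbl < 0) or np.any(tbl != np.floor(tbl)):
        raise ValueError("cell counts must be nonnegative integers")
    a, b = tbl[0]
    c, d = tbl[1]
    n = tbl.sum()
    if n == 0:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero marginal: statistic undefined")
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(chi2), float(stats.chi2.sf(chi2, 1)), 1


def power_two_sample_t(n_per_group: int, effect_size: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t-test at n per group.

    Noncentral-t with df = 2n - 2 and ncp = d * sqrt(n/2).
    """
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = abs(effect_size) * math.sqrt(n_per_group / 2)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def sample_size_two_t(
    mean1: float, mean2: float, sd: float,
    alpha: float = 0.05, power: float = 0.95, max_n: int = 1_000_000,
) -> int:
    """Smallest per-group n reaching the target power (two-tailed t)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if mean1 == mean2:
        raise ValueError("means must differ")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    d = abs(mean1 - mean2) / sd
    n = 2
    while power_two_sample_t(n, d, alpha) < power:
        n += 1
        if n > max_n:
            raise ValueError("target power unreachable within max_n")
    return n


def inflate_dropout(n_per_group: int, rate: float) -> tuple[int, int]:
    """Inflate per-group n for anticipated dropout: ceil(n * (1 + rate))."""
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must be in [0, 1)")
    n_inflated = math.ceil(n_per_group * (1 + rate))
    return n_inflated, 2 * n_inflated


def proportion_pct(k: int, n: int, decimals: int = 1) -> float:
    """Percentage reporting helper (e.g. blinding guess rates)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, decimals)
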