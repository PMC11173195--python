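"""Behavioral statistics: t tests, effect sizes, JZS Bayes factors, ICC.

The Bayes factor is the default one-sample (paired) JZS form with a Cauchy
prior of scale r on standardized effect size delta:

    BF10 = [ integral_0^inf (1+Ng)^(-1/2)
             (1 + t^2 / ((1+Ng) nu))^(-(nu+1)/2) pi(g) dg ]
           / (1 + t^2/nu)^(-(nu+1)/2)

with pi(g) the inverse-gamma(1/2, r^2/2) density induced by the Cauchy(0, r)
prior, nu the degrees of freedom, and N the (effective) sample size.  The
integral is evaluated by adaptive quadrature in log space; the natural log
of BF10 is returned.  The paired effect size is d_z = mean(diff)/sd(diff) =
t/sqrt(n).  Test-retest reliability is the two-way random-effects,
absolute-agreement, single-measure intraclass correlation (ICC2) with an
F-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "TestResult",
    "IccResult",
    "paired_t",
    "two_sample_t",
    "jzs_lnbf",
    "icc_testretest",
    "affect_desirability_report",
]

DEFAULT_RSCALE = np.sqrt(2.0) / 2.0


@dataclass
class TestResult:
    t: float
    df: float
    d: float
    ln_bf10: float
    p: float

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")
        if not np.isfinite(self.ln_bf10):
            raise ValueError("ln BF10 is not finite")


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    variant: str = "ICC2 (two-way random, absolute agreement, single measure)"

    def __post_init__(self) -> None:
        if not self.ci_low <= self.icc <= self.ci_high:
            raise ValueError("ICC estimate outside its confidence interval")
        if self.icc > 1:
            raise ValueError("ICC cannot exceed 1")


def jzs_lnbf(t: float, n: int, rscale: float = DEFAULT_RSCALE, n2: int | None = None) -> float:
    """Natural-log JZS Bayes factor BF10 for a t statistic.

    One-sample/paired when ``n2`` is None (N = n, df = n-1); two-sample
    otherwise (effective N = n*n2/(n+n2), df = n+n2-2).  Values above
    ln BF10 ~ 2.2 are conventionally read as overwhelming evidence for the
    alternative.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if rscale <= 0:
        raise ValueError("rscale must be positive")
    if n2 is None:
        N, nu = float(n), float(n - 1)
    else:
        N, nu = n * n2 / (n + n2), float(n + n2 - 2)
    t = float(t)
    r2 = rscale**2
    log_prior_const = 0.5 * np.log(r2 / 2.0) - special.gammaln(0.5)

    def ratio(g: float) -> float:
        # likelihood ratio against the g=0 (null-scaled) term, times pi(g)
        lr = -0.5 * np.log1p(N * g) - (nu + 1.0) / 2.0 * (
            np.log1p(t * t / ((1.0 + N * g) * nu)) - np.log1p(t * t / nu)
        )
        lp = log_prior_const - 1.5 * np.log(g) - r2 / (2.0 * g)
        return np.exp(lr + lp)

    val, err = integrate.quad(ratio, 0.0, np.inf, limit=300)
    if val <= 0 or (err / val) > 1e-4:
        raise RuntimeError(
            f"JZS quadrature did not converge (value {val:.3e}, error {err:.3e})"
        )
    return float(np.log(val))


def paired_t(x: np.ndarray, y: np.ndarray, rscale: float = DEFAULT_RSCALE) -> TestResult:
    """Paired t test with d_z effect size and JZS ln BF10.

    d_z = mean(x - y) / sd(x - y) = t / sqrt(n), so the effect size and the
    t statistic are tied by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = x - y
    if diff.std(ddof=1) < 1e-300:
        raise ValueError("zero-variance differences: t undefined")
    n = diff.size
    res = stats.ttest_rel(x, y)
    t = float(res.statistic)
    return TestResult(
        t=t, df=float(n - 1), d=t / np.sqrt(n),
        ln_bf10=jzs_lnbf(t, n, rscale), p=float(res.pvalue),
    )


def two_sample_t(a: np.ndarray, b: np.ndarray, rscale: float = DEFAULT_RSCALE) -> TestResult:
    """Pooled-variance Student t with Cohen's d and two-sample JZS ln BF10."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 < 1e-300:
        raise ValueError("zero pooled variance: t undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    t = float(res.statistic)
    return TestResult(
        t=t,
        df=float(na + nb - 2),
        d=(a.mean() - b.mean()) / np.sqrt(sp2),
        ln_bf10=jzs_lnbf(t, na, rscale, n2=nb),
        p=float(res.pvalue),
    )


def icc_testretest(session1: np.ndarray, session2: np.ndarray) -> IccResult:
    """ICC2 (absolute agreement, single measure) between two sessions.

    Items are the targets, sessions the raters, following the standard
    two-way random-effects decomposition; the 95% CI is the F-based one.
    Delegates to pingouin's intraclass_corr.
    """
    import pingouin as pg  # deferred: pingouin import is slow

    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape or s1.size < 3:
        raise ValueError("need matched sessions with at least 3 items")
    if s1.std() < 1e-300 and s2.std() < 1e-300 and np.allclose(s1, s2) and np.allclose(s1, s1[0]):
        raise ValueError("degenerate ratings: no variance across items")
    n = s1.size
    df = pd.DataFrame(
        {
            "item": np.tile(np.arange(n), 2),
            "session": np.repeat(["pre", "post"], n),
            "rating": np.concatenate([s1, s2]),
        }
    )
    res = pg.intraclass_corr(df, targets="item", raters="session", ratings="rating")
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    icc = float(row["ICC"])
    lo, hi = (float(v) for v in row[ci_col])
    if not (np.isfinite(lo) and np.isfinite(hi)):
        lo = hi = icc  # perfect-agreement limit: the F-based CI degenerates
    return IccResult(icc=icc, ci_low=min(lo, icc), ci_high=max(hi, icc))


def affect_desirability_report(ratings: pd.DataFrame, concept_set: pd.DataFrame) -> dict:
    """Full behavioral analysis of a long-format ratings table.

    Per dimension: a paired t test of each subject's mean rating for
    concepts defined as high vs low on that dimension (averaged over
    sessions), plus test-retest ICC over the subject x concept ratings
    between the pre and post sessions.
    """
    meta = concept_set.set_index("concept_id")
    out: dict = {}
    for dim in ("affect", "desirability"):
        sub = ratings[ratings["dimension"] == dim].copy()
        sub["level"] = meta.loc[sub["concept_id"], dim].to_numpy()
        per_subj = sub.pivot_table(index="subject_id", columns="level", values="rating")
        test = paired_t(per_subj["high"].to_numpy(), per_subj["low"].to_numpy())
        piv = sub.pivot_table(
            index=["subject_id", "concept_id"], columns="session", values="rating"
        )
        icc = icc_testretest(piv["pre"].to_numpy(), piv["post"].to_numpy())
        out[dim] = {
            "t": test.t,
            "df": test.df,
            "d_z": test.d,
            "ln_bf10": test.ln_bf10,
            "p": test.p,
            "icc": icc.icc,
            "icc_ci": [icc.ci_low, icc.ci_high],
            "mean_high": float(per_subj["high"].mean()),
            "mean_low": float(per_subj["low"].mean()),
        }
    return out
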