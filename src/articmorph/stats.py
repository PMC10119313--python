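"""Cohort statistics: summaries, t-tests, normality, ANOVA, Games-Howell.

Thin, explicit wrappers around scipy/statsmodels plus a hand-implemented
Games-Howell post-hoc (Welch-type standard errors with studentized-range
p-values), which corrects for unequal group variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps

__all__ = [
    "StatResult",
    "summary_ci",
    "t_test",
    "shapiro_wilk",
    "three_way_anova",
    "games_howell",
]


@dataclass(frozen=True)
class StatResult:
    test: str
    estimate: float
    statistic: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float
    tail: str = "two-sided"

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def summary_ci(values, confidence: float = 0.95) -> StatResult:
    """Mean, sample SD and t-based confidence interval of one sample."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    half = tcrit * sd / np.sqrt(n)
    return StatResult(
        test="summary",
        estimate=mean,
        statistic=sd,
        df=n - 1,
        p_value=np.nan,
        ci_low=mean - half,
        ci_high=mean + half,
    )


def t_test(
    values,
    mu0: float = 0.0,
    mode: str = "one_sample_two_tailed",
    direction: str | None = None,
    paired_with=None,
) -> StatResult:
    """One-sample (one- or two-tailed) or specimen-paired t-test.

    For the one-tailed mode the direction defaults to the side of ``mu0`` the
    sample mean lies on.  A paired test with zero variance of differences and
    zero mean difference reports p = 1 by convention.
    """
    x = np.asarray(values, dtype=float)
    if mode == "paired":
        if paired_with is None:
            raise ValueError("paired mode needs a second sample")
        y = np.asarray(paired_with, dtype=float)
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        x = x - y
        mu = 0.0
    else:
        mu = mu0
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / np.sqrt(n)
    df = n - 1
    if se == 0.0:
        t = 0.0 if mean == mu else np.inf * np.sign(mean - mu)
    else:
        t = (mean - mu) / se
    p_two = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if mode in ("one_sample_two_tailed", "paired"):
        p, tail = p_two, "two-sided"
    elif mode == "one_sample_one_tailed":
        if direction is None:
            direction = "greater" if mean >= mu else "less"
        if direction == "greater":
            p = float(sps.t.sf(t, df))
        elif direction == "less":
            p = float(sps.t.cdf(t, df))
        else:
            raise ValueError(f"unknown direction {direction!r}")
        tail = direction
    else:
        raise ValueError(f"unknown mode {mode!r}")
    tcrit = float(sps.t.ppf(0.975, df))
    return StatResult(
        test=f"t_{mode}",
        estimate=mean,
        statistic=float(t),
        df=df,
        p_value=min(p, 1.0),
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        tail=tail,
    )


def shapiro_wilk(values) -> StatResult:
    """Shapiro-Wilk normality test (Royston approximation, 3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 to 5000 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance sample")
    w, p = sps.shapiro(x)
    return StatResult(
        test="shapiro_wilk",
        estimate=float(x.mean()),
        statistic=float(w),
        df=len(x),
        p_value=float(p),
        ci_low=np.nan,
        ci_high=np.nan,
    )


def three_way_anova(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, str, str],
) -> pd.DataFrame:
    """Main-effects three-way ANOVA with Type II sums of squares.

    ``table`` is tidy (one row per measurement); ``factors`` are column names
    (e.g. region/bone, specimen, side), all treated as categorical.  Returns
    the statsmodels ANOVA table with columns sum_sq, df, F, PR(>F).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    # internal column names avoid collisions with patsy syntax (e.g. "C")
    rename = {response: "_y", **{f: f"_f{i}" for i, f in enumerate(factors)}}
    df = table[[response, *factors]].rename(columns=rename).copy()
    for i, f in enumerate(factors):
        col = f"_f{i}"
        if df[col].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
        df[col] = df[col].astype(str)
    formula = "_y ~ " + " + ".join(f"C(_f{i})" for i in range(len(factors)))
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova.index = [*(f for f in factors), "Residual"]
    return anova


from functools import lru_cache


@lru_cache(maxsize=4096)
def _studentized_range_crit(k: int, df_rounded: float) -> float:
    return float(sps.studentized_range.ppf(0.95, k, df_rounded))


def games_howell(groups: list, labels: list | None = None) -> pd.DataFrame:
    """Games-Howell pairwise post-hoc comparisons.

    For each pair: Welch t statistic, Welch-Satterthwaite df, p from the
    studentized-range distribution with k groups at q = |t| * sqrt(2), and a
    CI from the same quantile.  Robust to unequal variances and sizes.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = list(range(k))
    means = [g.mean() for g in arrays]
    vars_ = [g.var(ddof=1) for g in arrays]
    ns = [len(g) for g in arrays]
    rows = []
    for i, j in combinations(range(k), 2):
        se2 = vars_[i] / ns[i] + vars_[j] / ns[j]
        se = np.sqrt(se2)
        diff = means[i] - means[j]
        if se == 0.0:
            t = 0.0 if diff == 0 else np.inf
            df = ns[i] + ns[j] - 2.0
        else:
            t = diff / se
            df = se2**2 / (
                (vars_[i] / ns[i]) ** 2 / (ns[i] - 1)
                + (vars_[j] / ns[j]) ** 2 / (ns[j] - 1)
            )
        q = abs(t) * np.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, df)) if np.isfinite(t) else 0.0
        # critical value varies slowly in df: cache on a rounded key
        qcrit = _studentized_range_crit(k, round(float(df), 1))
        half = qcrit / np.sqrt(2.0) * se
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": diff,
                "se": se,
                "t": t,
                "df": df,
                "p_value": min(p, 1.0),
                "ci_low": diff - half,
                "ci_high": diff + half,
            }
        )
    return pd.DataFrame(rows)
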