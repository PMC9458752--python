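"""Group-comparison statistics used throughout the toolkit.

Two-sample t tests can be computed either from raw values or from published
summary statistics (mean, SEM, n), which makes printed group summaries
directly checkable.  The repeated-measures two-way ANOVA is the classic
split-plot layout (one between-subjects factor, one within-subjects factor),
implemented directly because the usual repeated-measures helpers do not
accept a between-subjects factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM summary of one group, as results are reported."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("GroupSummary requires n >= 2")
        if self.sem < 0:
            raise ValueError("GroupSummary requires sem >= 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 values")
        return cls(mean=float(x.mean()), sem=float(x.std(ddof=1) / np.sqrt(x.size)),
                   n=int(x.size))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")


def _as_summary(group) -> GroupSummary:
    if isinstance(group, GroupSummary):
        return group
    return GroupSummary.from_values(group)


def t_test(a, b, method: str = "pooled") -> TestResult:
    """Two-sample t test from raw values or ``GroupSummary`` objects.

    ``method='pooled'`` is the classic Student t with pooled variance and
    integer df = n1 + n2 - 2 (the convention behind printed dfs such as
    t_13); ``method='welch'`` uses the Welch–Satterthwaite df.  Raw-value
    input is first reduced to a summary, so the two input modes agree
    exactly when the summary derives from the same values.
    """
    ga, gb = _as_summary(a), _as_summary(b)
    if method == "pooled":
        df = ga.n + gb.n - 2
        sp2 = ((ga.n - 1) * ga.sd**2 + (gb.n - 1) * gb.sd**2) / df
        se = np.sqrt(sp2 * (1.0 / ga.n + 1.0 / gb.n))
    elif method == "welch":
        va, vb = ga.sem**2, gb.sem**2
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (ga.n - 1) + vb**2 / (gb.n - 1))
    else:
        raise ValueError(f"unknown t-test method: {method!r}")
    if se == 0:
        t = 0.0 if ga.mean == gb.mean else np.inf * np.sign(ga.mean - gb.mean)
    else:
        t = (ga.mean - gb.mean) / se
    p = float(2.0 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(statistic=float(t), df=float(df), p=p,
                      method=f"two-sample t ({method})")


def ks_two_sample(x, y, exact: bool | None = None) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test on empirical CDFs.

    D = sup |ECDF_x - ECDF_y|; p from the asymptotic K-S distribution by
    default, exact small-sample computation when ``exact=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    mode = "exact" if exact else ("asymp" if exact is False else "auto")
    res = sps.ks_2samp(x, y, method=mode)
    return TestResult(statistic=float(res.statistic), df=float("nan"),
                      p=float(res.pvalue), method="two-sample K-S")


def mann_whitney(x, y) -> TestResult:
    """Mann-Whitney U test; exact enumeration for combined n <= 10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 10 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), df=float("nan"),
                      p=float(res.pvalue), method=f"Mann-Whitney U ({method})")


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m_eff = p.size if m is None else int(m)
    return np.clip(1.0 - (1.0 - p) ** m_eff, 0.0, 1.0)


def outlier_filter(values, z_max: float = 2.5):
    """Single-pass outlier removal at |z| > z_max from the full-sample mean.

    The z score uses the mean and sample SD of the complete input (not
    recomputed after removals), matching a fixed a-priori criterion.
    Returns ``(kept_values, removed_indices)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("outlier_filter requires at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy(), np.array([], dtype=int)
    z = (x - x.mean()) / sd
    removed = np.flatnonzero(np.abs(z) > z_max)
    kept = np.delete(x, removed)
    return kept, removed


def two_way_anova(data: pd.DataFrame, dv: str, between: str, within: str,
                  subject: str | None = None) -> dict[str, TestResult]:
    """Two-way ANOVA with an optional repeated-measures (within) factor.

    With ``subject`` given, computes the balanced split-plot decomposition:
    the between-subjects effect is tested against subjects-within-groups,
    the within effect and interaction against the residual within-subjects
    error.  Without ``subject``, an ordinary crossed two-way ANOVA
    (independent observations per cell) is fitted via OLS.

    Returns a dict with keys ``between``, ``within``, ``interaction``.
    """
    df = data[[dv, between, within] + ([subject] if subject else [])].dropna()
    if subject is None:
        return _crossed_anova(df, dv, between, within)
    return _split_plot_anova(df, dv, between, within, subject)


def _crossed_anova(df, dv, between, within):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    d = df.rename(columns={dv: "_y", between: "_a", within: "_b"})
    model = ols("_y ~ C(_a) * C(_b)", data=d).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    out = {}
    for key, row in (("between", "C(_a)"), ("within", "C(_b)"),
                     ("interaction", "C(_a):C(_b)")):
        r = tab.loc[row]
        out[key] = TestResult(statistic=float(r["F"]), df=float(r["df"]),
                              p=float(r["PR(>F)"]), method="two-way ANOVA")
    return out


def _split_plot_anova(df, dv, between, within, subject):
    # balanced design required: every subject observed at every within level
    counts = df.groupby([subject, within], observed=True)[dv].count()
    n_levels = df[within].nunique()
    per_subj = df.groupby(subject, observed=True)[within].nunique()
    if (counts != 1).any() or (per_subj != n_levels).any():
        raise ValueError("unsupported design: need exactly one observation "
                         "per subject per within level")
    subj_groups = df.groupby(subject, observed=True)[between].nunique()
    if (subj_groups != 1).any():
        raise ValueError("each subject must belong to exactly one group")
    n_per_group = df.groupby(between, observed=True)[subject].nunique()
    if n_per_group.nunique() != 1:
        raise ValueError("unsupported design: unequal group sizes")

    y = df[dv].astype(float)
    grand = y.mean()
    a_levels = df[between].unique()
    b_levels = df[within].unique()
    n_a, n_b = len(a_levels), len(b_levels)
    n_subj = df[subject].nunique()

    mean_a = df.groupby(between, observed=True)[dv].mean()
    mean_b = df.groupby(within, observed=True)[dv].mean()
    mean_ab = df.groupby([between, within], observed=True)[dv].mean()
    mean_s = df.groupby(subject, observed=True)[dv].mean()
    group_of = df.groupby(subject, observed=True)[between].first()

    n_per = n_subj // n_a  # subjects per group (balanced)
    ss_a = n_b * n_per * float(((mean_a - grand) ** 2).sum())
    ss_subj = n_b * float(((mean_s - mean_a[group_of].values) ** 2).sum())
    ss_b = n_subj * float(((mean_b - grand) ** 2).sum())
    ss_ab = n_per * float(sum(
        (mean_ab[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in a_levels for b in b_levels))
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_a - ss_subj - ss_b - ss_ab

    df_a, df_subj = n_a - 1, n_subj - n_a
    df_b, df_ab = n_b - 1, (n_a - 1) * (n_b - 1)
    df_err = df_subj * df_b

    def _f(ss_eff, df_eff, ss_e, df_e, label):
        if df_eff <= 0:  # effect undefined (e.g. a single within level)
            return TestResult(statistic=float("nan"), df=0.0,
                              p=float("nan"),
                              method=f"split-plot ANOVA ({label}; undefined)")
        ms_e = ss_e / df_e if df_e > 0 else 0.0
        ms_eff = ss_eff / df_eff
        # an error term indistinguishable from zero at double precision
        # (degenerate noiseless designs) reports an infinite F
        if ms_e <= 1e-10 * max(ms_eff, 1e-300):
            f = np.inf if ms_eff > 0 else 0.0
            p = 0.0 if ms_eff > 0 else 1.0
        else:
            f = ms_eff / ms_e
            p = float(sps.f.sf(f, df_eff, df_e))
        return TestResult(statistic=float(f), df=float(df_eff), p=p,
                          method=f"split-plot ANOVA ({label}; error df={df_e})")

    return {
        "between": _f(ss_a, df_a, ss_subj, df_subj, "between"),
        "within": _f(ss_b, df_b, ss_err, df_err, "within"),
        "interaction": _f(ss_ab, df_ab, ss_err, df_err, "interaction"),
    }
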