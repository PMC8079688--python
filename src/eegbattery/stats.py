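"""Statistical layer of the biomarker battery.

Implements the tests the battery's reporting relies on: Welch's unequal-variance
t test, the exact Mann-Whitney U test (full null enumeration), a
Kolmogorov-Smirnov normality gate with Lilliefors-style Monte-Carlo p-values,
the Holm-Sidak step-down adjustment, balanced two-way (optionally mixed
repeated-measures) ANOVA, and the repeated-measures correlation (common-slope
ANCOVA).  All of these are written here rather than delegated so that every
number in a report is traceable to the formulas below; established library
implementations are used as independent oracles in the test suite only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as _scistats  # distributions only (t, F, norm sf)

__all__ = [
    "StatResult",
    "AnovaTable",
    "RmcorrResult",
    "welch_t",
    "mannwhitney_exact",
    "ks_normality",
    "holm_sidak",
    "anova_two_way",
    "rmcorr",
    "normality_gated_comparison",
]


@dataclass
class StatResult:
    """A single test outcome: statistic, df, two-tailed p, direction, n."""

    name: str
    statistic: float
    p_value: float
    df: float | None = None
    direction: int = 0
    n: tuple[int, ...] = ()
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class AnovaTable:
    """Two-way ANOVA decomposition in long form (one row per effect)."""

    table: pd.DataFrame
    repeated: str | None = None

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


@dataclass
class RmcorrResult:
    r_rm: float
    df: int
    p_value: float
    slope: float
    intercepts: dict
    n_obs: int
    n_subjects: int
    dropped_subjects: list = field(default_factory=list)


def _as_sample(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"sample {name!r} is empty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return a


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

def welch_t(x, y) -> StatResult:
    """Unpaired two-tailed Welch's t test with Welch-Satterthwaite df.

    Degenerate variance handling: if both samples are constant with equal
    means the result is t = 0, p = 1; constant samples with unequal means
    raise, since the statistic is undefined (zero pooled standard error).
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if x.mean() == y.mean():
            return StatResult("welch_t", 0.0, 1.0, df=float(n1 + n2 - 2), n=(n1, n2))
        raise ValueError("zero variance in both groups with unequal means")
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * _scistats.t.sf(abs(t), df)
    return StatResult(
        "welch_t", t, min(p, 1.0), df=df, direction=int(np.sign(t)), n=(n1, n2)
    )


# ---------------------------------------------------------------------------
# Exact Mann-Whitney
# ---------------------------------------------------------------------------

def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of the Mann-Whitney U null distribution for sizes n1, n2.

    counts[u] = number of the C(n1+n2, n1) equally likely rank assignments
    giving U = u, built with the classic recurrence over "subset of size k
    with rank-sum s" (a restricted-partition count).
    """
    # f[k][s]: number of k-subsets of {1..N} whose rank sum is s (shifted).
    # Iterate items, updating a 2-D table; U = ranksum - n1(n1+1)/2.
    N = n1 + n2
    max_u = n1 * n2
    f = np.zeros((n1 + 1, max_u + 1), dtype=np.float64)
    f[0, 0] = 1.0
    for item in range(1, N + 1):
        kmax = min(item, n1)
        for k in range(kmax, 0, -1):
            # choosing rank `item` as the k-th member adds (item - k) to U
            add = item - k
            if add > max_u:
                continue
            f[k, add:] += f[k - 1, : max_u + 1 - add]
    return f[n1]


def mannwhitney_exact(x, y, max_exact: int = 10_000_000) -> StatResult:
    """Mann-Whitney U with an exact two-tailed p by full null enumeration.

    U counts the (x, y) pairs with x > y (ties count 1/2).  Exact path (no
    ties, C(n1+n2, n1) <= ``max_exact``): two-tailed p = 2 x min(P(U <= u),
    P(U >= u)) capped at 1.  Ties or large samples fall back to the
    midrank/normal approximation with tie correction and continuity
    correction, flagged in ``flags``.
    """
    x = _as_sample(x, "x")
    y = _as_sample(y, "y")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = _scistats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # pairs x > y, ties as 1/2
    has_ties = np.unique(combined).size < combined.size
    n_comb = special.comb(n1 + n2, n1, exact=True)
    flags: dict = {}
    if not has_ties and n_comb <= max_exact:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        p_le = counts[: ui + 1].sum() / total
        p_ge = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        flags["method"] = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return StatResult(
                "mannwhitney_u", u, 1.0, n=(n1, n2), flags={"method": "degenerate"}
            )
        z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * _scistats.norm.sf(abs(z)))
        flags["method"] = "normal_approx"
        flags["ties"] = bool(has_ties)
    return StatResult(
        "mannwhitney_u",
        float(u),
        p,
        direction=int(np.sign(u - n1 * n2 / 2.0)),
        n=(n1, n2),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# KS normality gate (Lilliefors)
# ---------------------------------------------------------------------------

_LILLIEFORS_TABLE_SIZE = 5000
_lilliefors_cache: dict[int, np.ndarray] = {}


def _lilliefors_d(x: np.ndarray) -> float:
    n = x.size
    xs = np.sort(x)
    z = (xs - xs.mean()) / xs.std(ddof=1)
    cdf = _scistats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _lilliefors_null(n: int) -> np.ndarray:
    """Seeded Monte-Carlo null distribution of D for sample size n (cached)."""
    if n not in _lilliefors_cache:
        rng = np.random.default_rng(987_001 + n)
        sims = rng.standard_normal((_LILLIEFORS_TABLE_SIZE, n))
        ds = np.empty(_LILLIEFORS_TABLE_SIZE)
        for j, row in enumerate(sims):
            ds[j] = _lilliefors_d(row)
        _lilliefors_cache[n] = np.sort(ds)
    return _lilliefors_cache[n]


def ks_normality(x, alpha: float = 0.05) -> StatResult:
    """Kolmogorov-Smirnov normality test with estimated mean/SD.

    Because the null parameters are estimated from the sample, the classical
    KS distribution is wrong; the p-value is taken from a seeded Monte-Carlo
    null table (the Lilliefors correction, simulated rather than tabulated).
    The routing decision (``flags['normal']``) at ``alpha`` feeds the
    parametric-vs-nonparametric gate used throughout the battery's reports.
    """
    x = _as_sample(x, "x")
    n = x.size
    if n < 5:
        raise ValueError("normality gate needs n >= 5")
    if x.std(ddof=1) == 0.0:
        return StatResult(
            "ks_normality", 1.0, 0.0, n=(n,), flags={"normal": False, "constant": True}
        )
    d = _lilliefors_d(x)
    null = _lilliefors_null(n)
    p = float((null >= d).mean())
    return StatResult(
        "ks_normality", d, p, n=(n,),
        flags={"normal": p > alpha, "correction": "lilliefors_mc"},
    )


# ---------------------------------------------------------------------------
# Holm-Sidak
# ---------------------------------------------------------------------------

def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, original order preserved.

    Sorted ascending, step i of m gets the Sidak correction for the m - i
    remaining hypotheses, 1 - (1 - p)^(m - i); the running maximum enforces
    monotonicity and results are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, step)
        adj_sorted[i] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Two-way (mixed) ANOVA, balanced designs only
# ---------------------------------------------------------------------------

def _f_ratio(ms: float, ms_err: float, df1: float, df2: float) -> tuple[float, float]:
    """F and p with the degenerate zero-error-MS convention (F = 0, p = 1)."""
    if ms_err <= 0:
        return (0.0, 1.0) if ms <= 0 else (np.inf, 0.0)
    f = ms / ms_err
    return f, float(_scistats.f.sf(f, df1, df2))


def anova_two_way(
    data: pd.DataFrame,
    dv: str = "y",
    factor_a: str = "A",
    factor_b: str = "B",
    subject: str = "subject",
    repeated: str | None = None,
) -> AnovaTable:
    """Balanced two-way ANOVA; optionally mixed with one within-subject factor.

    ``repeated=None`` gives the fully between-subjects two-way decomposition
    with replication (effects tested against the cell-residual MS).  With
    ``repeated`` naming one factor, subjects are nested in the other
    (between) factor, the between effect is tested against the
    subject-within-group MS and the within-factor effects against the
    subject x within interaction MS.  Unbalanced designs are refused rather
    than silently resolved with a sums-of-squares convention.
    """
    df = data[[c for c in {dv, factor_a, factor_b, subject} if c in data.columns]].copy()
    if df[dv].isna().any():
        raise ValueError("missing responses not supported")
    a_levels = np.sort(df[factor_a].unique())
    b_levels = np.sort(df[factor_b].unique())
    counts = df.groupby([factor_a, factor_b], sort=True)[dv].count()
    if counts.size != a_levels.size * b_levels.size or counts.nunique() != 1:
        raise ValueError("unbalanced design: equal cell counts required")
    grand = df[dv].mean()
    n_total = len(df)
    ss_total = ((df[dv] - grand) ** 2).sum()
    mean_a = df.groupby(factor_a)[dv].mean()
    mean_b = df.groupby(factor_b)[dv].mean()
    mean_ab = df.groupby([factor_a, factor_b])[dv].mean()
    n_per_a = n_total / a_levels.size
    n_per_b = n_total / b_levels.size
    n_per_cell = counts.iloc[0]
    ss_a = (n_per_a * (mean_a - grand) ** 2).sum()
    ss_b = (n_per_b * (mean_b - grand) ** 2).sum()
    ss_cells = (n_per_cell * (mean_ab - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a = a_levels.size - 1
    df_b = b_levels.size - 1
    df_ab = df_a * df_b

    rows = []
    if repeated is None:
        ss_err = ss_total - ss_cells
        df_err = n_total - a_levels.size * b_levels.size
        ms_err = ss_err / df_err
        for name, ss, dfe in (
            (factor_a, ss_a, df_a),
            (factor_b, ss_b, df_b),
            (f"{factor_a}:{factor_b}", ss_ab, df_ab),
        ):
            ms = ss / dfe
            f, p = _f_ratio(ms, ms_err, dfe, df_err)
            rows.append((name, ss, dfe, ms, f, p))
        rows.append(("error", ss_err, df_err, ms_err, np.nan, np.nan))
    else:
        if repeated not in (factor_a, factor_b):
            raise ValueError(f"repeated must be one of {factor_a!r}, {factor_b!r}")
        within = repeated
        between = factor_b if repeated == factor_a else factor_a
        # every subject must appear at every within level, once
        pivot = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="count")
        if pivot.isna().any().any() or not (pivot == 1).all().all():
            raise ValueError(
                "mixed design requires each subject observed exactly once per within level"
            )
        grp_of = df.groupby(subject)[between].nunique()
        if (grp_of != 1).any():
            raise ValueError("each subject must belong to a single between-group level")
        n_w = df[within].nunique()
        subj_means = df.groupby(subject)[dv].mean()
        subj_group = df.groupby(subject)[between].first()
        grp_means = df.groupby(between)[dv].mean()
        n_subj = subj_means.size
        ss_between_subj = n_w * ((subj_means - grand) ** 2).sum()
        ss_g = ss_a if between == factor_a else ss_b
        df_g = df_a if between == factor_a else df_b
        ss_subj_within = ss_between_subj - ss_g
        df_subj_within = n_subj - (df_g + 1)
        ss_w = ss_b if between == factor_a else ss_a
        df_w = df_b if between == factor_a else df_a
        ss_gw = ss_ab
        df_gw = df_ab
        ss_within_total = ss_total - ss_between_subj
        ss_err_within = ss_within_total - ss_w - ss_gw
        df_err_within = df_subj_within * df_w
        ms_subj = ss_subj_within / df_subj_within
        ms_errw = ss_err_within / df_err_within
        f_g, p_g = _f_ratio(ss_g / df_g, ms_subj, df_g, df_subj_within)
        rows.append((between, ss_g, df_g, ss_g / df_g, f_g, p_g))
        rows.append(("subjects(between)", ss_subj_within, df_subj_within, ms_subj,
                     np.nan, np.nan))
        for name, ss, dfe in ((within, ss_w, df_w), (f"{between}:{within}", ss_gw, df_gw)):
            ms = ss / dfe
            f, p = _f_ratio(ms, ms_errw, dfe, df_err_within)
            rows.append((name, ss, dfe, ms, f, p))
        rows.append(("subjects:within", ss_err_within, df_err_within, ms_errw,
                     np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["effect", "SS", "df", "MS", "F", "p"])
    if np.any(table["SS"] < -1e-9 * max(ss_total, 1.0)):
        raise AssertionError("negative sum of squares in decomposition")
    table["SS"] = table["SS"].clip(lower=0.0)
    return AnovaTable(table=table, repeated=repeated)


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------

def rmcorr(data: pd.DataFrame, subject: str = "subject", x: str = "x", y: str = "y") -> RmcorrResult:
    """Repeated-measures correlation: the common within-subject association.

    Fits y = subject intercept + b*x by least squares (an ANCOVA with
    subject as a factor and a shared slope); r_rm carries the sign of b and
    magnitude sqrt(SS_x / (SS_x + SS_err)) where SS_x is the reduction in
    residual SS from adding x.  df = N_obs - k_subjects - 1; p from the F
    test of the slope.  Subjects with constant x (no within-subject spread)
    cannot inform a within-subject slope and are dropped with a warning.
    """
    df = data[[subject, x, y]].dropna().copy()
    dropped = []
    for s, grp in df.groupby(subject):
        if grp[x].nunique() < 2:
            dropped.append(s)
    if dropped:
        warnings.warn(f"rmcorr: dropping subjects with constant x: {dropped}")
        df = df[~df[subject].isin(dropped)]
    subjects = df[subject].unique()
    k = subjects.size
    n = len(df)
    if k < 2:
        raise ValueError("rmcorr needs at least 2 subjects with within-subject spread")
    if n - k - 1 <= 0:
        raise ValueError("not enough observations for rmcorr df > 0")
    # within-subject centering is equivalent to projecting out subject dummies
    xc = df[x] - df.groupby(subject)[x].transform("mean")
    yc = df[y] - df.groupby(subject)[y].transform("mean")
    sxx = float((xc**2).sum())
    sxy = float((xc * yc).sum())
    syy = float((yc**2).sum())
    b = sxy / sxx
    ss_x = sxy**2 / sxx
    ss_err = syy - ss_x
    dof = n - k - 1
    if ss_x + ss_err <= 0:
        r = 0.0
        p = 1.0
    else:
        r = math.copysign(math.sqrt(ss_x / (ss_x + ss_err)), b)
        if ss_err <= 0:
            p = 0.0
        else:
            f = ss_x / (ss_err / dof)
            p = float(_scistats.f.sf(f, 1, dof))
    sub_means = df.groupby(subject)[[x, y]].mean()
    intercepts = {s: float(sub_means.loc[s, y] - b * sub_means.loc[s, x]) for s in subjects}
    return RmcorrResult(
        r_rm=float(np.clip(r, -1.0, 1.0)), df=dof, p_value=p, slope=float(b),
        intercepts=intercepts, n_obs=n, n_subjects=int(k), dropped_subjects=dropped,
    )


# ---------------------------------------------------------------------------
# The battery's routing convention
# ---------------------------------------------------------------------------

def normality_gated_comparison(x, y, alpha: float = 0.05) -> dict:
    """Two-group comparison with the battery's normality gate.

    Runs the KS normality gate on each group; if either fails at ``alpha``
    the headline test is the exact Mann-Whitney, otherwise Welch's t.  Both
    tests are always computed and returned together with the routing
    decision so reports can show the road not taken.
    """
    gx, gy = ks_normality(x, alpha), ks_normality(y, alpha)
    normal = gx.flags["normal"] and gy.flags["normal"]
    res_w = welch_t(x, y)
    res_m = mannwhitney_exact(x, y)
    return {
        "selected": "welch_t" if normal else "mannwhitney_u",
        "welch_t": res_w,
        "mannwhitney_u": res_m,
        "normality": (gx, gy),
    }
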