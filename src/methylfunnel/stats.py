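"""Statistical procedures used by the screening and validation stages.

Every test is implemented from its textbook definition — sums of squares,
rank transforms, least squares — with scipy used only for the reference
distributions (t, F, chi-squared) that convert a statistic into a p-value.
This keeps the module checkable against independent oracles (scipy's own
test functions, statsmodels OLS, exhaustive permutation) in the test suite.

Conventions
-----------
* All p-values are two-sided.
* The unpaired t-test defaults to the Student (pooled-variance) form; Welch
  is available via ``equal_variance=False``.
* A one-way ANOVA on all-constant input (0/0 F ratio) returns F=0, p=1 by
  convention rather than erroring, so pipelines survive degenerate loci.
* Spearman's rho is the Pearson correlation of mid-ranks (ties averaged);
  the p-value uses the t approximation by default, with an exact permutation
  p available for n <= 9 (relevant at the small n of the discovery stage).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _dist

__all__ = [
    "TestResult",
    "AncovaResult",
    "t_test_unpaired",
    "one_way_anova",
    "ancova_group_age",
    "spearman",
    "pearson",
    "chi_square_independence",
]


@dataclass
class TestResult:
    """A scalar test: statistic, degrees of freedom, two-sided p, and the
    context-dependent estimate (mean difference, rho, r, ...)."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    estimate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class AncovaResult:
    """One-factor ANCOVA with a single continuous covariate.

    ``adjusted_group_means`` are model predictions per group at the grand
    mean of the covariate; ``group_F``/``group_p`` come from the
    extra-sum-of-squares comparison against the covariate-only model;
    ``contrasts`` are unadjusted pairwise t-tests on differences of adjusted
    means using the full model's residual variance.
    """

    groups: list[str]
    adjusted_group_means: dict[str, float]
    covariate_slope: float
    group_F: float
    group_df: tuple[int, int]
    group_p: float
    contrasts: dict[tuple[str, str], tuple[float, float, float]]  # diff, t, p
    residual_sd: float
    n: int


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def t_test_unpaired(x, y, equal_variance: bool = True) -> TestResult:
    """Two-sample unpaired t-test (Student by default, Welch optionally)."""
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("t-test needs at least 2 values per sample")
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if equal_variance:
        df: float = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    else:
        sex2, sey2 = vx / nx, vy / ny
        se = math.sqrt(sex2 + sey2)
        if se > 0:
            df = (sex2 + sey2) ** 2 / (
                sex2**2 / (nx - 1) + sey2**2 / (ny - 1)
            )
        else:
            df = nx + ny - 2
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    p = 2.0 * _dist.t.sf(abs(t), df) if math.isfinite(t) else 0.0
    return TestResult(statistic=t, df=df, p_value=min(p, 1.0), estimate=diff)


def one_way_anova(samples) -> TestResult:
    """One-way fixed-effects ANOVA across two or more groups."""
    groups = [_clean(s) for s in samples]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = sum(g.sum() for g in groups) / n
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0.0:
        if ms_b == 0.0:
            # all-constant input: define F=0, p=1
            return TestResult(0.0, (df_b, df_w), 1.0, 0.0)
        return TestResult(math.inf, (df_b, df_w), 0.0, math.inf)
    F = ms_b / ms_w
    p = _dist.f.sf(F, df_b, df_w)
    return TestResult(statistic=F, df=(df_b, df_w), p_value=p, estimate=F)


def ancova_group_age(values, groups, ages, group_order=None) -> AncovaResult:
    """ANCOVA: value ~ group + covariate, fitted by least squares.

    ``group_F`` compares the full model against the covariate-only model
    (extra sum of squares); adjusted means are evaluated at the grand mean
    of the covariate.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    groups = np.asarray(groups, dtype=object)
    mask = np.isfinite(values)
    if not np.all(np.isfinite(ages[mask])):
        raise ValueError("covariate (age) missing for a subject in the model")
    values, ages, groups = values[mask], ages[mask], groups[mask]

    if group_order is None:
        group_order = list(dict.fromkeys(groups))
    else:
        group_order = list(group_order)
    k = len(group_order)
    if k < 2:
        raise ValueError("ANCOVA needs >= 2 groups")
    counts = {g: int(np.sum(groups == g)) for g in group_order}
    if any(c < 3 for c in counts.values()):
        raise ValueError(f"ANCOVA needs >= 3 subjects per group, got {counts}")
    n = len(values)

    # Design: intercept + (k-1) treatment dummies + covariate.
    X = np.ones((n, k + 1))
    for j, g in enumerate(group_order[1:], start=1):
        X[:, j] = (groups == g).astype(float)
    X[:, k] = ages
    if np.linalg.matrix_rank(X) < X.shape[1]:
        if np.ptp(ages) == 0.0:
            raise ValueError("singular design: covariate 'age' is constant")
        raise ValueError("singular design: group indicators are collinear")

    beta, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    rss_full = float(resid @ resid)
    df_resid = n - (k + 1)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = rss_full / df_resid

    # Reduced model: intercept + covariate only.
    Xr = np.column_stack([np.ones(n), ages])
    br, _, _, _ = np.linalg.lstsq(Xr, values, rcond=None)
    rr = values - Xr @ br
    rss_red = float(rr @ rr)
    df_num = k - 1
    if sigma2 == 0.0:
        F = 0.0 if rss_red - rss_full <= 1e-12 else math.inf
        group_p = 1.0 if F == 0.0 else 0.0
    else:
        F = max(rss_red - rss_full, 0.0) / df_num / sigma2
        group_p = float(_dist.f.sf(F, df_num, df_resid))

    grand_age = float(ages.mean())
    XtXinv = np.linalg.inv(X.T @ X)
    adjusted = {}
    for j, g in enumerate(group_order):
        c = np.zeros(k + 1)
        c[0] = 1.0
        if j >= 1:
            c[j] = 1.0
        c[k] = grand_age
        adjusted[g] = float(c @ beta)

    contrasts: dict[tuple[str, str], tuple[float, float, float]] = {}
    for i, j in itertools.combinations(range(k), 2):
        c = np.zeros(k + 1)
        if i >= 1:
            c[i] = 1.0
        if j >= 1:
            c[j] -= 1.0
        # difference of adjusted means g_i - g_j (covariate term cancels)
        diff = float(c @ beta)
        se = math.sqrt(max(sigma2 * float(c @ XtXinv @ c), 0.0))
        if se == 0.0:
            t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            p = 1.0 if diff == 0.0 else 0.0
        else:
            t = diff / se
            p = float(2.0 * _dist.t.sf(abs(t), df_resid))
        contrasts[(group_order[i], group_order[j])] = (diff, t, p)

    return AncovaResult(
        groups=group_order,
        adjusted_group_means=adjusted,
        covariate_slope=float(beta[k]),
        group_F=float(F),
        group_df=(df_num, df_resid),
        group_p=group_p,
        contrasts=contrasts,
        residual_sd=math.sqrt(sigma2),
        n=n,
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties receive the mean of their rank span."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise ValueError("zero variance")
    return float(xc @ yc) / denom


def _t_approx_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _dist.t.sf(abs(t), n - 2))


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    return x[m], y[m]


def spearman(x, y, exact: bool = False) -> TestResult:
    """Spearman rank correlation with t-approximation or exact permutation p.

    The exact p enumerates all n! permutations of one rank vector and is only
    permitted for n <= 9.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs >= 3 complete pairs")
    rx, ry = _midranks(x), _midranks(y)
    try:
        rho = _pearson_r(rx, ry)
    except ValueError:
        raise ValueError("zero variance in ranks") from None
    if exact:
        if n > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        obs = abs(float(rxc @ ryc))
        perms = np.array(list(itertools.permutations(ryc)))
        stats = np.abs(perms @ rxc)
        p = float(np.mean(stats >= obs - 1e-12))
    else:
        p = _t_approx_p(rho, n)
    return TestResult(statistic=rho, df=n - 2, p_value=p, estimate=rho)


def pearson(x, y) -> TestResult:
    """Pearson product-moment correlation with t-approximation p."""
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("pearson needs >= 3 complete pairs")
    r = _pearson_r(x, y)
    return TestResult(statistic=r, df=n - 2, p_value=_t_approx_p(r, n), estimate=r)


def chi_square_independence(table, correction: bool = False) -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table."""
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if (O < 0).any():
        raise ValueError("counts must be nonnegative")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in contingency table")
    E = np.outer(row, col) / O.sum()
    dev = np.abs(O - E)
    if correction and O.shape == (2, 2):
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p = float(_dist.chi2.sf(chi2, df))
    return TestResult(statistic=chi2, df=df, p_value=p, estimate=chi2)
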