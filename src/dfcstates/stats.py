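"""Group-level inference: ANOVA, pairwise Bonferroni t tests, chi-square,
and covariate-adjusted partial correlation.

These are the standard tests applied to the state summaries: a one-way ANOVA
across diagnostic groups on each connectivity measure (optionally from
published summary statistics alone), pooled-variance pairwise t tests with
Bonferroni correction, a Pearson chi-square on categorical tables such as
sex by group, and partial Pearson correlation between connectivity and
cognition with age, education and mean framewise displacement regressed out.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "one_way_anova",
    "one_way_anova_from_summary",
    "pairwise_bonferroni",
    "chi_square_test",
    "partial_correlation",
]


@dataclass
class StatResult:
    """One test's outcome: statistic, degrees of freedom, p-values."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    adjusted_p: float | None = None
    comparison: str = ""
    n: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value:
            raise ValueError("adjusted p cannot be below the raw p")


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for g in out:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
    return out


def one_way_anova(groups, comparison: str = "") -> StatResult:
    """Fixed-effects one-way ANOVA: F = MSB/MSW on (g-1, N-g) df."""
    gs = _as_groups(groups)
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    n_total = int(ns.sum())
    grand = float(np.concatenate(gs).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b, df_w = len(gs) - 1, n_total - len(gs)
    if ssw == 0:
        if ssb == 0:
            raise ValueError("zero variance everywhere; F undefined")
        f = np.inf
    else:
        f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return StatResult(
        statistic=float(f), df=(df_b, df_w), p_value=p,
        comparison=comparison, n=n_total,
    )


def one_way_anova_from_summary(means, sds, ns, comparison: str = "") -> StatResult:
    """One-way ANOVA reconstructed from per-group mean, SD and n.

    Exactly reproduces :func:`one_way_anova` for any raw sample with the same
    summaries: the between-group sum of squares comes from the group means
    about the (weighted) grand mean and the within-group sum of squares is
    ``sum (n_i - 1) sd_i^2``.  Lets published demographic tables be checked
    without the raw data.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (means.shape == sds.shape == ns.shape) or means.ndim != 1:
        raise ValueError("means, sds, ns must be 1-D and equal length")
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("each group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("sds must be non-negative")
    n_total = int(ns.sum())
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b, df_w = len(means) - 1, n_total - len(means)
    if ssw == 0:
        if ssb == 0:
            raise ValueError("zero variance everywhere; F undefined")
        f = np.inf
    else:
        f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return StatResult(
        statistic=float(f), df=(df_b, df_w), p_value=p,
        comparison=comparison, n=n_total,
    )


def pairwise_bonferroni(groups, names: list[str] | None = None) -> list[StatResult]:
    """All pairwise pooled-variance t tests, Bonferroni-adjusted.

    The adjusted p is ``min(1, m * p_raw)`` with m the number of pairs
    (3 for three groups).
    """
    gs = _as_groups(groups)
    if names is None:
        names = [f"group_{i}" for i in range(len(gs))]
    pairs = list(combinations(range(len(gs)), 2))
    m = len(pairs)
    results = []
    for i, j in pairs:
        t, p = sps.ttest_ind(gs[i], gs[j], equal_var=True)
        df = gs[i].size + gs[j].size - 2
        results.append(
            StatResult(
                statistic=float(t), df=df, p_value=float(p),
                adjusted_p=min(1.0, float(p) * m),
                comparison=f"{names[i]} vs {names[j]}",
                n=gs[i].size + gs[j].size,
            )
        )
    return results


def chi_square_test(table, comparison: str = "") -> StatResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return StatResult(
        statistic=float(chi2), df=int(dof), p_value=float(p),
        comparison=comparison, n=int(table.sum()),
    )


def partial_correlation(
    x, y, covariates=None, comparison: str = ""
) -> StatResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are regressed on the covariates plus an intercept by
    least squares; r is the Pearson correlation of the residual series.
    Degrees of freedom are ``n - q - 2`` (q covariates) and the two-tailed p
    comes from ``t = r * sqrt(df / (1 - r^2))`` on Student-t(df).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    q = cov.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > q + 2 (n={n}, q={q})")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariates are rank deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - q - 2
    r_clipped = min(max(r, -1.0), 1.0)
    if abs(r_clipped) == 1.0:
        p = 0.0
    else:
        t = r_clipped * np.sqrt(df / (1.0 - r_clipped**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(
        statistic=r_clipped, df=df, p_value=p, comparison=comparison, n=n
    )
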