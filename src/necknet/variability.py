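"""Coefficient-of-variation analysis across network parameters.

The relative variability of each network parameter across species is
summarized by its coefficient of variation CV = s / mean (sample standard
deviation).  Uncertainty comes from a percentile bootstrap; equality of
CVs across parameters is tested globally with a signed-likelihood-ratio
test under normal models sharing a common CV, and pairwise with the
Feltz-Miller asymptotic chi-square test, Bonferroni corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "CVReport",
    "cv",
    "cv_bootstrap_ci",
    "mslrt_equal_cv",
    "asymptotic_cv_test",
    "pairwise_cv_tests",
    "cv_report",
]


@dataclass
class CVReport:
    cvs: pd.Series
    ci: pd.DataFrame  # columns lower/upper
    mslrt_statistic: float
    mslrt_p: float
    pairwise_p: pd.DataFrame  # Bonferroni-adjusted


def cv(values) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("CV requires at least 2 observations")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def cv_bootstrap_ci(
    values,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "percentile",
) -> tuple[float, float]:
    """Bootstrap confidence interval for the CV.

    ``method='percentile'`` (default) takes the alpha/2 and 1-alpha/2
    quantiles of the resampled CVs; ``'bca'`` applies the
    bias-corrected-and-accelerated adjustment.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = x[idx]
    means = samples.mean(axis=1)
    sds = samples.std(axis=1, ddof=1)
    boots = np.where(means != 0, sds / np.where(means == 0, 1, means), np.nan)
    boots = boots[np.isfinite(boots)]
    if method == "percentile":
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)
    if method == "bca":
        theta = cv(x)
        z0 = stats.norm.ppf(np.mean(boots < theta))
        jack = np.array([cv(np.delete(x, i)) for i in range(n)])
        jm = jack.mean()
        num = np.sum((jm - jack) ** 3)
        den = 6 * np.sum((jm - jack) ** 2) ** 1.5
        a = num / den if den else 0.0
        zl, zu = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
        p_lo = stats.norm.cdf(z0 + (z0 + zl) / (1 - a * (z0 + zl)))
        p_hi = stats.norm.cdf(z0 + (z0 + zu) / (1 - a * (z0 + zu)))
        lo, hi = np.percentile(boots, [100 * p_lo, 100 * p_hi])
        return float(lo), float(hi)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# equality tests


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 observations")
        if g.mean() == 0:
            raise ValueError("CV undefined for a zero-mean group")
    return gs


def mslrt_equal_cv(groups, modified: bool = True) -> tuple[float, float]:
    """Signed-likelihood-ratio test for equality of CVs across k groups.

    Normal models with a common coefficient of variation tau are fitted by
    profile maximum likelihood (the group means solve a quadratic given
    tau, tau is optimized numerically); the statistic 2(l1 - l0) is
    referred to chi-square with k-1 degrees of freedom.  With
    ``modified=True`` (default) the likelihood uses degrees-of-freedom
    (n-1) weighting of the variance terms, a small-sample adjustment in
    the spirit of the modified signed-likelihood ratio test; ``False``
    gives the plain ML statistic.
    """
    gs = _check_groups(groups)
    k = len(gs)

    def weights(x):
        n = len(x)
        m = (n - 1) if modified else n
        return n, m

    def loglik_h1() -> float:
        total = 0.0
        for x in gs:
            n, m = weights(x)
            a = ((x - x.mean()) ** 2).sum()
            s2 = a / m
            total += -m / 2 * np.log(s2) - a / (2 * s2)
        return total

    def profile_h0(tau: float) -> float:
        total = 0.0
        for x in gs:
            n, m = weights(x)
            xb = x.mean()
            a = ((x - xb) ** 2).sum()
            # d/dmu of the profile likelihood yields
            #   m tau^2 mu^2 + n xb mu - (a + n xb^2) = 0
            mu = (
                -n * xb + np.sqrt(n**2 * xb**2 + 4 * m * tau**2 * (a + n * xb**2))
            ) / (2 * m * tau**2)
            s2 = tau**2 * mu**2
            total += -m / 2 * np.log(s2) - (a + n * (xb - mu) ** 2) / (2 * s2)
        return total

    res = minimize_scalar(
        lambda t: -profile_h0(t), bounds=(1e-8, 10.0), method="bounded"
    )
    statistic = 2 * (loglik_h1() - (-res.fun))
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), p


def asymptotic_cv_test(groups) -> tuple[float, float]:
    """Feltz-Miller asymptotic chi-square test for equality of CVs."""
    gs = _check_groups(groups)
    nu = np.array([len(g) - 1 for g in gs], dtype=float)
    c = np.array([cv(g) for g in gs])
    cbar = np.sum(nu * c) / nu.sum()
    d = np.sum(nu * (c - cbar) ** 2) / (cbar**2 * (0.5 + cbar**2))
    p = float(stats.chi2.sf(d, len(gs) - 1))
    return float(d), p


def pairwise_cv_tests(groups, names=None) -> pd.DataFrame:
    """All pairwise asymptotic CV-equality tests, Bonferroni corrected.

    Returns a symmetric matrix of adjusted p-values with unit diagonal;
    the multiplier is the number of pairs, capped at 1.
    """
    gs = _check_groups(groups)
    k = len(gs)
    names = list(names) if names is not None else [f"g{i}" for i in range(k)]
    n_pairs = k * (k - 1) // 2
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            _, raw = asymptotic_cv_test([gs[i], gs[j]])
            p[i, j] = p[j, i] = min(1.0, raw * n_pairs)
    return pd.DataFrame(p, index=names, columns=names)


def cv_report(
    table: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> CVReport:
    """Full CV analysis of a species x parameter table."""
    cols = list(table.columns)
    cvs = pd.Series({c: cv(table[c]) for c in cols})
    ss = np.random.SeedSequence(seed)
    ci_rows = {}
    for c, child in zip(cols, ss.spawn(len(cols))):
        sub = int(child.generate_state(1)[0] % (2**31))
        ci_rows[c] = cv_bootstrap_ci(table[c], n_boot=n_boot, seed=sub)
    ci = pd.DataFrame(ci_rows, index=["lower", "upper"]).T
    groups = [table[c].to_numpy(dtype=float) for c in cols]
    m_stat, m_p = mslrt_equal_cv(groups)
    pw = pairwise_cv_tests(groups, names=cols)
    return CVReport(cvs=cvs, ci=ci, mslrt_statistic=m_stat, mslrt_p=m_p,
                    pairwise_p=pw)
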