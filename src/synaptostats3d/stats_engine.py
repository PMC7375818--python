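"""The study's statistical battery.

Contingency chi-square with the expected-frequency formula
``E_ij = T_i * T_j / T``, two-sample Kolmogorov-Smirnov, Mann-Whitney U,
one-way ANOVA with Tukey HSD, log-normal / log-logistic size-distribution
fits, squared Pearson correlation, and the dual significance-threshold
convention: alpha = 0.05 when the sampling unit is the subject, and the
stricter alpha = 0.001 when the sampling unit is the individual synapse
(tens of thousands of observations make tiny effects "significant"
otherwise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: Significance thresholds by sampling-unit basis.
ALPHA_BY_BASIS = {"subjects": 0.05, "synapses": 0.001}


def alpha_for_basis(n_basis: str) -> float:
    try:
        return ALPHA_BY_BASIS[n_basis]
    except KeyError:
        raise ValueError(f"n_basis must be one of {tuple(ALPHA_BY_BASIS)}") from None


@dataclass(frozen=True)
class TestResult:
    """One hypothesis-test outcome under the dual-threshold convention."""

    test: str
    statistic: float
    p_value: float
    df: float | None
    n_basis: str
    alpha: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @classmethod
    def from_p(cls, test: str, statistic: float, p: float,
               n_basis: str, df: float | None = None) -> "TestResult":
        a = alpha_for_basis(n_basis)
        return cls(test=test, statistic=float(statistic), p_value=float(p),
                   df=df, n_basis=n_basis, alpha=a, significant=bool(p < a))


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

def expected_frequencies(table: np.ndarray) -> np.ndarray:
    """E_ij = T_i * T_j / T from the row, column and grand totals."""
    obs = np.asarray(table, float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("contingency table is all zero")
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total


def chi2_contingency(table, n_basis: str = "synapses") -> TestResult:
    """Pearson chi-square test of association, no continuity correction.

    The statistic is ``sum (O_ij - E_ij)^2 / E_ij`` over cells with
    ``E_ij > 0``, on ``(rows-1)(cols-1)`` degrees of freedom.  A warning
    is issued when any expected count falls below 5 (the classical
    approximation caveat).
    """
    obs = np.asarray(table, float)
    exp = expected_frequencies(obs)
    if (exp[exp > 0] < 5).any():
        warnings.warn("expected frequencies below 5; chi-square "
                      "approximation may be poor")
    mask = exp > 0
    stat = float((((obs - exp) ** 2)[mask] / exp[mask]).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult.from_p("chi2", stat, p, n_basis, df=df)


def pairwise_chi2(table: pd.DataFrame, n_basis: str = "synapses") -> pd.DataFrame:
    """All 2-column sub-table chi-square comparisons (e.g. layer pairs)."""
    cols = list(table.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            res = chi2_contingency(table[[a, b]].to_numpy(), n_basis=n_basis)
            rows.append({"group_a": a, "group_b": b, "statistic": res.statistic,
                         "df": res.df, "p_value": res.p_value,
                         "alpha": res.alpha, "significant": res.significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-sample and multi-group tests
# ---------------------------------------------------------------------------

def _check_sample(x, name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, float).ravel()
    if len(arr) < min_n:
        raise ValueError(f"sample {name} needs at least {min_n} observations")
    return arr


def ks_two_sample(x, y, n_basis: str = "synapses") -> TestResult:
    """Two-sample Kolmogorov-Smirnov: sup |ECDF_x - ECDF_y|."""
    x, y = _check_sample(x, "x"), _check_sample(y, "y")
    stat, p = sps.ks_2samp(x, y)
    return TestResult.from_p("ks", stat, p, n_basis)


def mann_whitney(x, y, n_basis: str = "subjects") -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null distribution for small tie-free samples (both n <= 8),
    otherwise the normal approximation with tie correction.
    """
    x, y = _check_sample(x, "x"), _check_sample(y, "y")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult.from_p("mann_whitney", res.statistic, res.pvalue, n_basis)


def anova_tukey(groups: dict[str, np.ndarray] | list[np.ndarray],
                n_basis: str = "subjects") -> tuple[TestResult, pd.DataFrame]:
    """Classical one-way ANOVA plus Tukey HSD pairwise comparisons."""
    if isinstance(groups, dict):
        names, samples = list(groups), [_check_sample(v, k, 2) for k, v in groups.items()]
    else:
        samples = [_check_sample(g, str(i), 2) for i, g in enumerate(groups)]
        names = [f"group{i}" for i in range(len(samples))]
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups")
    f, p = sps.f_oneway(*samples)
    k = len(samples)
    n = sum(len(s) for s in samples)
    anova = TestResult.from_p("anova", f, p, n_basis, df=k - 1)
    values = np.concatenate(samples)
    labels = np.concatenate([[nm] * len(s) for nm, s in zip(names, samples)])
    hsd = pairwise_tukeyhsd(values, labels, alpha=anova.alpha)
    pair = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    return anova, pair


# ---------------------------------------------------------------------------
# Size-distribution fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Fitted size distribution with goodness-of-fit summaries."""

    family: str
    params: dict[str, float]
    log_likelihood: float
    ks_distance: float
    aic: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood must be finite")
        if not (0.0 <= self.ks_distance <= 1.0):
            raise ValueError("KS distance outside [0, 1]")


def fit_size_distribution(sample, family: str) -> FitResult:
    """Maximum-likelihood fit of a right-skewed size distribution.

    ``lognormal`` uses the closed-form MLE on log values (mu, sigma of
    log size); ``loglogistic`` (CDF ``1/(1 + (x/alpha)^-beta)``) is fit
    numerically.  Returns the KS distance against the fitted CDF and
    AIC = 2k - 2*logL with k = 2 parameters.
    """
    x = _check_sample(sample, "sample", min_n=10)
    if (x <= 0).any():
        raise ValueError("sizes must be strictly positive")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: distribution fit is degenerate")
    if family == "lognormal":
        logx = np.log(x)
        mu = float(logx.mean())
        sigma = float(logx.std(ddof=0))
        dist = sps.lognorm(s=sigma, scale=math.exp(mu))
        params = {"mu": mu, "sigma": sigma}
    elif family == "loglogistic":
        beta, _, alpha = sps.fisk.fit(x, floc=0.0)
        dist = sps.fisk(c=beta, scale=alpha)
        params = {"alpha": float(alpha), "beta": float(beta)}
    else:
        raise ValueError(f"unknown family {family!r}")
    ll = float(dist.logpdf(x).sum())
    ks = float(sps.kstest(x, dist.cdf).statistic)
    return FitResult(family=family, params=params, log_likelihood=ll,
                     ks_distance=ks, aic=2 * 2 - 2 * ll)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def r_squared(x, y) -> float:
    """Squared Pearson correlation (direction reported separately)."""
    x, y = _check_sample(x, "x", 3), _check_sample(y, "y", 3)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def results_table(results: list[TestResult], analysis_ids: list[str] | None = None
                  ) -> pd.DataFrame:
    """Tidy CSV-ready table of test outcomes."""
    ids = analysis_ids or [f"analysis_{i}" for i in range(len(results))]
    return pd.DataFrame([{
        "analysis": aid, "test": r.test, "statistic": r.statistic,
        "df": r.df, "p_value": r.p_value, "alpha": r.alpha,
        "n_basis": r.n_basis, "significant": r.significant,
    } for aid, r in zip(ids, results)])
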