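"""Method-comparison statistics: Bland-Altman, Pearson, Spearman, OLS.

Differences are defined as ``test - reference``, so a negative bias means
the test method underestimates the reference (e.g. CT-based CL vs
MRI-based CL). The report carries both the conventional 95% limits of
agreement (bias ± 1.96 SD of differences) and the 95% confidence interval
of the mean difference (bias ± t SD/sqrt(n)): published method-comparison
tables sometimes print the latter under the former's name, so both are
reported under explicit labels.

The core statistics are computed from their defining formulas (moment
sums, midranks, paired-t) rather than delegated; library implementations
serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

from .errors import SampleSizeError


def _as_pair(reference, test, min_n: int) -> Tuple[np.ndarray, np.ndarray]:
    r = np.asarray(reference, dtype=np.float64).ravel()
    t = np.asarray(test, dtype=np.float64).ravel()
    if r.size != t.size:
        raise SampleSizeError("reference and test must have equal length")
    if r.size < min_n:
        raise SampleSizeError(f"need at least {min_n} pairs, got {r.size}")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
        raise SampleSizeError("non-finite values in input vectors")
    return r, t


def _rank_midtie(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=np.float64)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def pearson_correlation(x, y) -> Tuple[float, float]:
    """Pearson r from moment sums with a two-sided t-approximation p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan, np.nan
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if n < 3 or abs(r) == 1.0:
        return r, 0.0 if abs(r) == 1.0 and n >= 3 else np.nan
    tstat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(tstat), n - 2)
    return r, float(p)


def spearman_correlation(x, y) -> Tuple[float, float]:
    """Spearman rho: Pearson correlation of midranks; p via t-approximation."""
    rx = _rank_midtie(np.asarray(x, dtype=np.float64).ravel())
    ry = _rank_midtie(np.asarray(y, dtype=np.float64).ravel())
    return pearson_correlation(rx, ry)


def paired_t(x, y) -> Tuple[float, float]:
    """Two-tailed paired t-test of zero mean difference (x - y)."""
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return np.nan, np.nan
    tstat = float(d.mean() / (sd / np.sqrt(n)))
    return tstat, float(2 * sps.t.sf(abs(tstat), n - 1))


def ols_line(x, y) -> dict:
    """Least-squares fit of y on x: slope, intercept and Pearson r."""
    x, y = _as_pair(x, y, 3)
    vx = np.var(x)
    if vx == 0:
        raise SampleSizeError("degenerate fit: x has zero variance")
    slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    intercept = float(y.mean() - slope * x.mean())
    r, _ = pearson_correlation(x, y)
    return {"slope": slope, "intercept": intercept, "r": r}


@dataclass
class AgreementReport:
    """Agreement between a test route and a reference route."""

    n: int
    bias: float  # mean of (test - reference)
    sd_diff: float  # SD of differences, N-1
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    ci_low: float  # bias - t(0.975, n-1) sd/sqrt(n)
    ci_high: float
    t_stat: Optional[float]
    p_paired: Optional[float]
    pearson_r: float
    pearson_p: float
    slope: float  # OLS of reference on test
    intercept: float
    spearman_rho: Optional[float]
    spearman_p: Optional[float]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def bland_altman(reference, test) -> AgreementReport:
    """Full agreement report for a pair of routes (differences test - ref)."""
    r, t = _as_pair(reference, test, 3)
    n = r.size
    d = t - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0
    if degenerate:
        t_stat = p_paired = None
    else:
        t_stat, p_paired = paired_t(t, r)
    tcrit = float(sps.t.ppf(0.975, n - 1))
    half_ci = tcrit * sd / np.sqrt(n)
    if np.var(t) > 0:
        fit = ols_line(t, r)
        slope, intercept = fit["slope"], fit["intercept"]
    else:
        slope = intercept = np.nan
    pr, pp = pearson_correlation(r, t)
    means = (t + r) / 2.0
    if np.ptp(d) == 0 or np.ptp(means) == 0:
        rho = rho_p = None
    else:
        rho, rho_p = spearman_correlation(d, means)
    return AgreementReport(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        ci_low=bias - half_ci,
        ci_high=bias + half_ci,
        t_stat=t_stat,
        p_paired=p_paired,
        pearson_r=pr,
        pearson_p=pp,
        slope=slope,
        intercept=intercept,
        spearman_rho=rho,
        spearman_p=rho_p,
        degenerate=degenerate,
    )


def spearman_load_dependence(reference, test, axis: str = "mean") -> dict:
    """Association between route differences and amyloid load.

    ``axis="mean"`` (standard Bland-Altman practice) correlates
    ``test - reference`` with the pairwise means; ``axis="reference"``
    uses the reference values alone.
    """
    r, t = _as_pair(reference, test, 4)
    d = t - r
    load = (t + r) / 2.0 if axis == "mean" else r
    if np.ptp(d) == 0:
        return {"rho": None, "p": None, "degenerate": True}
    rho, p = spearman_correlation(d, load)
    return {"rho": rho, "p": p, "degenerate": False}
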