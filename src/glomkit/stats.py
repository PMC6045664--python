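"""Group-comparison tests and concentration-response sigmoid fitting.

Thin, uniform wrappers over the scipy test battery used throughout the
analysis (Wilcoxon rank-sum, sign-rank, Kolmogorov-Smirnov, Kruskal-Wallis)
with optional Bonferroni correction, plus a seeded bootstrap test on the
difference of group means and a four-parameter logistic dose-response fit.
All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n_per_group: tuple[int, ...]
    adjusted: bool = False
    correction: str = "none"
    status: str = "ok"


@dataclass
class SigmoidFit:
    bottom: float
    top: float
    ec50: float
    hill_slope: float
    residual_norm: float
    status: str = "ok"  # or "degenerate", "fit_failed"


_TESTS = {"rank_sum", "sign_rank", "ks", "kruskal_wallis"}


def compare_groups(
    *groups: np.ndarray,
    test_name: str = "rank_sum",
    correction: str = "none",
    k: int = 1,
) -> TestResult:
    """Two-sided group comparison with optional Bonferroni correction.

    rank_sum and ks compare two independent samples; sign_rank compares two
    paired equal-length samples; kruskal_wallis accepts two or more groups.
    Bonferroni multiplies p by ``k`` comparisons and clips at 1.
    """
    if test_name not in _TESTS:
        raise ValueError(f"unsupported test: {test_name!r}")
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("all samples must be non-empty")

    if test_name == "kruskal_wallis":
        if len(arrs) < 2:
            raise ValueError("kruskal_wallis needs at least 2 groups")
        res = sps.kruskal(*arrs)
    else:
        if len(arrs) != 2:
            raise ValueError(f"{test_name} compares exactly 2 samples")
        a, b = arrs
        if test_name == "rank_sum":
            # Mann-Whitney U with normal approximation and tie correction:
            # the rank-sum test on tied data
            res = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic")
        elif test_name == "sign_rank":
            if a.size != b.size:
                raise ValueError("sign_rank requires paired equal-length samples")
            res = sps.wilcoxon(a, b, zero_method="wilcox")
        else:  # ks
            res = sps.ks_2samp(a, b)

    p = float(res.pvalue)
    adjusted = False
    if correction == "bonferroni":
        p = min(1.0, k * p)
        adjusted = True
    elif correction != "none":
        raise ValueError(f"unknown correction: {correction!r}")
    return TestResult(
        statistic=float(res.statistic),
        p_value=p,
        test_name=test_name,
        n_per_group=tuple(a.size for a in arrs),
        adjusted=adjusted,
        correction=correction,
    )


def bootstrap_mean_diff(
    a: np.ndarray, b: np.ndarray, n_boot: int = 100_000, seed: int = 0
) -> TestResult:
    """Two-sided bootstrap test on the difference of group means.

    Each group is resampled with replacement ``n_boot`` times; the bootstrap
    distribution of the mean difference, centered at the observed difference
    (the null-centered distribution), gives
    p = (1 + #{|d* - d_obs| >= |d_obs|}) / (n_boot + 1).
    Two zero-variance samples are degenerate and return p = 1.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    d_obs = a.mean() - b.mean()
    if a.std() == 0 and b.std() == 0:
        return TestResult(d_obs, 1.0, "bootstrap_mean", (a.size, b.size),
                          status="degenerate")
    rng = np.random.default_rng(seed)
    # vectorized resampling in chunks to bound memory
    chunk = max(1, min(n_boot, int(2e7 // max(a.size + b.size, 1))))
    count = 0
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        ma = a[rng.integers(0, a.size, size=(m, a.size))].mean(axis=1)
        mb = b[rng.integers(0, b.size, size=(m, b.size))].mean(axis=1)
        count += int(np.sum(np.abs((ma - mb) - d_obs) >= abs(d_obs)))
        done += m
    p = (1 + count) / (n_boot + 1)
    return TestResult(float(d_obs), float(p), "bootstrap_mean",
                      (a.size, b.size))


def _logistic4(x, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


def fit_sigmoid(concentrations: np.ndarray, responses: np.ndarray) -> SigmoidFit:
    """Four-parameter logistic fit of response vs concentration.

    Model: bottom + (top - bottom) / (1 + (ec50 / x)^hill), the standard
    dose-response sigmoid on a log-concentration axis. Requires >= 4
    distinct positive concentrations. Constant responses or fit failure
    are flagged rather than raised.
    """
    x = np.asarray(concentrations, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("concentrations and responses must match")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if np.ptp(y) < 1e-12 * max(abs(y.mean()), 1.0):
        return SigmoidFit(float(y.mean()), float(y.mean()), np.nan, np.nan,
                          0.0, status="degenerate")
    p0 = (y.min(), y.max(), float(np.exp(np.mean(np.log(x)))), 1.0)
    try:
        popt, _ = curve_fit(
            _logistic4, x, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-30, 0.05],
                    [np.inf, np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                          status="fit_failed")
    bottom, top, ec50, hill = popt
    resid = float(np.linalg.norm(y - _logistic4(x, *popt)))
    status = "ok" if top >= bottom else "flagged_decreasing"
    return SigmoidFit(float(bottom), float(top), float(ec50), float(hill),
                      resid, status=status)
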