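"""Rank correlation, R², and bootstrap intervals for site-level comparisons.

The headline analyses correlate per-site infection potential against host
diversity with a one-sided Spearman test (the direction of the alternative
is an ecological hypothesis, so the caller must state it), report the R² of
the least-squares line through the same points, and back the correlation
with a percentile bootstrap over site resamples.

Spearman's rho is the Pearson correlation of the average-ranked vectors.
The default one-sided p uses the classical t approximation
``t = rho sqrt((n-2)/(1-rho²))`` on n−2 degrees of freedom; for n ≤ 9 an
exact permutation p (all n! rank orderings enumerated) is available.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "CorrelationResult",
    "spearman_rho",
    "spearman_one_sided",
    "r_squared",
    "bootstrap_corr_ci",
    "correlate",
]

logger = logging.getLogger("virhost")

EXACT_N_MAX = 9  # n! permutations are enumerated; 9! = 362880 is the ceiling


@dataclass
class CorrelationResult:
    """A one-sided rank correlation with its regression and bootstrap context."""

    rho: float
    p_one_sided: float
    alternative: str  # "less" or "greater"
    n: int
    r_squared: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    ci_level: float = float("nan")
    seed: int | None = None
    method: str = "t"  # p-value method: "t" or "exact"


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if not keep.all():
        logger.warning("NA_PAIRS_DROPPED n=%d", int((~keep).sum()))
    return x[keep], y[keep]


def _check_not_constant(x: np.ndarray, y: np.ndarray) -> None:
    if np.ptp(x) == 0:
        raise UndefinedMetricError("correlation undefined: x is constant")
    if np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined: y is constant")


def spearman_rho(x, y) -> float:
    """Spearman's rho: Pearson correlation of average-ranked vectors."""
    x, y = _clean_pairs(x, y)
    _check_not_constant(x, y)
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float, alternative: str) -> float:
    """Exact permutation p by enumerating every ordering of the y ranks."""
    n = rx.size
    rxc = rx - rx.mean()
    denom = np.sqrt(np.sum(rxc**2))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        ryp = ry[list(perm)]
        ryc = ryp - ryp.mean()
        rho = float(np.dot(rxc, ryc) / (denom * np.sqrt(np.sum(ryc**2))))
        if alternative == "less":
            count += rho <= rho_obs + 1e-12
        else:
            count += rho >= rho_obs - 1e-12
        total += 1
    return count / total


def spearman_one_sided(x, y, alternative: str, method: str = "t") -> CorrelationResult:
    """One-sided Spearman correlation test.

    ``alternative="less"`` tests for negative association, ``"greater"`` for
    positive.  ``method="t"`` uses the t approximation on n−2 degrees of
    freedom; ``method="exact"`` enumerates all rank permutations (n ≤ 9).
    NA pairs are removed pairwise before anything else.
    """
    if alternative not in ("less", "greater"):
        raise ValidationError(f"alternative must be 'less' or 'greater', got {alternative!r}")
    x, y = _clean_pairs(x, y)
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n}")
    _check_not_constant(x, y)
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "exact":
        if n > EXACT_N_MAX:
            raise ValidationError(f"exact permutation p limited to n <= {EXACT_N_MAX}, got {n}")
        p = _exact_p(rx, ry, rho, alternative)
    elif method == "t":
        if abs(rho) >= 1.0:
            p = 0.0  # perfect monotone order in the tested direction
            if (alternative == "less") != (rho < 0):
                p = 1.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            if alternative == "less":
                p = float(sps.t.cdf(t, df=n - 2))
            else:
                p = float(sps.t.sf(t, df=n - 2))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return CorrelationResult(
        rho=rho,
        p_one_sided=p,
        alternative=alternative,
        n=n,
        r_squared=r_squared(x, y),
        method=method,
    )


def r_squared(x, y) -> float:
    """Coefficient of determination of the least-squares line y = a + b·x.

    For simple regression this equals the squared Pearson correlation, which
    also makes the value symmetric in x and y.
    """
    x, y = _clean_pairs(x, y)
    if x.size < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise UndefinedMetricError("R^2 undefined: x is constant")
    xc = x - x.mean()
    b = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    a = float(y.mean() - b * x.mean())
    ss_res = float(np.sum((y - (a + b * x)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def bootstrap_corr_ci(
    x,
    y,
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for Spearman's rho.

    Sites (x, y pairs) are resampled with replacement ``n_boot`` times and
    rho recomputed per replicate.  Replicates in which either resampled
    vector is constant are redrawn and counted; more degenerate draws than
    ``n_boot`` aborts (the data are too small or too tied to bootstrap).
    """
    x, y = _clean_pairs(x, y)
    n = x.size
    if n < 5:
        raise ValidationError(f"bootstrap needs >= 5 complete pairs, got {n}")
    _check_not_constant(x, y)
    if rng is None:
        rng = np.random.default_rng(seed)
    rhos = np.empty(n_boot, dtype=float)
    degenerate = 0
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            degenerate += 1
            if degenerate > n_boot:
                raise ValidationError(
                    f"bootstrap aborted: {degenerate} degenerate replicates "
                    f"(> 50% of draws); data too small or too tied"
                )
            continue
        rxb = sps.rankdata(xb, method="average")
        ryb = sps.rankdata(yb, method="average")
        rhos[filled] = np.corrcoef(rxb, ryb)[0, 1]
        filled += 1
    if degenerate:
        logger.warning("DEGENERATE_BOOT n=%d of %d draws redrawn", degenerate, n_boot + degenerate)
    lo_q = (1.0 - ci_level) / 2.0
    ci_low, ci_high = np.quantile(rhos, [lo_q, 1.0 - lo_q])
    return float(ci_low), float(ci_high)


def correlate(
    x,
    y,
    alternative: str,
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed: int | None = None,
    method: str = "t",
) -> CorrelationResult:
    """One-sided Spearman test plus R² plus a bootstrap CI, in one record."""
    result = spearman_one_sided(x, y, alternative, method=method)
    ci_low, ci_high = bootstrap_corr_ci(x, y, n_boot=n_boot, ci_level=ci_level, seed=seed)
    result.ci_low = ci_low
    result.ci_high = ci_high
    result.n_boot = n_boot
    result.ci_level = ci_level
    result.seed = seed
    return result
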