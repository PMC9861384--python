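"""Hypothesis testing for the univariate concordance statistic.

Tests H0: concordance = 0.5 with a z-statistic whose variance is the
average of two estimators with complementary bias:

* ``cvar`` -- the exact permutation (null) variance of the weighted
  concordance tally given the realized comparability pattern.  It is
  unbiased when the true concordance is 0.5 and conservative otherwise.
* ``ivar`` -- an infinitesimal-jackknife variance built from
  per-observation influence values of the weighted concordance ratio.
  It is approximately unbiased away from 0.5 but can under-estimate
  near the null.

z = (estimate - 0.5) / sqrt((cvar + ivar) / 2), referred to the standard
normal.  Both estimators use the same bridge-pair weight as the point
estimate, so the test describes exactly the statistic that was computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
from scipy import stats

from .core import (
    ArrayLike,
    CensoredVector,
    Mode,
    PairPartition,
    RoxEstimate,
    _estimate_from_partition,
    as_censored,
    partition_pairs,
)

__all__ = ["RoxTestResult", "cvar_null", "ivar_jackknife", "rox_test"]

Alternative = Literal["two-sided", "greater", "less"]


@dataclass(frozen=True)
class RoxTestResult:
    """Concordance estimate with its z-test against H0: concordance = 0.5."""

    estimate: float
    cvar: float
    ivar: float
    z: float
    pvalue: float
    n_effective: int
    detail: Optional[RoxEstimate] = None


def _weighted_pairs(part: PairPartition, p_weight: float):
    if part.pairs is None:
        raise ValueError("partition must be built with keep_pairs=True")
    pr = part.pairs
    w = np.where(pr.bridge, p_weight, 1.0)
    keep = w > 0
    return pr.lo[keep], pr.hi[keep], w[keep], pr.score[keep]


def _null_pair_moments(xa: np.ndarray) -> tuple[float, float]:
    """Moments of the pair score under permutation of the realized x.

    For a random pair drawn without replacement from the multiset of
    covariate values, the concordance score (1 / 0.5 / 0) has variance
    ``v2``; two scores sharing an observation in the same role have
    covariance ``cplus`` (opposite roles: ``-cplus``).  Without ties
    these are the classical 1/4 and 1/12 of Kendall-type statistics.
    """
    n = xa.size
    xs = np.sort(xa)
    right = np.searchsorted(xs, xa, side="right")
    left = np.searchsorted(xs, xa, side="left")
    greater = n - right
    equal = right - left - 1  # ties with *other* observations
    g = greater / (n - 1)
    e = equal / (n - 1)
    # P(two draws tied), exact over the multiset
    _, cnt = np.unique(xa, return_counts=True)
    t2 = float((cnt * (cnt - 1)).sum()) / (n * (n - 1))
    v2 = (1.0 - t2) / 4.0
    cplus = float(np.mean((g + 0.5 * e) ** 2)) - 0.25
    return v2, cplus


def _cvar_from_partition(part: PairPartition, x: np.ndarray, p_weight: float) -> float:
    lo, hi, w, _ = _weighted_pairs(part, p_weight)
    if lo.size == 0:
        raise ValueError("degenerate pair structure: no weighted comparable pairs")
    n = part.n
    active = np.union1d(lo, hi)
    if active.size < 3:
        raise ValueError("degenerate pair structure: fewer than 3 active observations")
    v2, cplus = _null_pair_moments(x[active])
    W = w.sum()
    A = np.bincount(lo, weights=w, minlength=n)
    B = np.bincount(hi, weights=w, minlength=n)
    w2 = w * w
    C = np.bincount(lo, weights=w2, minlength=n) + np.bincount(hi, weights=w2, minlength=n)
    varS = v2 * w2.sum() + cplus * float(((A - B) ** 2 - C).sum())
    return max(varS, 0.0) / W**2


def _ivar_from_partition(part: PairPartition, p_weight: float) -> float:
    lo, hi, w, s = _weighted_pairs(part, p_weight)
    if lo.size == 0:
        raise ValueError("degenerate pair structure: no weighted comparable pairs")
    n = part.n
    ws = w * s
    D = w.sum()
    d = ws.sum() / D
    Ni = np.bincount(lo, weights=ws, minlength=n) + np.bincount(hi, weights=ws, minlength=n)
    Di = np.bincount(lo, weights=w, minlength=n) + np.bincount(hi, weights=w, minlength=n)
    U = (Ni - d * Di) / D
    return float((U * U).sum())


def cvar_null(
    y: Union[CensoredVector, ArrayLike],
    x: ArrayLike,
    p_weight: float,
) -> float:
    """Null (permutation) variance of the weighted concordance estimate.

    Computed in closed form from the realized comparability/tie pattern
    under exchangeability of the covariate: unbiased when the true
    concordance is 0.5, conservative otherwise.  With ``p_weight == 0``
    only the complete stratum (and its observations) enters.
    """
    y = as_censored(y)
    x = np.asarray(x, dtype=float)
    part = partition_pairs(y, x, keep_pairs=True)
    return _cvar_from_partition(part, x, p_weight)


def ivar_jackknife(
    y: Union[CensoredVector, ArrayLike],
    x: ArrayLike,
    p_weight: float,
) -> float:
    """Infinitesimal-jackknife variance of the weighted concordance.

    Each observation's influence is its aggregate signed contribution to
    the numerator and denominator of the concordance ratio, combined by
    the delta method; the variance is the sum of squared influences.
    """
    y = as_censored(y)
    if y.n < 3:
        raise ValueError("need at least 3 observations for the jackknife")
    x = np.asarray(x, dtype=float)
    part = partition_pairs(y, x, keep_pairs=True)
    if x.size > 0 and np.all(x == x[0]):
        warnings.warn(
            "covariate is constant: influence values are all zero",
            RuntimeWarning,
            stacklevel=2,
        )
    return _ivar_from_partition(part, p_weight)


def rox_test(
    y: Union[CensoredVector, ArrayLike],
    x: ArrayLike,
    mode: Mode = "auto",
    alternative: Alternative = "two-sided",
) -> RoxTestResult:
    """z-test of the concordance statistic against H0: concordance = 0.5.

    The variance estimators are computed on the same weighted pair
    structure as the point estimate, including the complete-case switch
    of ``mode="auto"``.
    """
    y = as_censored(y)
    x = np.asarray(x, dtype=float)
    if y.n < 3:
        raise ValueError("need at least 3 observations for inference")
    part = partition_pairs(y, x, keep_pairs=True)
    x_constant = bool(x.size > 0 and np.all(x == x[0]))
    if x_constant:
        warnings.warn(
            "covariate is constant: test is degenerate, p-value 1",
            RuntimeWarning,
            stacklevel=2,
        )
    est = _estimate_from_partition(part, mode, x_constant=x_constant)
    p_used = est.p_weight
    cvar = _cvar_from_partition(part, x, p_used)
    ivar = _ivar_from_partition(part, p_used)
    se = float(np.sqrt((cvar + ivar) / 2.0))
    diff = est.estimate - 0.5
    if diff == 0.0:
        z = 0.0
    elif se == 0.0:
        z = float(np.sign(diff)) * float("inf")
    else:
        z = diff / se
    if alternative == "two-sided":
        pvalue = 2.0 * float(stats.norm.sf(abs(z)))
    elif alternative == "greater":
        pvalue = float(stats.norm.sf(z))
    elif alternative == "less":
        pvalue = float(stats.norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    n_effective = part.n if p_used > 0 and part.countb > 0 else part.n1
    return RoxTestResult(
        estimate=est.estimate,
        cvar=cvar,
        ivar=ivar,
        z=z,
        pvalue=min(pvalue, 1.0),
        n_effective=n_effective,
        detail=est,
    )
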