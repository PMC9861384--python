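"""Semiparametric multivariable concordance regression.

Models the probability that one observation's response exceeds
another's through an exponential link on a linear score eta = X beta:
for an oriented comparable pair (lo, hi) with y[lo] < y[hi],

    P(y[lo] < y[hi]) = exp(eta[hi]) / (exp(eta[lo]) + exp(eta[hi]))
                     = sigmoid(eta[hi] - eta[lo]).

Positive coefficients therefore mean "higher covariate, higher
response" (concordance above 0.5).  The pairwise log-likelihood sums
these terms over the comparable pairs, weighting the bridge stratum
(one response missing, ranked lowest) by the debiasing weight ``n1/n``
when the missingness pattern is LOD-consistent and by 0 otherwise --
exactly mirroring the univariate estimator.

Because overlapping pairs share observations, the pairwise likelihood
is a composite likelihood: the reported standard errors use a
Godambe (sandwich) covariance with per-observation score clustering,
which keeps the Wald tests calibrated.  The naive inverse-Hessian
covariance is also retained on the fit object for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .core import (
    ArrayLike,
    CensoredVector,
    Mode,
    PairPartition,
    RoxEstimate,
    as_censored,
    default_weight,
    lod_consistency,
    partition_pairs,
    rox,
    _oriented_pairs,
)

__all__ = ["ConregFit", "pair_loglik", "fit_conreg", "wald_tests"]

_MAX_BETA_NORM = 50.0


@dataclass(frozen=True)
class ConregFit:
    """Result of a multivariable concordance-regression fit."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    overall_concordance: RoxEstimate
    wald_z: np.ndarray
    wald_p: np.ndarray
    names: list[str]
    p_weight: float
    lod_consistent: Optional[bool]
    cov: np.ndarray
    cov_naive: np.ndarray
    mode: Mode = "auto"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "z": self.wald_z,
                "p": self.wald_p,
            },
            index=self.names,
        )


def pair_loglik(
    eta: ArrayLike,
    part: PairPartition,
    p: float = 1.0,
    lod_consistent: bool = True,
) -> float:
    """Pairwise log-likelihood of a score vector ``eta``.

    Each comparable pair contributes the log-probability of its realized
    response ordering, ``log sigmoid(eta[hi] - eta[lo])`` (computed via
    log-sum-exp, overflow-safe).  Complete pairs weigh 1; bridge pairs
    weigh ``p`` if ``lod_consistent`` else 0.  Only pairwise differences
    of ``eta`` matter: the value is invariant under ``eta + c``.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    if part.pairs is None:
        raise ValueError("partition must be built with keep_pairs=True")
    pr = part.pairs
    delta = eta[pr.hi] - eta[pr.lo]
    terms = -np.logaddexp(0.0, -delta)  # log sigmoid(delta)
    wb = p if lod_consistent else 0.0
    return float(terms[~pr.bridge].sum() + wb * terms[pr.bridge].sum())


def _validate_design(
    X: Union[pd.DataFrame, ArrayLike], n: int, names: Optional[Sequence[str]]
) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        resolved = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        resolved = list(names) if names is not None else [f"x{j}" for j in range(Xa.shape[1])]
    if Xa.ndim != 2:
        raise ValueError("design matrix must be two-dimensional")
    if Xa.shape[0] != n:
        raise ValueError(f"design has {Xa.shape[0]} rows, expected {n}")
    if len(resolved) != Xa.shape[1]:
        raise ValueError("number of column names does not match design")
    if not np.all(np.isfinite(Xa)):
        raise ValueError("design matrix must have no missing or non-finite entries")
    k = Xa.shape[1]
    if k < 1:
        raise ValueError("design matrix needs at least one column")
    centered = Xa - Xa.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    if np.any(norms == 0):
        bad = resolved[int(np.argmin(norms))]
        raise ValueError(f"constant column {bad!r} in design matrix")
    if np.linalg.matrix_rank(centered) < k:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    return Xa, resolved


def _newton(
    Xd: np.ndarray,
    w: np.ndarray,
    max_iter: int,
    gtol: float,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Maximize the weighted pairwise log-likelihood; returns
    (beta, negative Hessian, loglik, converged, n_iter)."""
    keep = w > 0
    Xd = Xd[keep]
    w = w[keep]
    if Xd.shape[0] == 0:
        raise ValueError("no weighted comparable pairs to fit on")
    k = Xd.shape[1]
    beta = np.zeros(k)
    W = w.sum()

    def loglik_of(delta: np.ndarray) -> float:
        return float(-(w * np.logaddexp(0.0, -delta)).sum())

    delta = Xd @ beta
    ll = loglik_of(delta)
    converged = False
    diverged = False
    it = 0
    for it in range(1, max_iter + 1):
        sig = expit(delta)
        grad = Xd.T @ (w * (1.0 - sig))
        if np.max(np.abs(grad)) < gtol * max(1.0, W):
            converged = True
            break
        h = w * sig * (1.0 - sig)
        negH = (Xd * h[:, None]).T @ Xd
        try:
            step = np.linalg.solve(negH, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(negH, grad, rcond=None)[0]
        # step halving: the likelihood is concave but a full Newton step
        # can overshoot far from the optimum
        dstep = Xd @ step
        scale = 1.0
        for _ in range(30):
            cand_delta = delta + scale * dstep
            ll_new = loglik_of(cand_delta)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        delta = delta + scale * dstep
        ll = ll_new
        if np.linalg.norm(beta) > _MAX_BETA_NORM:
            diverged = True
            break
    if diverged:
        warnings.warn(
            "coefficients diverging (separation); fit capped",
            RuntimeWarning,
            stacklevel=3,
        )
        beta = beta * (_MAX_BETA_NORM / np.linalg.norm(beta))
        delta = Xd @ beta
        ll = loglik_of(delta)
    sig = expit(delta)
    h = w * sig * (1.0 - sig)
    negH = (Xd * h[:, None]).T @ Xd
    return beta, negH, ll, converged, it


def _sandwich_cov(
    Xd: np.ndarray,
    w: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    n: int,
    beta: np.ndarray,
    negH: np.ndarray,
) -> np.ndarray:
    """Godambe covariance H^-1 V H^-1 with scores clustered by observation."""
    keep = w > 0
    Xd, w, lo, hi = Xd[keep], w[keep], lo[keep], hi[keep]
    sig = expit(Xd @ beta)
    psi = Xd * (w * (1.0 - sig))[:, None]  # per-pair score, k columns
    k = psi.shape[1]
    S = np.zeros((n, k))
    for j in range(k):
        S[:, j] = np.bincount(lo, weights=psi[:, j], minlength=n) + np.bincount(
            hi, weights=psi[:, j], minlength=n
        )
    V = S.T @ S - psi.T @ psi
    Hinv = np.linalg.pinv(negH)
    return Hinv @ V @ Hinv


def fit_conreg(
    y: Union[CensoredVector, ArrayLike],
    X: Union[pd.DataFrame, ArrayLike],
    mode: Mode = "auto",
    *,
    max_iter: int = 100,
    gtol: float = 1e-8,
    names: Optional[Sequence[str]] = None,
) -> ConregFit:
    """Fit the multivariable concordance regression by Newton iteration.

    ``mode="auto"`` first fits with all comparable pairs weighted 1,
    checks the LOD consistency of the response against the fitted score
    (one pass, no iteration), then refits with the bridge weight
    ``n1/n`` if consistent and 0 (complete-case) otherwise.
    ``mode="strict"`` / ``"cca"`` force the two extremes.

    The overall model concordance is the univariate statistic between
    the response and the fitted score X beta.
    """
    y = as_censored(y)
    Xa, resolved = _validate_design(X, y.n, names)
    k = Xa.shape[1]
    if y.n < k + 2:
        raise ValueError(f"need at least k+2 = {k + 2} observations, got {y.n}")
    if y.n1 < 2:
        raise ValueError("insufficient observed values (need at least 2)")
    lo, hi, bridge, _, _ = _oriented_pairs(y)
    if np.count_nonzero(~bridge) == 0:
        raise ValueError("no complete pairs: regression undefined")
    Xd = Xa[hi] - Xa[lo]
    p_default = default_weight(y.n1, y.n)
    n0 = y.n0

    consistent: Optional[bool] = None
    if mode == "auto":
        if n0 == 0:
            p_final = p_default  # no bridge pairs; weight is irrelevant
        else:
            # the preliminary score only feeds the d1/db direction check,
            # so a loose tolerance suffices
            w_pre = np.ones(Xd.shape[0])
            beta_pre, _, _, _, _ = _newton(Xd, w_pre, max_iter, max(gtol, 1e-4))
            eta_pre = Xa @ beta_pre
            part_pre = partition_pairs(y, eta_pre)
            consistent, _, _, _ = lod_consistency(part_pre)
            p_final = p_default if consistent else 0.0
    elif mode == "strict":
        p_final = p_default
    elif mode == "cca":
        p_final = 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    w = np.where(bridge, p_final, 1.0)
    beta, negH, ll, converged, n_iter = _newton(Xd, w, max_iter, gtol)
    cov_naive = np.linalg.pinv(negH)
    cov = _sandwich_cov(Xd, w, lo, hi, y.n, beta, negH)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald_z = np.where(se > 0, beta / se, 0.0)
    wald_p = 2.0 * stats.norm.sf(np.abs(wald_z))

    eta_hat = Xa @ beta
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant score at beta=0
        overall = rox(y, eta_hat, mode=mode)

    return ConregFit(
        beta=beta,
        se=se,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        overall_concordance=overall,
        wald_z=wald_z,
        wald_p=wald_p,
        names=resolved,
        p_weight=p_final,
        lod_consistent=consistent,
        cov=cov,
        cov_naive=cov_naive,
        mode=mode,
    )


def wald_tests(fit: ConregFit) -> pd.DataFrame:
    """Per-coefficient Wald z-statistics and two-sided normal p-values."""
    if not fit.converged:
        raise ValueError("fit did not converge; Wald tests unreliable")
    if np.any(fit.se == 0):
        raise ValueError("zero standard error; Wald test undefined")
    z = fit.beta / fit.se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"z": z, "p": p}, index=fit.names)
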