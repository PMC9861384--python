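"""Concordance estimation for left-censored measurements.

Values below an instrument's limit of detection (LOD) are reported as
missing, but they still carry rank information: under the LOD assumption
every missing value is lower than every observed one.  A pair of
observations is therefore *comparable* whenever at least one response
value is observed.  The estimator implemented here scores concordance
over two strata of comparable pairs -- "complete" pairs (both responses
observed, ties in the response dropped) and "bridge" pairs (exactly one
response missing) -- and down-weights the bridge stratum by the observed
fraction ``n1/n`` to remove the upward bias caused by discarding
missing-missing pairs.  A self-adjusting check compares the concordance
of the two strata and falls back to complete-case analysis when the
observed missingness pattern contradicts the LOD assumption.

Conventions (shared by every operation in this package):

* ties in the response between two observed values are dropped;
* ties in the covariate score 0.5 (neither concordant nor discordant),
  in both strata;
* an estimate of 1 means perfect concordance, 0 perfect discordance,
  0.5 random ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Optional, Sequence, Union

import numpy as np


@lru_cache(maxsize=4)
def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    # repeated calls at the same sample size dominate simulation loops
    return np.triu_indices(n, k=1)

__all__ = [
    "CensoredVector",
    "PairIndex",
    "PairPartition",
    "RoxEstimate",
    "partition_pairs",
    "rox_core",
    "rox_weighted",
    "default_weight",
    "lod_consistency",
    "rox",
]

Mode = Literal["auto", "strict", "cca"]
ArrayLike = Union[Sequence[float], np.ndarray]


@dataclass(frozen=True)
class CensoredVector:
    """A response vector with an explicit missingness mask.

    ``mask[i] == True`` marks a missing (below-LOD) entry.  The numeric
    slot of a masked position is never read; any placeholder (NaN or
    otherwise) is ignored by all operations.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if mask.shape != values.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match values shape {values.shape}"
            )
        if not np.all(np.isfinite(values[~mask])):
            raise ValueError("observed (unmasked) values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_values(cls, values: ArrayLike) -> "CensoredVector":
        """Build from a float array where NaN encodes missingness."""
        values = np.asarray(values, dtype=float)
        return cls(values=values, mask=np.isnan(values))

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n1(self) -> int:
        """Number of observed entries."""
        return int(np.count_nonzero(~self.mask))

    @property
    def n0(self) -> int:
        """Number of missing entries."""
        return int(np.count_nonzero(self.mask))

    def observed(self) -> np.ndarray:
        return self.values[~self.mask]


def as_censored(y: Union[CensoredVector, ArrayLike]) -> CensoredVector:
    """Coerce an array (NaN = missing) or CensoredVector to CensoredVector."""
    if isinstance(y, CensoredVector):
        return y
    return CensoredVector.from_values(y)


@dataclass(frozen=True)
class PairIndex:
    """Oriented comparable pairs: ``lo`` has the lower response.

    For bridge pairs ``lo`` is the missing observation (missing ranks
    below every observed value under the LOD assumption).  ``score`` is
    the concordance contribution of each pair from the covariate:
    1 if x[lo] < x[hi], 0.5 on a covariate tie, 0 otherwise.
    """

    lo: np.ndarray
    hi: np.ndarray
    bridge: np.ndarray
    score: np.ndarray


@dataclass(frozen=True)
class PairPartition:
    """Counts and concordance tallies over the comparable-pair strata."""

    count1: int
    countb: int
    conc1: float
    concb: float
    dropped_y_ties: int
    noncomparable: int
    n: int
    n1: int
    pairs: Optional[PairIndex] = field(default=None, compare=False, repr=False)

    @property
    def d1(self) -> float:
        """Concordance of the complete-pair stratum."""
        if self.count1 == 0:
            return float("nan")
        return self.conc1 / self.count1

    @property
    def db(self) -> float:
        """Concordance of the bridge-pair stratum."""
        if self.countb == 0:
            return float("nan")
        return self.concb / self.countb


@dataclass(frozen=True)
class RoxEstimate:
    """Point estimate of the concordance together with its provenance."""

    estimate: float
    p_weight: float
    d1: float
    db: float
    lod_consistent: Optional[bool]
    direction: Literal["positive", "negative", "undetermined"]
    partition: PairPartition
    mode: Mode = "auto"
    x_constant: bool = False


def _oriented_pairs(y: CensoredVector) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Enumerate oriented comparable pairs of ``y``.

    Returns ``(lo, hi, bridge, dropped_y_ties, noncomparable)`` where
    ``lo``/``hi`` index into the original vector and ``bridge`` flags
    pairs with exactly one missing response.
    """
    mask = y.mask
    obs = np.flatnonzero(~mask)
    mis = np.flatnonzero(mask)
    n1 = obs.size
    n0 = mis.size
    if n1 == 0:
        raise ValueError("no observed values in y")
    vals = y.values

    # complete pairs (both observed), oriented by the response
    iu, ju = _triu_indices(n1)
    a = obs[iu]
    b = obs[ju]
    ya = vals[a]
    yb = vals[b]
    tie = ya == yb
    dropped = int(np.count_nonzero(tie))
    keep = ~tie
    a, b, ya, yb = a[keep], b[keep], ya[keep], yb[keep]
    swap = ya > yb
    lo1 = np.where(swap, b, a)
    hi1 = np.where(swap, a, b)

    # bridge pairs: missing response ranks below every observed one
    lob = np.repeat(mis, n1)
    hib = np.tile(obs, n0)

    lo = np.concatenate([lo1, lob])
    hi = np.concatenate([hi1, hib])
    bridge = np.zeros(lo.size, dtype=bool)
    bridge[lo1.size:] = True
    noncomparable = n0 * (n0 - 1) // 2
    return lo, hi, bridge, dropped, noncomparable


def partition_pairs(
    y: Union[CensoredVector, ArrayLike],
    x: ArrayLike,
    *,
    keep_pairs: bool = False,
) -> PairPartition:
    """Classify every unordered pair and tally concordance per stratum.

    Pairs with both responses missing are noncomparable; pairs of equal
    observed responses are dropped; the rest split into the complete
    stratum (both observed) and the bridge stratum (one missing, ranked
    lowest).  Covariate ties score 0.5 in either stratum.

    Parameters
    ----------
    y : response with missing entries (CensoredVector or NaN-coded array)
    x : fully observed covariate, same length as ``y``
    keep_pairs : retain the oriented pair index arrays on the result
        (needed by the inference and regression layers).
    """
    y = as_censored(y)
    x = np.asarray(x, dtype=float)
    if x.shape != (y.n,):
        raise ValueError(f"x has length {x.size}, expected {y.n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be fully observed and finite")
    lo, hi, bridge, dropped, noncomp = _oriented_pairs(y)

    xlo = x[lo]
    xhi = x[hi]
    score = (xlo < xhi).astype(float)
    score[xlo == xhi] = 0.5

    count1 = int(np.count_nonzero(~bridge))
    countb = int(np.count_nonzero(bridge))
    conc1 = float(score[~bridge].sum())
    concb = float(score[bridge].sum())
    pairs = PairIndex(lo=lo, hi=hi, bridge=bridge, score=score) if keep_pairs else None
    return PairPartition(
        count1=count1,
        countb=countb,
        conc1=conc1,
        concb=concb,
        dropped_y_ties=dropped,
        noncomparable=noncomp,
        n=y.n,
        n1=y.n1,
        pairs=pairs,
    )


def rox_core(part: PairPartition) -> float:
    """Strict-LOD concordance: all comparable pairs weighted equally (p = 1)."""
    return rox_weighted(part, 1.0)


def rox_weighted(part: PairPartition, p: float) -> float:
    """Weighted concordance ``(conc1 + p*concb) / (count1 + p*countb)``.

    ``p = 1`` reproduces the strict-LOD estimator; ``p = 0`` reproduces
    complete-case concordance.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"weight p must be in [0, 1], got {p}")
    denom = part.count1 + p * part.countb
    if denom <= 0:
        raise ValueError("no comparable pairs at this weight")
    return (part.conc1 + p * part.concb) / denom


def default_weight(n1: int, n: int) -> float:
    """Debiasing weight ``n1/n`` (observed fraction) for the bridge stratum."""
    if n1 <= 0:
        raise ValueError("n1 must be positive")
    if n1 > n:
        raise ValueError("n1 cannot exceed n")
    return n1 / n


def lod_consistency(
    part: PairPartition,
) -> tuple[Optional[bool], Literal["positive", "negative", "undetermined"], float, float]:
    """Check whether the missingness pattern is consistent with an LOD.

    Under a strict LOD with positive association (d1 >= 0.5) the bridge
    stratum must be *more* concordant than the complete stratum
    (d1 < db); under negative association the inequality mirrors
    (db < d1).  A failed check signals non-LOD missingness and the
    estimator falls back to complete-case analysis.

    Returns ``(lod_consistent, direction, d1, db)``.  With no bridge
    pairs the check is not applicable: ``(None, direction, d1, nan)``.
    Boundary ``d1 == db`` counts as inconsistent (the strict inequality
    fails).
    """
    if part.count1 == 0:
        raise ValueError("no complete pairs: LOD-consistency check undefined")
    d1 = part.d1
    direction: Literal["positive", "negative"] = "positive" if d1 >= 0.5 else "negative"
    if part.countb == 0:
        return None, direction, d1, float("nan")
    db = part.db
    consistent = (d1 < db) if direction == "positive" else (db < d1)
    return bool(consistent), direction, d1, db


def _estimate_from_partition(
    part: PairPartition, mode: Mode, *, x_constant: bool = False
) -> RoxEstimate:
    if mode not in ("auto", "strict", "cca"):
        raise ValueError(f"unknown mode {mode!r}")
    if part.n1 < 2:
        raise ValueError("insufficient observed values (need at least 2)")
    if part.count1 == 0:
        raise ValueError(
            "no complete pairs (all observed responses tied); estimate undefined"
        )
    consistent, direction, d1, db = lod_consistency(part)
    p_default = default_weight(part.n1, part.n)
    if part.countb == 0:
        # no missing values: every mode degenerates to the classical c-index
        return RoxEstimate(
            estimate=part.conc1 / part.count1,
            p_weight=p_default,
            d1=d1,
            db=db,
            lod_consistent=None,
            direction=direction,
            partition=part,
            mode=mode,
            x_constant=x_constant,
        )
    if mode == "auto":
        p = p_default if consistent else 0.0
    elif mode == "strict":
        p = p_default
    else:  # cca
        p = 0.0
    return RoxEstimate(
        estimate=rox_weighted(part, p),
        p_weight=p,
        d1=d1,
        db=db,
        lod_consistent=consistent,
        direction=direction,
        partition=part,
        mode=mode,
        x_constant=x_constant,
    )


def rox(
    y: Union[CensoredVector, ArrayLike],
    x: ArrayLike,
    mode: Mode = "auto",
) -> RoxEstimate:
    """Concordance between a left-censored response and a covariate.

    Parameters
    ----------
    y : response with missing entries (CensoredVector or NaN-coded array)
    x : fully observed covariate
    mode : ``"auto"`` applies the self-adjusting rule (bridge weight
        ``n1/n`` when the pattern is LOD-consistent, else complete-case
        analysis); ``"strict"`` always weights bridge pairs by ``n1/n``;
        ``"cca"`` always drops them.

    Returns
    -------
    RoxEstimate with the point estimate, the weight actually applied,
    the stratum concordances d1/db, and the consistency verdict.
    """
    y = as_censored(y)
    x = np.asarray(x, dtype=float)
    if y.n1 < 2:
        raise ValueError("insufficient observed values (need at least 2)")
    part = partition_pairs(y, x)
    x_constant = bool(x.size > 0 and np.all(x == x[0]))
    if x_constant:
        warnings.warn(
            "covariate is constant: every pair is tied in x, estimate is 0.5",
            RuntimeWarning,
            stacklevel=2,
        )
    return _estimate_from_partition(part, mode, x_constant=x_constant)
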