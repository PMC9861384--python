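"""Competitor methods and ground-truth utilities.

Implements the approaches the concordance framework is benchmarked
against -- complete-case analysis is simply ``rox(..., mode="cca")``;
this module adds minimum imputation, the classical tie-aware c-index,
and the construction of high-confidence hits (HC-hits) on case/control
feature panels: the union of complete-case Wilcoxon rank-sum hits and
Fisher's-exact-on-missingness hits, each Bonferroni-adjusted across
features.  Both component tests have low false-positive rates under
opposite missingness mechanisms, so their union serves as a
ground-truth proxy when no true association list exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ArrayLike, CensoredVector, as_censored, partition_pairs

__all__ = ["HCHitResult", "min_impute", "cindex", "hc_hits"]

logger = logging.getLogger(__name__)

Variant = Literal["min", "half_min", "below_min"]


@dataclass(frozen=True)
class HCHitResult:
    """Per-feature outcome of the high-confidence hit construction."""

    feature: str
    wilcoxon_p: float
    fisher_p: float
    wilcoxon_p_adj: float
    fisher_p_adj: float
    is_hc_hit: bool
    excluded: bool = False
    reason: str = ""


def min_impute(
    y: Union[CensoredVector, ArrayLike], variant: Variant = "min"
) -> np.ndarray:
    """Fill missing entries with a low constant.

    ``"min"`` uses the observed minimum, ``"half_min"`` half of it (the
    common practice on raw, positive intensities), ``"below_min"`` a
    constant strictly below the observed minimum -- the variant whose
    ranks reproduce the strict-LOD ordering exactly.
    """
    y = as_censored(y)
    if y.n1 == 0:
        raise ValueError("cannot impute: all values missing")
    m = float(y.observed().min())
    if variant == "min":
        fill = m
    elif variant == "half_min":
        fill = m / 2.0
    elif variant == "below_min":
        fill = m - 1.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    out = y.values.copy()
    out[y.mask] = fill
    return out


def cindex(y_complete: ArrayLike, x: ArrayLike) -> float:
    """Classical tie-aware concordance index on complete data.

    Pairs tied in ``y`` are dropped; pairs tied in ``x`` score 0.5.
    """
    y = np.asarray(y_complete, dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("y_complete must have no missing values")
    cv = CensoredVector(values=y, mask=np.zeros(y.size, dtype=bool))
    part = partition_pairs(cv, x)
    if part.count1 < 1:
        raise ValueError("fewer than one usable (untied) pair")
    return part.conc1 / part.count1


def hc_hits(
    data: pd.DataFrame,
    group: Sequence,
    alpha: float = 0.05,
    correction: Literal["bonferroni", "bh"] = "bonferroni",
) -> pd.DataFrame:
    """High-confidence hits on a samples x features panel with two groups.

    Per feature: a Wilcoxon rank-sum test on the observed values only
    (complete-case) and Fisher's exact test on the 2x2
    missing/observed x group table.  P-values are adjusted across
    features within each test family; a feature is an HC-hit if either
    adjusted p-value falls below ``alpha`` (union rule).  Features with
    fewer than 2 observed values in either group are excluded with a
    logged reason.

    Returns a DataFrame with raw and adjusted p-values, the hit flag,
    and exclusion bookkeeping, indexed like ``data``'s columns.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float))
    group = np.asarray(group)
    if group.shape[0] != data.shape[0]:
        raise ValueError("group labels must match the number of samples (rows)")
    levels = pd.unique(group)
    if levels.size != 2:
        raise ValueError(f"need exactly two groups, got {levels.size}")
    in_g1 = group == levels[1]
    if in_g1.all() or (~in_g1).all():
        raise ValueError("both groups must be non-empty")

    records: list[HCHitResult] = []
    for feat in data.columns:
        col = data[feat].to_numpy(dtype=float)
        missing = np.isnan(col)
        obs0 = col[~missing & ~in_g1]
        obs1 = col[~missing & in_g1]
        if obs0.size < 2 or obs1.size < 2:
            reason = "fewer than 2 observed values in a group"
            logger.info("excluding feature %s: %s", feat, reason)
            records.append(
                HCHitResult(str(feat), np.nan, np.nan, np.nan, np.nan, False, True, reason)
            )
            continue
        # exact Wilcoxon for small untied samples, tie-corrected normal
        # approximation otherwise (scipy's automatic policy)
        wp = float(
            stats.mannwhitneyu(obs0, obs1, alternative="two-sided", method="auto").pvalue
        )
        table = [
            [int((missing & ~in_g1).sum()), int((~missing & ~in_g1).sum())],
            [int((missing & in_g1).sum()), int((~missing & in_g1).sum())],
        ]
        fp = float(stats.fisher_exact(table, alternative="two-sided")[1])
        records.append(HCHitResult(str(feat), wp, fp, np.nan, np.nan, False))

    out = pd.DataFrame(
        {
            "wilcoxon_p": [r.wilcoxon_p for r in records],
            "fisher_p": [r.fisher_p for r in records],
            "excluded": [r.excluded for r in records],
            "reason": [r.reason for r in records],
        },
        index=[r.feature for r in records],
    )
    method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
    included = ~out["excluded"]
    for col in ("wilcoxon_p", "fisher_p"):
        adj = np.full(len(out), np.nan)
        if included.any():
            adj[included.to_numpy()] = multipletests(
                out.loc[included, col].to_numpy(), method=method
            )[1]
        out[col + "_adj"] = adj
    out["is_hc_hit"] = (
        (out["wilcoxon_p_adj"] < alpha) | (out["fisher_p_adj"] < alpha)
    ).fillna(False) & included
    return out
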