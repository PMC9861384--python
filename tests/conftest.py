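"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use plain double loops over index pairs
so they share no code path with the vectorized implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from rox.core import CensoredVector


def brute_partition(yvals, mask, x):
    """O(n^2) double-loop pair classification, independent of the package.

    Returns (count1, countb, conc1, concb, dropped_y_ties, noncomparable).
    """
    n = len(yvals)
    count1 = countb = dropped = noncomp = 0
    conc1 = concb = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = mask[i], mask[j]
            if mi and mj:
                noncomp += 1
                continue
            if not mi and not mj:
                if yvals[i] == yvals[j]:
                    dropped += 1
                    continue
                count1 += 1
                lo, hi = (i, j) if yvals[i] < yvals[j] else (j, i)
                if x[lo] < x[hi]:
                    conc1 += 1.0
                elif x[lo] == x[hi]:
                    conc1 += 0.5
            else:
                countb += 1
                lo, hi = (i, j) if mi else (j, i)  # missing ranks lowest
                if x[lo] < x[hi]:
                    concb += 1.0
                elif x[lo] == x[hi]:
                    concb += 0.5
    return count1, countb, conc1, concb, dropped, noncomp


def brute_cindex(y, x):
    """Tie-aware c-index by double loop (y-ties dropped, x-ties 0.5)."""
    c1, cb, s1, sb, _, _ = brute_partition(list(y), [False] * len(y), list(x))
    assert cb == 0
    return s1 / c1


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_censored_instance(rng, n_max=12, allow_ties=True):
    """A small random instance: (CensoredVector, x) with mixed patterns."""
    n = int(rng.integers(4, n_max + 1))
    if allow_ties and rng.random() < 0.5:
        y = rng.integers(0, 4, size=n).astype(float)  # frequent y-ties
        x = rng.integers(0, 4, size=n).astype(float)  # frequent x-ties
    else:
        y = rng.standard_normal(n)
        x = rng.standard_normal(n)
    mask = rng.random(n) < 0.3
    if (~mask).sum() < 2:
        mask[:2] = False
    return CensoredVector(values=y, mask=mask), x
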