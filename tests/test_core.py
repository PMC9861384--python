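"""Pair partitioning and the univariate concordance estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rox import (
    CensoredVector,
    cindex,
    default_weight,
    lod_consistency,
    min_impute,
    partition_pairs,
    rox,
    rox_core,
    rox_weighted,
)
from rox.core import PairPartition

from conftest import brute_partition, random_censored_instance

NA = np.nan


class TestPartitionPairs:
    @pytest.mark.parametrize(
        "y, x, expected",
        [
            # perfect monotone complete data
            ([1, 2, 3], [1, 2, 3], dict(count1=3, countb=0, conc1=3.0)),
            # missing value is comparable to (and below) every observed one
            ([NA, 2, 3], [1, 2, 3], dict(count1=1, countb=2, conc1=1.0, concb=2.0)),
            # missing-missing pairs are noncomparable
            ([NA, NA, 3], [1, 2, 3], dict(count1=0, countb=2, noncomparable=1)),
            # observed response ties are dropped
            ([1, 2, 2], [1, 2, 3], dict(count1=2, dropped_y_ties=1)),
        ],
    )
    def test_stratum_counts(self, y, x, expected):
        part = partition_pairs(np.array(y, dtype=float), x)
        for key, val in expected.items():
            assert getattr(part, key) == val

    def test_x_tie_scores_half_in_both_strata(self):
        part = partition_pairs(np.array([NA, 2.0, 3.0]), [5.0, 5.0, 5.0])
        assert part.conc1 == 0.5
        assert part.concb == 1.0  # two bridge pairs at 0.5 each

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            partition_pairs(np.array([1.0, 2.0]), [1.0, 2.0, 3.0])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            partition_pairs(np.array([NA, NA]), [1.0, 2.0])

    def test_strata_exhaust_all_pairs(self, rng):
        for _ in range(50):
            yc, x = random_censored_instance(rng)
            part = partition_pairs(yc, x)
            total = part.count1 + part.countb + part.dropped_y_ties + part.noncomparable
            assert total == yc.n * (yc.n - 1) // 2

    @given(st.data())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_double_loop_oracle(self, data):
        n = data.draw(st.integers(3, 12))
        y = data.draw(
            st.lists(st.integers(0, 5), min_size=n, max_size=n).map(
                lambda v: [float(t) for t in v]
            )
        )
        x = data.draw(
            st.lists(st.integers(0, 5), min_size=n, max_size=n).map(
                lambda v: [float(t) for t in v]
            )
        )
        mask = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if sum(not m for m in mask) == 0:
            mask[0] = False
        yc = CensoredVector(values=np.array(y), mask=np.array(mask))
        part = partition_pairs(yc, np.array(x))
        ref = brute_partition(y, mask, x)
        assert (
            part.count1,
            part.countb,
            part.conc1,
            part.concb,
            part.dropped_y_ties,
            part.noncomparable,
        ) == ref


class TestEstimators:
    def test_core_counts_bridge_pairs_equally(self):
        part = partition_pairs(np.array([NA, 2.0, 3.0]), [1.0, 2.0, 3.0])
        assert rox_core(part) == 1.0

    def test_core_discordant_bridge(self):
        # x of the missing observation is largest: all bridge pairs discordant
        part = partition_pairs(np.array([NA, 2.0, 3.0, 4.0]), [4.0, 1.0, 2.0, 3.0])
        assert part.conc1 == 3.0 and part.concb == 0.0
        assert rox_core(part) == 0.5

    def test_perfect_discordance_is_zero(self):
        part = partition_pairs(np.arange(5.0), [5.0, 4.0, 3.0, 2.0, 1.0])
        assert rox_core(part) == 0.0

    def test_weighted_interpolates(self):
        part = partition_pairs(np.array([NA, 2.0, 3.0, 4.0]), [4.0, 1.0, 2.0, 3.0])
        assert rox_weighted(part, 1.0) == rox_core(part)
        assert rox_weighted(part, 0.0) == 1.0  # complete-case
        assert rox_weighted(part, 0.75) == pytest.approx(3.0 / 5.25)

    def test_weighted_rejects_bad_weight(self):
        part = partition_pairs(np.array([1.0, 2.0, 3.0]), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            rox_weighted(part, 1.5)

    @pytest.mark.parametrize(
        "n1, n, expected", [(7, 10, 0.7), (10, 10, 1.0), (1, 100, 0.01)]
    )
    def test_default_weight(self, n1, n, expected):
        assert default_weight(n1, n) == pytest.approx(expected)

    def test_default_weight_rejects_zero_observed(self):
        with pytest.raises(ValueError):
            default_weight(0, 10)


def _partition(count1, countb, conc1, concb):
    return PairPartition(
        count1=count1, countb=countb, conc1=conc1, concb=concb,
        dropped_y_ties=0, noncomparable=0, n=count1 + countb, n1=count1,
    )


class TestLodConsistency:
    def test_positive_direction(self):
        ok, direction, d1, db = lod_consistency(_partition(10, 10, 6.0, 8.0))
        assert ok and direction == "positive" and d1 == 0.6 and db == 0.8

    def test_inconsistent_pattern(self):
        ok, _, d1, db = lod_consistency(_partition(10, 10, 10.0, 0.0))
        assert not ok and d1 == 1.0 and db == 0.0

    def test_negative_direction_mirrors(self):
        ok, direction, _, _ = lod_consistency(_partition(10, 10, 3.0, 1.0))
        assert ok and direction == "negative"

    def test_boundary_equality_is_inconsistent(self):
        ok, _, _, _ = lod_consistency(_partition(10, 10, 6.0, 6.0))
        assert not ok

    def test_no_bridge_pairs_not_applicable(self):
        ok, _, _, db = lod_consistency(_partition(10, 0, 6.0, 0.0))
        assert ok is None and np.isnan(db)


class TestRox:
    def test_perfect_concordance_complete(self):
        assert rox(np.arange(5.0), np.arange(5.0)).estimate == 1.0

    def test_self_adjustment_switches_to_cca(self):
        est = rox(np.array([NA, 2.0, 3.0, 4.0]), [4.0, 1.0, 2.0, 3.0], mode="auto")
        assert est.lod_consistent is False
        assert est.p_weight == 0.0
        assert est.estimate == 1.0

    def test_consistent_pattern_weighted(self):
        est = rox(np.array([NA, 2.0, 3.0, 4.0]), [1.0, 2.0, 3.0, 4.0], mode="auto")
        assert est.estimate == 1.0  # all comparable pairs concordant

    def test_modes_coincide_without_missingness(self, rng):
        y = rng.standard_normal(30)
        x = rng.standard_normal(30)
        vals = {m: rox(y, x, mode=m).estimate for m in ("auto", "strict", "cca")}
        assert len(set(vals.values())) == 1

    def test_estimate_bounds(self, rng):
        for _ in range(50):
            yc, x = random_censored_instance(rng)
            try:
                est = rox(yc, x)
            except ValueError:
                continue
            assert 0.0 <= est.estimate <= 1.0

    def test_too_few_observed_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            rox(np.array([NA, NA, 3.0]), [1.0, 2.0, 3.0])

    def test_constant_x_warns_and_returns_half(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            est = rox(np.array([1.0, 2.0, 3.0]), [2.0, 2.0, 2.0])
        assert est.estimate == 0.5
        assert est.x_constant

    def test_antisymmetry_in_x(self, rng):
        # negating x flips concordance: rox(y, -x) = 1 - rox(y, x).  The
        # self-adjusting mode mirrors its direction rule, except exactly at
        # d1 = 0.5 where the positive-direction tie-break applies.
        for _ in range(100):
            yc, x = random_censored_instance(rng, allow_ties=False)
            try:
                a = rox(yc, x, mode="auto")
                b = rox(yc, -x, mode="auto")
            except ValueError:
                continue
            for m in ("strict", "cca"):
                sa = rox(yc, x, mode=m).estimate
                sb = rox(yc, -x, mode=m).estimate
                assert sb == pytest.approx(1.0 - sa, abs=1e-12)
            if a.d1 != 0.5:
                assert b.estimate == pytest.approx(1.0 - a.estimate, abs=1e-12)

    def test_cca_equals_established_concordance(self, rng):
        from lifelines.utils import concordance_index

        for _ in range(100):
            yc, x = random_censored_instance(rng)
            obs = ~yc.mask
            y_obs, x_obs = yc.values[obs], x[obs]
            if np.unique(y_obs).size < 2:
                continue
            est = rox(yc, x, mode="cca").estimate
            ref = concordance_index(y_obs, x_obs)
            assert est == pytest.approx(ref, abs=1e-12)

    def test_unweighted_equals_below_min_imputation(self, rng):
        # the unweighted comparable-pair estimator (p = 1) is exactly the
        # tie-aware c-index after imputing any constant strictly below the
        # observed minimum: missing-missing pairs become dropped y-ties and
        # every other ordering is preserved
        for _ in range(200):
            yc, x = random_censored_instance(rng)
            try:
                part = partition_pairs(yc, x)
                unweighted = rox_core(part)
            except ValueError:
                continue
            imputed = min_impute(yc, "below_min")
            assert unweighted == pytest.approx(cindex(imputed, x), abs=1e-12)

    def test_auto_debiasing_beats_strict_and_cca(self, rng):
        # strict-LOD censoring of a positively concordant pair: the strict
        # estimator overshoots, complete-case undershoots, the debiased
        # self-adjusting estimator lands closest to the truth
        from rox import apply_strict_lod, tune_lambda

        d_true = 0.85
        lam, _ = tune_lambda(d_true, n=8000, seed=4)
        means = {"auto": [], "strict_p1": [], "cca": []}
        for rep in range(25):
            x = rng.standard_normal(800)
            y = x + lam * rng.standard_normal(800)
            yc = apply_strict_lod(y, 0.5)
            part = partition_pairs(yc, x)
            means["auto"].append(rox(yc, x, "auto").estimate)
            means["strict_p1"].append(rox_core(part))
            means["cca"].append(rox(yc, x, "cca").estimate)
        err = {k: abs(np.mean(v) - d_true) for k, v in means.items()}
        assert np.mean(means["strict_p1"]) > d_true  # unweighted overestimates
        assert np.mean(means["cca"]) < d_true  # complete-case underestimates
        assert err["auto"] < err["strict_p1"]
        assert err["auto"] < err["cca"]
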