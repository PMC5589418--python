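"""Fractional labeling, normalized contributions, comparisons, t-tests."""

import math

import numpy as np
import pytest

from cystrace import (
    LabelingSample,
    MassIsotopomerDistribution,
    cystine_induced_increase,
    fractional_labeling,
    normalized_contribution,
    steady_state_check,
    summarize_condition,
    unpaired_t_test,
)
from cystrace.enrichment import EnrichmentError


def mid(metabolite, fractions):
    return MassIsotopomerDistribution(metabolite, "M-57", np.asarray(fractions, float))


def make_sample(sample_id, condition, rep, akg_m5, gln_m5=0.33):
    return LabelingSample(
        sample_id=sample_id,
        condition=condition,
        replicate=rep,
        mids={
            "glutamine": mid("glutamine", [1 - gln_m5, 0, 0, 0, 0, gln_m5]),
            "alpha-ketoglutarate": mid("alpha-ketoglutarate", [1 - akg_m5, 0, 0, 0, 0, akg_m5]),
        },
    )


class TestFractionalLabeling:
    @pytest.mark.parametrize(
        "fractions, shift, expected",
        [
            ([0.67, 0, 0, 0, 0, 0.33], 5, 0.33),
            ([1, 0, 0, 0, 0, 0], 5, 0.0),
            ([0.4, 0.1, 0.1, 0.1, 0.1, 0.2], 0, 0.4),
        ],
    )
    def test_direct_read(self, fractions, shift, expected):
        assert fractional_labeling(mid("x", fractions), shift) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(Exception):
            fractional_labeling(mid("x", [1.0]), 1)


class TestNormalizedContribution:
    def test_glutamate_example(self):
        # 27% m+5 glutamate over 33% glutamine enrichment -> ~80% glutamine-derived
        glu = mid("glutamate", [0.73, 0, 0, 0, 0, 0.27])
        gln = mid("glutamine", [0.67, 0, 0, 0, 0, 0.33])
        assert normalized_contribution(glu, 5, gln, 5) == pytest.approx(0.27 / 0.33)
        assert round(100 * normalized_contribution(glu, 5, gln, 5), 1) == 81.8

    def test_identical_pools_give_one(self):
        gln = mid("glutamine", [0.67, 0, 0, 0, 0, 0.33])
        assert normalized_contribution(gln, 5, gln, 5) == pytest.approx(1.0)

    def test_unlabeled_metabolite_gives_zero(self):
        glu = mid("glutamate", [1, 0, 0, 0, 0, 0])
        gln = mid("glutamine", [0.67, 0, 0, 0, 0, 0.33])
        assert normalized_contribution(glu, 5, gln, 5) == 0.0

    def test_zero_tracer_enrichment_raises(self):
        glu = mid("glutamate", [0.9, 0, 0, 0, 0, 0.1])
        gln = mid("glutamine", [1, 0, 0, 0, 0, 0])
        with pytest.raises(EnrichmentError):
            normalized_contribution(glu, 5, gln, 5)

    def test_scale_free(self):
        # halving enrichment and labeling together leaves the ratio unchanged
        hi = normalized_contribution(
            mid("m", [0.8, 0, 0, 0, 0, 0.2]), 5, mid("glutamine", [0.6, 0, 0, 0, 0, 0.4]), 5
        )
        lo = normalized_contribution(
            mid("m", [0.9, 0, 0, 0, 0, 0.1]), 5, mid("glutamine", [0.8, 0, 0, 0, 0, 0.2]), 5
        )
        assert hi == pytest.approx(lo)


class TestCystineInducedIncrease:
    def high_low(self, high_vals, low_vals):
        highs = [make_sample(f"h{i}", "high", i, v * 0.33) for i, v in enumerate(high_vals)]
        lows = [make_sample(f"l{i}", "low", i, v * 0.33) for i, v in enumerate(low_vals)]
        return summarize_condition(highs), summarize_condition(lows)

    def test_mean_difference(self):
        high, low = self.high_low([0.6, 0.6, 0.6], [0.2, 0.2, 0.2])
        comp = cystine_induced_increase(high, low)
        assert comp.statistic == pytest.approx(0.4)

    def test_null_case(self):
        high, low = self.high_low([0.5, 0.5], [0.5, 0.5])
        assert cystine_induced_increase(high, low).statistic == pytest.approx(0.0)

    def test_antisymmetric(self):
        high, low = self.high_low([0.55, 0.65, 0.6], [0.25, 0.2, 0.3])
        forward = cystine_induced_increase(high, low).statistic
        backward = cystine_induced_increase(low, high).statistic
        assert forward == pytest.approx(-backward)
        assert forward > 0

    def test_missing_metabolite_names_condition(self):
        high, low = self.high_low([0.5], [0.4])
        with pytest.raises(EnrichmentError, match="citrate"):
            cystine_induced_increase(high, low, metabolite="citrate")


class TestSteadyState:
    def test_hand_evaluated_series(self):
        attained, when = steady_state_check([1, 2, 3, 4], [0.30, 0.31, 0.305, 0.31], rel_tol=0.05)
        assert attained and when == 2

    def test_constant_series_steady_at_first_point(self):
        attained, when = steady_state_check([0, 4, 8], [0.3, 0.3, 0.3])
        assert attained and when == 0

    def test_doubling_series_never_steady(self):
        attained, when = steady_state_check([1, 2, 3, 4], [0.1, 0.2, 0.4, 0.8])
        assert not attained and when is None

    def test_late_attainment(self):
        attained, when = steady_state_check([0, 2, 4, 8, 24], [0.05, 0.15, 0.28, 0.32, 0.33])
        assert attained and when == 24

    def test_single_point_rejected(self):
        with pytest.raises(EnrichmentError):
            steady_state_check([1], [0.3])


class TestTTest:
    def test_closed_form_example(self):
        res = unpaired_t_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.p == pytest.approx(0.0213, abs=2e-4)

    def test_identical_groups(self):
        res = unpaired_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_symmetry(self):
        a, b = [1.1, 2.3, 0.8], [2.0, 2.2, 3.1]
        fwd, back = unpaired_t_test(a, b), unpaired_t_test(b, a)
        assert fwd.t == pytest.approx(-back.t)
        assert fwd.p == pytest.approx(back.p)

    def test_matches_permutation_test(self, rng):
        a = rng.normal(0.0, 1.0, 5)
        b = rng.normal(1.2, 1.0, 5)
        res = unpaired_t_test(a, b)
        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        hits = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:5].mean() - perm[5:].mean()) >= observed - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        assert abs(res.p - p_perm) < 3 * math.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02

    def test_small_groups_rejected(self):
        with pytest.raises(EnrichmentError):
            unpaired_t_test([1.0], [2.0, 3.0])
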