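import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasetrans import (DcConfig, PeConfig, ScaleRange, TimeSeries,
                        distribution_measure, dynamic_complexity,
                        fluctuation_measure, ordinal_pattern,
                        permutation_entropy)

UNIT = ScaleRange(0.0, 1.0)


class TestFluctuation:
    def test_constant_window_is_zero(self):
        assert fluctuation_measure([0.4] * 7, UNIT) == 0.0

    def test_full_range_alternation_is_one(self):
        assert np.isclose(fluctuation_measure([0, 1, 0, 1, 0, 1, 0], UNIT), 1.0)

    def test_monotone_ramp(self):
        # one run over 6 steps: (1/6) / (1*6) = 1/36
        assert np.isclose(fluctuation_measure(np.linspace(0, 1, 7), UNIT), 1 / 36)

    def test_out_of_range_values_clipped(self):
        a = fluctuation_measure([-5, 9, -5, 9, -5, 9, -5], UNIT)
        assert np.isclose(a, 1.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            fluctuation_measure([0.5], UNIT)


class TestDistribution:
    def test_uniform_grid_is_one(self):
        assert np.isclose(distribution_measure(np.linspace(0, 1, 7), UNIT), 1.0)

    def test_degenerate_at_low_end_is_zero(self):
        assert np.isclose(distribution_measure([0.0] * 7, UNIT), 0.0)

    def test_midpoint_cluster_value(self):
        # sorted deviations from the grid {0,1/6,..,1} sum to 2.0;
        # 1 - 2.0 / (7*0.5) = 3/7
        assert np.isclose(distribution_measure([0.5] * 7, UNIT), 3 / 7)

    def test_order_invariance(self, rng):
        w = rng.uniform(0, 1, 7)
        shuffled = rng.permutation(w)
        assert np.isclose(distribution_measure(w, UNIT),
                          distribution_measure(shuffled, UNIT))


class TestDynamicComplexity:
    def test_constant_series_all_zero(self):
        dc = dynamic_complexity(TimeSeries(np.full(30, 2.0)))
        np.testing.assert_allclose(dc.values, 0.0)
        assert dc.offset == 7

    def test_noise_exceeds_slow_ramp(self, rng):
        """I.i.d. noise over the full range is far more complex than a
        drift of the same range."""
        noise = dynamic_complexity(TimeSeries(rng.uniform(0, 1, 200)),
                                   DcConfig(range=UNIT))
        ramp = dynamic_complexity(TimeSeries(np.linspace(0, 1, 200)),
                                  DcConfig(range=UNIT))
        assert noise.values.mean() > 10 * ramp.values.mean()

    def test_bounds_on_random_windows(self, rng):
        for _ in range(1000):
            w = rng.uniform(-3, 3, 7)
            r = ScaleRange(-3, 3)
            f, d = fluctuation_measure(w, r), distribution_measure(w, r)
            assert 0.0 <= f <= 1.0 and 0.0 <= d <= 1.0

    def test_affine_invariance(self, rng):
        """Rescaling series and range together leaves DC unchanged."""
        x = rng.uniform(0, 1, 60)
        a, b = 4.2, -1.7
        dc1 = dynamic_complexity(TimeSeries(x), DcConfig(range=UNIT))
        dc2 = dynamic_complexity(TimeSeries(a * x + b),
                                 DcConfig(range=ScaleRange(b, a + b)))
        np.testing.assert_allclose(dc1.values, dc2.values, atol=1e-10)


class TestPermutationEntropy:
    def test_ordinal_pattern_ranks_and_ties(self):
        assert ordinal_pattern([1, 3, 2]) == (0, 2, 1)
        assert ordinal_pattern([3, 2, 5]) == (1, 0, 2)
        # earlier index takes the lower rank among ties
        assert ordinal_pattern([2, 2, 1]) == (1, 2, 0)

    def test_monotone_window_zero_entropy(self):
        pe = permutation_entropy(TimeSeries(np.arange(7.0)))
        assert np.isclose(pe.values[0], 0.0)

    def test_hand_enumerated_window(self):
        # words of {1,3,2,5,4,7,6}: 3x (0,2,1) and 2x (1,0,2)
        pe = permutation_entropy(TimeSeries([1, 3, 2, 5, 4, 7, 6]))
        expected = -(0.6 * math.log(0.6) + 0.4 * math.log(0.4)) / math.log(6)
        assert np.isclose(pe.values[0], expected, atol=1e-6)
        assert np.isclose(pe.values[0], 0.3756, atol=5e-4)

    def test_maximal_entropy_window(self):
        """A width-8 window whose 6 words realize all 6 patterns has H=1
        (width 7 offers only 5 words, so the maximum is unreachable there)."""
        for perm in itertools.permutations(range(8)):
            pats = {ordinal_pattern(perm[i:i + 3]) for i in range(6)}
            if len(pats) == 6:
                pe = permutation_entropy(TimeSeries(np.array(perm, float)),
                                         PeConfig(window=8, order=3))
                assert np.isclose(pe.values[0], 1.0)
                return
        pytest.fail("no permutation of 8 values realizes all 6 patterns")

    def test_bounds_and_offset(self, rng):
        s = TimeSeries(rng.standard_normal(100))
        pe = permutation_entropy(s)
        assert np.all(pe.values >= 0.0) and np.all(pe.values <= 1.0)
        assert pe.offset == 7 and len(pe) == 94

    @given(st.lists(st.integers(-500, 500), min_size=20, max_size=60,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, xs):
        # integer grid keeps values distinct after the monotone transform
        # (arbitrary floats can collide in exp and silently create ties)
        x = np.asarray(xs, dtype=float) / 50.0
        a = permutation_entropy(TimeSeries(x)).values
        b = permutation_entropy(TimeSeries(np.exp(x / 10.0))).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_window_must_exceed_order(self):
        with pytest.raises(ValueError):
            PeConfig(window=3, order=3)
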