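import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from otfti import Decision, GradientSeries, assess, histogram_pair, js_distance, protocol_preset, split_halves
from otfti.convergence import decide

from conftest import make_series


def probs(draw_floats):
    x = np.asarray(draw_floats, dtype=float)
    return x / x.sum()


prob_vectors = st.lists(st.floats(1e-6, 1.0), min_size=7, max_size=7).map(probs)


class TestSplitHalves:
    def test_even_split(self):
        a, b = split_halves([1, 2, 3, 4])
        assert list(a) == [1, 2] and list(b) == [3, 4]

    def test_odd_second_half_gets_extra(self):
        a, b = split_halves([1, 2, 3, 4, 5])
        assert list(a) == [1, 2] and list(b) == [3, 4, 5]

    @pytest.mark.parametrize("values", [[], [1.0]])
    def test_too_short(self, values):
        with pytest.raises(ValueError):
            split_halves(values)


class TestHistogramPair:
    def test_identical_halves_give_equal_probs(self, rng):
        x = rng.normal(size=200)
        _, p, q, degenerate = histogram_pair(x, x, 7)
        assert np.allclose(p, q)
        assert not degenerate
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_point_masses_at_extremes(self):
        _, p, q, _ = histogram_pair(np.zeros(100), np.ones(100), 7)
        assert p[0] == 1.0 and np.all(p[1:] == 0)
        assert q[6] == 1.0 and np.all(q[:6] == 0)

    def test_uniform_grid_two_bins(self):
        grid = np.linspace(0.0, 1.0, 101)
        first = grid[grid < 0.5]
        second = grid[grid >= 0.5]
        _, p, q, _ = histogram_pair(first, second, 2)
        assert np.allclose(p, [1.0, 0.0])
        assert np.allclose(q, [0.0, 1.0])

    def test_rightmost_bin_closed(self):
        # the pooled maximum must land in the last bin, not fall off
        _, p, _, _ = histogram_pair(np.array([0.0, 1.0]), np.array([0.5]), 4)
        assert p[-1] == 0.5

    def test_zero_width_range_flagged(self):
        _, p, q, degenerate = histogram_pair(np.full(10, 2.0), np.full(5, 2.0), 7)
        assert degenerate
        assert np.array_equal(p, q)
        assert p.sum() == 1.0


class TestJsDistance:
    def test_identical_distributions(self):
        p = np.full(7, 1 / 7)
        assert js_distance(p, p) == 0.0

    def test_disjoint_supports_max_out(self):
        assert js_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_value(self):
        # JSD = (0.20752 + 0.41504)/2 bits; distance is its square root
        assert js_distance([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.55792, abs=1e-5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=prob_vectors, q=prob_vectors)
    def test_matches_scipy_oracle_and_symmetry(self, p, q):
        d = js_distance(p, q)
        assert d == pytest.approx(jensenshannon(p, q, base=2), abs=1e-12)
        assert d == pytest.approx(js_distance(q, p), abs=1e-12)
        assert 0.0 <= d <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=prob_vectors, q=prob_vectors, r=prob_vectors)
    def test_triangle_inequality(self, p, q, r):
        assert js_distance(p, r) <= js_distance(p, q) + js_distance(q, r) + 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            js_distance([0.5, 0.6], [0.5, 0.5])
        with pytest.raises(ValueError):
            js_distance([1.5, -0.5], [0.5, 0.5])

    def test_expected_js_shrinks_with_sample_size(self):
        """For one stationary distribution, the two-half JS distance
        decreases in median as the sample grows."""
        sizes = (100, 1000, 10_000)
        medians = []
        for n in sizes:
            ds = []
            for seed in range(20):
                x = np.random.default_rng(seed).standard_normal(n)
                a, b = split_halves(x)
                _, p, q, _ = histogram_pair(a, b, 7)
                ds.append(js_distance(p, q))
            medians.append(np.median(ds))
        assert medians[0] > medians[1] > medians[2]


class TestDecision:
    @pytest.mark.parametrize("js_low", [True, False])
    @pytest.mark.parametrize("enough", [True, False])
    @pytest.mark.parametrize("time_band", ["early", "soft", "hard"])
    def test_truth_table(self, js_low, enough, time_band):
        cfg = protocol_preset("A")
        js = 0.05 if js_low else 0.5
        n_dec = 200 if enough else 10
        total = {"early": 3.0, "soft": 6.5, "hard": 10.5}[time_band]
        got = decide(js, n_dec, total, cfg)
        if js_low and enough:
            expected = Decision.CONVERGED
        elif total >= 6.5 and n_dec > 50:
            expected = Decision.SOFT_CAP_STOP
        elif total >= 10.5:
            expected = Decision.HARD_CAP_STOP
        else:
            expected = Decision.EXTEND
        assert got is expected

    def test_tie_at_threshold_converges(self):
        cfg = protocol_preset("A")
        assert decide(0.1, 50, 3.0, cfg) is Decision.CONVERGED

    def test_exactly_min_samples_at_soft_cap_does_not_stop(self):
        # soft cap needs strictly more than the minimum sample count
        cfg = protocol_preset("A")
        assert decide(0.5, 50, 6.5, cfg) is Decision.EXTEND

    def test_few_samples_at_hard_cap_still_stops(self):
        cfg = protocol_preset("A")
        assert decide(0.5, 5, 10.5, cfg) is Decision.HARD_CAP_STOP
        assert decide(math.nan, 0, 10.5, cfg) is Decision.HARD_CAP_STOP

    def test_under_min_samples_extends_despite_low_js(self):
        cfg = protocol_preset("A")
        assert decide(0.05, 49, 3.0, cfg) is Decision.EXTEND


class TestAssess:
    def test_stationary_series_converges_first_check(self, rng):
        s = GradientSeries(0.2, 0.001, rng.normal(5.0, 1.0, 2500))
        report = assess(s, protocol_preset("A"), total_time=2.5)
        assert report.decision is Decision.CONVERGED
        assert report.js_distance < 0.1
        assert report.n_decorrelated >= 50

    def test_degenerate_decorrelation_reports_nan_js(self):
        # strong linear drift: nearly all samples correlated, few survive
        vals = np.linspace(0.0, 100.0, 40)
        s = make_series(vals)
        report = assess(s, protocol_preset("A"), total_time=3.0)
        if report.n_decorrelated < 2:
            assert math.isnan(report.js_distance)
            assert report.decision is Decision.EXTEND

    def test_report_serializes_nan_as_none(self):
        vals = np.linspace(0.0, 100.0, 40)
        report = assess(make_series(vals), protocol_preset("A"), total_time=3.0)
        d = report.to_dict()
        assert d["js_distance"] is None or isinstance(d["js_distance"], float)
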