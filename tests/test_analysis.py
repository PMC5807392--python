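"""Response detection, Faithfulness, areas, return maps and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mauthner.analysis import (
    ResponseSeries,
    classify_pattern,
    count_upward_crossings,
    detect_responses,
    faithfulness,
    response_areas,
    return_map,
    slow_projection,
)
from mauthner.stimulus import PulseTrain


class FakeTrace:
    """Minimal stand-in trace (synthetic, for detector unit tests)."""

    def __init__(self, t, v):
        self.t = np.asarray(t, dtype=np.float64)
        self.v1 = np.asarray(v, dtype=np.float64)


def make_series(times, fired):
    times = np.asarray(times, dtype=np.float64)
    fired = np.asarray(fired, dtype=bool)
    lat = np.where(fired, 5.0, np.nan)
    return ResponseSeries(stimulus_times=times, fired=fired, latencies=lat)


class TestDetectResponses:
    def test_flat_subthreshold_trace_detects_nothing(self):
        train = PulseTrain(onset=100.0, frequency=10.0, count=5, width=2.0)
        t = np.arange(0.0, 700.0, 0.5)
        trace = FakeTrace(t, np.full(t.size, -34.0))
        series = detect_responses(trace, train)
        assert not series.fired.any()
        assert np.isnan(series.latencies).all()

    def test_injected_spike_located_with_latency(self):
        # one synthetic spike 7 ms after pulse 3 -> fired only there
        train = PulseTrain(onset=100.0, frequency=10.0, count=5, width=2.0)
        t = np.arange(0.0, 700.0, 0.5)
        v = np.full(t.size, -34.0)
        spike_t = train.times()[3] + 7.0
        v[(t >= spike_t) & (t < spike_t + 2.0)] = 20.0
        series = detect_responses(FakeTrace(t, v), train)
        np.testing.assert_array_equal(series.fired, [0, 0, 0, 1, 0])
        assert series.latencies[3] == pytest.approx(7.0, abs=0.5)

    def test_coarse_sampling_rejected(self):
        train = PulseTrain(onset=100.0, frequency=1.0, count=2, width=2.0)
        t = np.arange(0.0, 3000.0, 5.0)
        with pytest.raises(ValueError, match="sampling too coarse"):
            detect_responses(FakeTrace(t, np.full(t.size, -34.0)), train)

    def test_trace_must_cover_train(self):
        train = PulseTrain(onset=100.0, frequency=1.0, count=5, width=2.0)
        t = np.arange(0.0, 2000.0, 0.5)
        with pytest.raises(ValueError, match="cover"):
            detect_responses(FakeTrace(t, np.zeros(t.size)), train)


class TestFaithfulness:
    def test_extremes(self):
        s_all = make_series(np.arange(10) * 1000.0, np.ones(10))
        s_none = make_series(np.arange(10) * 1000.0, np.zeros(10))
        assert faithfulness(s_all, 0.0, 10000.0) == 1.0
        assert faithfulness(s_none, 0.0, 10000.0) == 0.0

    def test_fractional_count(self):
        fired = [1, 1, 1, 0, 1, 0, 1, 0, 1, 0]
        s = make_series(np.arange(10) * 1000.0, fired)
        assert faithfulness(s, 0.0, 10000.0) == pytest.approx(0.6)

    def test_published_window_stimulus_counts(self):
        # 1 Hz from 20 s: the 20-30 s window holds 10 stimuli, 40-70 s holds 30
        times = 20000.0 + np.arange(60) * 1000.0
        s = make_series(times, np.ones(60))
        for w0, w1, n in ((20000.0, 30000.0, 10), (40000.0, 70000.0, 30)):
            mask = (s.stimulus_times >= w0) & (s.stimulus_times < w1)
            assert int(mask.sum()) == n

    def test_empty_window_raises(self):
        s = make_series([1000.0], [1])
        with pytest.raises(ValueError):
            faithfulness(s, 5000.0, 6000.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    def test_matches_brute_force_recount(self, flags):
        # independent oracle: recount the flags one by one
        times = np.arange(len(flags)) * 1000.0
        s = make_series(times, flags)
        value = faithfulness(s, 0.0, len(flags) * 1000.0)
        brute = sum(1 for f in flags if f) / len(flags)
        assert value == pytest.approx(brute)
        assert 0.0 <= value <= 1.0


class TestResponseAreas:
    def test_all_subthreshold_gives_zero(self):
        train = PulseTrain(onset=0.0, frequency=10.0, count=3, width=2.0)
        t = np.arange(0.0, 400.0, 0.5)
        trace = FakeTrace(t, np.full(t.size, -50.0))
        areas = response_areas(trace, train, area_threshold=-30.0)
        np.testing.assert_array_equal(areas, 0.0)

    def test_rectangular_excursion_closed_form(self):
        # height h above threshold lasting d ms -> area h * d
        train = PulseTrain(onset=0.0, frequency=1.0, count=1, width=2.0)
        t = np.arange(0.0, 1000.0, 0.1)
        v = np.full(t.size, -40.0)
        h, d = 15.0, 50.0
        v[(t >= 100.0) & (t < 100.0 + d)] = -30.0 + h
        areas = response_areas(FakeTrace(t, v), train, area_threshold=-30.0)
        assert areas[0] == pytest.approx(h * d, rel=0.01)


class TestReturnMap:
    def test_constant_areas_sit_on_identity_line(self):
        times = np.arange(30) * 1000.0
        pairs = return_map(np.full(30, 7.0), times, 0.0, 30000.0)
        assert pairs.shape == (29, 2)
        np.testing.assert_allclose(pairs[:, 0], pairs[:, 1])

    def test_period_two_sequence_forms_two_clusters(self):
        times = np.arange(40) * 1000.0
        areas = np.tile([2.0, 5.0], 20)
        pairs = return_map(areas, times, 0.0, 40000.0)
        offdiag = set(map(tuple, np.round(pairs, 9)))
        assert offdiag == {(2.0, 5.0), (5.0, 2.0)}

    def test_window_restriction_and_log(self):
        times = np.arange(10) * 1000.0
        areas = np.arange(10, dtype=float) + 1.0
        pairs = return_map(areas, times, 2000.0, 7000.0, log=True)
        assert pairs.shape == (4, 2)
        np.testing.assert_allclose(10 ** pairs[0], [3.0, 4.0])

    def test_log_with_zero_area_raises(self):
        times = np.arange(5) * 1000.0
        with pytest.raises(ValueError, match="area"):
            return_map(np.array([1.0, 0.0, 1.0, 1.0, 1.0]), times, 0.0, 5000.0, log=True)


class TestClassifyPattern:
    def make(self, fired, areas=None):
        n = len(fired)
        times = np.arange(n) * 1000.0
        series = make_series(times, fired)
        if areas is None:
            areas = np.where(series.fired, 500.0, 1.0)
        return series, np.asarray(areas, dtype=float), 0.0, n * 1000.0

    def test_silent_converged_is_subthreshold_fixed_point(self):
        series, areas, w0, w1 = self.make(np.zeros(30), np.full(30, 2.0))
        assert classify_pattern(series, areas, w0, w1) == "subthreshold_fixed_point"

    def test_full_response_is_suprathreshold_fixed_point(self):
        series, areas, w0, w1 = self.make(np.ones(30))
        assert classify_pattern(series, areas, w0, w1) == "suprathreshold_fixed_point"

    def test_alternating_sequence_classified_by_firing_fraction(self):
        series, areas, w0, w1 = self.make(np.tile([1, 0], 15))
        assert classify_pattern(series, areas, w0, w1) == "subthreshold_periodic"
        series, areas, w0, w1 = self.make(np.tile([1, 1, 0], 10))
        assert classify_pattern(series, areas, w0, w1) == "suprathreshold_periodic"

    def test_aperiodic_sequence_is_irregular(self):
        rng = np.random.default_rng(0)
        fired = rng.random(60) < 0.4
        fired[0] = True
        fired[1] = False
        series, areas, w0, w1 = self.make(fired)
        assert classify_pattern(series, areas, w0, w1) == "irregular"

    def test_short_window_rejected(self):
        series, areas, w0, w1 = self.make(np.ones(10))
        with pytest.raises(ValueError, match="20"):
            classify_pattern(series, areas, w0, w1)


class TestSlowProjection:
    def test_constant_when_unstimulated(self, dominant_params, dominant_qss):
        from mauthner.simulate import integrate

        # zero-amplitude pulses: onset states exist but nothing perturbs them
        train = PulseTrain(onset=100.0, frequency=10.0, count=5, width=2.0,
                          amplitude=0.0)
        trace = integrate(dominant_qss, dominant_params, train, t_end=700.0,
                          sample_interval=0.1)
        series = detect_responses(trace, train)
        proj = slow_projection(trace, train, series)
        assert len(proj) == 5
        assert proj["fired"].sum() == 0
        # residual slow drift of the finite 20 s relaxation is tiny
        assert proj["Ca"].std() < 1e-4
        assert proj["E_net"].std() < 1e-3


class TestCrossingCounter:
    def test_counts_upward_crossings_only(self):
        v = np.array([-1.0, 1.0, -1.0, 1.0, 2.0, -1.0])
        assert count_upward_crossings(v, 0.0) == 2
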