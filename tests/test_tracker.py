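import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathradar import synth, tracker
from breathradar.errors import ConfigError, EmptyTraceError

from conftest import analytic_extrema, make_spec


def flat_trace(duration=60.0, dt=0.05, level=1000.0):
    n = int(round(duration / dt)) + 1
    return synth.RadarTrace(0.0, dt, np.full(n, level))


class TestPreprocess:
    def test_flat_unchanged(self):
        trace = flat_trace()
        out = tracker.preprocess(trace)
        np.testing.assert_allclose(out.samples, trace.samples, atol=1e-9)

    def test_denoising_correlation(self):
        spec = make_spec(noise_sd=0.5, seed=4)
        noisy, _ = synth.generate_radar_trace(spec)
        clean, _ = synth.generate_radar_trace(make_spec(noise_sd=0.0))
        out = tracker.preprocess(noisy)
        r = np.corrcoef(out.samples, clean.samples)[0, 1]
        assert r >= 0.99

    def test_near_idempotent(self):
        trace, _ = synth.generate_radar_trace(make_spec())
        once = tracker.preprocess(trace)
        twice = tracker.preprocess(once)
        rms = np.sqrt(np.mean((twice.samples - once.samples) ** 2))
        scale = np.sqrt(np.mean((once.samples - once.samples.mean()) ** 2))
        assert rms < 0.01 * scale

    def test_empty_rejected(self):
        with pytest.raises(EmptyTraceError):
            tracker.preprocess(synth.RadarTrace(0.0, 0.05, np.empty(0)))


class TestSegmentBreaths:
    def test_flat_trace_no_cycles_no_motion(self):
        res = tracker.segment_breaths(flat_trace())
        assert res.cycles == ()
        assert res.motion_events == ()

    @pytest.mark.parametrize("period", [3.0, 4.0, 5.0, 7.5, 10.0])
    def test_oracle_equivalence_noiseless(self, period):
        rate = 60.0 / period
        duration = 5 * period + period / 2  # ends mid-cycle
        spec = make_spec(duration=duration, rate=rate)
        trace, _ = synth.generate_radar_trace(spec)
        res = tracker.segment_breaths(trace)
        maxima, minima = analytic_extrema(rate, duration)
        dt = trace.sample_interval
        assert len(res.cycles) == len(maxima) - 1
        for k, c in enumerate(res.cycles):
            assert c.start_time == pytest.approx(maxima[k], abs=dt)
            assert c.end_time == pytest.approx(maxima[k + 1], abs=dt)
            assert c.inhale_peak_time == pytest.approx(minima[k], abs=dt)
            assert c.period == pytest.approx(period, abs=2 * dt)

    def test_subthreshold_amplitude_yields_no_cycles(self):
        spec = make_spec(amplitude=0.3)
        trace, _ = synth.generate_radar_trace(spec)
        res = tracker.segment_breaths(trace)
        assert res.cycles == ()

    def test_motion_event_covers_step(self):
        spec = synth.ScenarioSpec(
            segments=(
                synth.BreathingSegment(30.0, "breathing", 15.0, 5.0),
                synth.BreathingSegment(3.0, "motion_transient", shift=100.0),
                synth.BreathingSegment(30.0, "breathing", 15.0, 5.0),
            ),
            noise_sd=0.25,
            seed=5,
        )
        trace, truth = synth.generate_radar_trace(spec)
        res = tracker.track(trace)
        assert len(res.motion_events) == 1
        ev = res.motion_events[0]
        (ms, me), = truth.motion_intervals
        # the event lies within the programmed transient (gate crossing is
        # necessarily a little after the step begins)
        assert ms <= ev.start_time <= me
        assert ev.end_time <= me + 0.5
        assert ev.magnitude > 20.0
        for c in res.cycles:
            assert c.end_time <= ev.start_time or c.start_time >= ev.end_time

    def test_no_cycle_overlaps_motion_invariant(self):
        spec = synth.preset_scenario("overdose_simulation", seed=2)
        trace, _ = synth.generate_radar_trace(spec)
        res = tracker.track(trace)
        assert len(res.motion_events) >= 1
        for c in res.cycles:
            for ev in res.motion_events:
                assert c.end_time <= ev.start_time or c.start_time >= ev.end_time
        # cycles are time-ordered and non-overlapping
        for a, b in zip(res.cycles, res.cycles[1:]):
            assert b.start_time >= a.end_time - 1e-9

    def test_excursion_within_gates(self):
        spec = make_spec(noise_sd=0.25, jitter_cv=0.05, seed=3)
        trace, _ = synth.generate_radar_trace(spec)
        res = tracker.track(trace)
        cfg = tracker.TrackerConfig()
        for c in res.cycles:
            assert cfg.min_excursion <= c.excursion <= cfg.max_excursion

    def test_empty_trace_rejected(self):
        with pytest.raises(EmptyTraceError):
            tracker.segment_breaths(synth.RadarTrace(0.0, 0.05, np.empty(0)))

    def test_sample_interval_mismatch_rejected(self):
        trace = flat_trace(dt=0.05)
        cfg = tracker.TrackerConfig(sample_interval=0.1)
        with pytest.raises(ConfigError):
            tracker.segment_breaths(trace, cfg)

    @given(amp=st.floats(min_value=0.05, max_value=0.7))
    @settings(max_examples=10, deadline=None)
    def test_gating_property_small_amplitudes(self, amp):
        spec = make_spec(duration=30.0, amplitude=amp)
        trace, _ = synth.generate_radar_trace(spec)
        assert tracker.segment_breaths(trace).cycles == ()

    def test_gating_property_large_excursion_triggers_motion(self):
        trace = flat_trace(duration=30.0)
        y = trace.samples.copy()
        t = trace.times
        y[(t > 14.0) & (t < 16.0)] += 50.0  # 50 mm excursion > 20 mm gate
        jumped = synth.RadarTrace(0.0, trace.sample_interval, y)
        res = tracker.segment_breaths(jumped)
        assert len(res.motion_events) >= 1


class TestEstimateRate:
    def _cycle(self, start, period):
        return tracker.BreathCycle(start, start + period, start + period / 2, 5.0)

    def test_rate_from_last_cycle(self):
        est = tracker.estimate_rate([self._cycle(0.0, 4.0)], at_time=10.0)
        assert est.valid
        assert est.rate == pytest.approx(15.0)

    def test_threshold_boundary_rate(self):
        est = tracker.estimate_rate([self._cycle(0.0, 7.5)], at_time=8.0)
        assert est.rate == pytest.approx(8.0)

    def test_no_cycles_invalid(self):
        est = tracker.estimate_rate([], at_time=5.0)
        assert not est.valid

    def test_staleness_horizon(self):
        cycles = [self._cycle(0.0, 4.0)]
        assert tracker.estimate_rate(cycles, at_time=18.0).valid
        assert not tracker.estimate_rate(cycles, at_time=30.0).valid

    def test_uses_most_recent_cycle(self):
        cycles = [self._cycle(0.0, 4.0), self._cycle(4.0, 5.0)]
        est = tracker.estimate_rate(cycles, at_time=10.0)
        assert est.rate == pytest.approx(12.0)


class TestTrack:
    def test_position_tuning_rate_band(self):
        spec = synth.preset_scenario("position_tuning", seed=0)
        spec = synth.ScenarioSpec(**{**spec.__dict__, "noise_sd": 0.0})
        trace, _ = synth.generate_radar_trace(spec)
        res = tracker.track(trace)
        rates = [e.rate for e in res.rate_series if e.valid]
        assert rates
        assert all(14.5 <= r <= 15.5 for r in rates)

    def test_cessation_no_cycles_after_apnea(self):
        spec = synth.preset_scenario("cessation", seed=1)
        trace, truth = synth.generate_radar_trace(spec)
        res = tracker.track(trace)
        apnea_start = truth.hold_intervals[0][0]
        assert all(c.end_time <= apnea_start + 1.0 for c in res.cycles)

    def test_overdose_simulation_cycle_recall(self):
        spec = synth.preset_scenario("overdose_simulation", seed=4)
        trace, truth = synth.generate_radar_trace(spec)
        res = tracker.track(trace)
        ends = np.array([c.end_time for c in res.cycles])
        bounds = truth.cycle_boundaries
        matched = 0
        total = 0
        for s, e in zip(bounds, bounds[1:]):
            # skip boundaries adjacent to motion transients
            if any(
                ms - 1.0 <= s <= me + 3.0 or ms - 1.0 <= e <= me + 3.0
                for ms, me in truth.motion_intervals
            ):
                continue
            total += 1
            if ends.size and np.min(np.abs(ends - e)) <= 0.5:
                matched += 1
        assert total >= 15
        assert matched / total >= 0.9

    def test_rate_recovery_median(self):
        for rate in (6.0, 10.0, 20.0):
            spec = make_spec(duration=60.0, rate=rate, noise_sd=0.25,
                             jitter_cv=0.02, seed=int(rate))
            trace, _ = synth.generate_radar_trace(spec)
            res = tracker.track(trace)
            rates = [e.rate for e in res.rate_series if e.valid]
            assert abs(np.median(rates) - rate) <= 0.5

    def test_determinism(self):
        spec = make_spec(noise_sd=0.25, seed=8)
        trace, _ = synth.generate_radar_trace(spec)
        a = tracker.track(trace)
        b = tracker.track(trace)
        assert a.cycles == b.cycles
        ra = np.array([e.rate for e in a.rate_series])
        rb = np.array([e.rate for e in b.rate_series])
        np.testing.assert_array_equal(np.nan_to_num(ra), np.nan_to_num(rb))
        assert [e.valid for e in a.rate_series] == [e.valid for e in b.rate_series]
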