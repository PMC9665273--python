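"""Peak/trough detection, phase construction, and quality triage."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from physiofc import (EventSeries, PhysioRecording, SimParams,
                      cardiac_phase, corrupt_physio, detect_extrema,
                      generate_physio, physio_quality, respiratory_phase)
from physiofc.physio import (InsufficientEventsError, NoEventsError,
                             SequencingError)


def _sine_recording(freq=1.0, dur=60.0, rate=50.0, channel="cardiac"):
    t = np.arange(0, dur, 1.0 / rate)
    return PhysioRecording(channel=channel, rate=rate, t0=0.0,
                           samples=np.sin(2 * np.pi * freq * t))


class TestDetectExtrema:
    def test_pure_sinusoid_peaks_at_analytic_maxima(self):
        """A 1 Hz sinusoid over 60 s has maxima at 0.25 + k seconds."""
        rec = _sine_recording()
        peaks = detect_extrema(rec, min_interval=0.4)
        expected = 0.25 + np.arange(60)
        # edge cycles may fall outside the prominence window
        assert 58 <= len(peaks) <= 60
        for t in peaks.times:
            assert np.min(np.abs(expected - t)) <= 1.0 / rec.rate + 1e-9

    def test_constant_trace_raises_no_events(self):
        rec = PhysioRecording("cardiac", 50.0, 0.0, np.ones(500))
        with pytest.raises(NoEventsError):
            detect_extrema(rec)

    def test_missing_recording_raises_with_quality(self):
        rec = PhysioRecording("cardiac", 50.0, 0.0, np.array([]),
                              present=False, quality="missing")
        with pytest.raises(NoEventsError) as exc:
            detect_extrema(rec)
        assert exc.value.quality == "missing"

    def test_recovers_generator_cycle_times(self):
        """Detected cardiac peaks land within 2 samples of the generator's
        drawn pulse peaks."""
        cardiac, _ = generate_physio(SimParams(seed=1))
        peaks = detect_extrema(cardiac)
        truth = cardiac.true_event_times
        tol = 2.0 / cardiac.rate
        # match each detected peak to the nearest true peak
        matched = 0
        for t in peaks.times:
            if np.min(np.abs(truth - t)) <= tol:
                matched += 1
        assert matched / len(peaks) > 0.99

    def test_respiratory_troughs_interleave_with_peaks(self):
        _, resp = generate_physio(SimParams(seed=1))
        pk = detect_extrema(resp)
        tr = detect_extrema(resp, troughs=True)
        merged = np.sort(np.concatenate([pk.times, tr.times]))
        kinds = np.concatenate([np.ones(len(pk)), np.zeros(len(tr))])
        kinds = kinds[np.argsort(np.concatenate([pk.times, tr.times]))]
        assert np.all(np.diff(kinds) != 0)


class TestCardiacPhase:
    def test_reset_midpoint_and_quarter(self):
        """Phase is 0 at peaks, pi at interval midpoints, pi/2 a quarter in."""
        peaks = EventSeries("peak", np.arange(0.0, 10.0))
        ph = cardiac_phase(peaks, np.array([3.0, 3.5, 0.25]))
        assert np.allclose(ph.phase, [0.0, np.pi, np.pi / 2])

    def test_range_and_piecewise_linearity(self):
        peaks = EventSeries("peak", np.cumsum(np.r_[0.0, 0.8 + 0.2 *
                                                    np.random.default_rng(0)
                                                    .random(50)]))
        t = np.linspace(peaks.times[0], peaks.times[-1], 500)
        ph = cardiac_phase(peaks, t)
        assert np.all(ph.phase >= 0) and np.all(ph.phase < 2 * np.pi)
        # second differences vanish inside one R-R interval
        seg = np.linspace(peaks.times[3] + 1e-6, peaks.times[4] - 1e-6, 20)
        p = cardiac_phase(peaks, seg).phase
        assert np.allclose(np.diff(p, 2), 0.0, atol=1e-9)

    def test_extrapolation_beyond_span_is_flagged(self):
        peaks = EventSeries("peak", np.array([1.0, 2.0, 3.0]))
        ph = cardiac_phase(peaks, np.array([0.5, 1.5, 3.5]))
        assert ph.extrapolated.tolist() == [True, False, True]
        assert np.isclose(ph.phase[0], np.pi)  # half a cycle before t=1

    def test_single_peak_raises(self):
        with pytest.raises(InsufficientEventsError):
            cardiac_phase(EventSeries("peak", np.array([1.0])),
                          np.array([1.0]))


class TestRespiratoryPhase:
    def setup_method(self):
        self.troughs = EventSeries("trough", np.array([0.0, 4.0, 8.0]))
        self.peaks = EventSeries("peak", np.array([2.0, 6.0]))

    def test_trough_is_zero_midpoints_are_half_pi(self):
        ph = respiratory_phase(self.peaks, self.troughs,
                               np.array([4.0, 1.0, 3.0]))
        assert np.allclose(ph.phase, [0.0, np.pi / 2, -np.pi / 2])

    def test_peak_value_is_circular_boundary(self):
        """At the breath peak the phase sits at the +/-pi boundary, keeping
        cos/sin regressors continuous."""
        ph = respiratory_phase(self.peaks, self.troughs, np.array([2.0]))
        assert np.isclose(np.abs(ph.phase[0]), np.pi)
        eps = 1e-6
        before = respiratory_phase(self.peaks, self.troughs,
                                   np.array([2.0 - eps])).phase[0]
        after = respiratory_phase(self.peaks, self.troughs,
                                  np.array([2.0 + eps])).phase[0]
        assert np.isclose(np.cos(before), np.cos(after), atol=1e-5)
        assert np.isclose(np.sin(before), np.sin(after), atol=1e-5)

    def test_range_invariant(self):
        t = np.linspace(0, 8, 200)
        ph = respiratory_phase(self.peaks, self.troughs, t)
        assert np.all(ph.phase >= -np.pi) and np.all(ph.phase <= np.pi)

    def test_non_interleaved_events_raise(self):
        with pytest.raises(SequencingError):
            respiratory_phase(EventSeries("peak", np.array([1.0, 2.0])),
                              EventSeries("trough", np.array([3.0])),
                              np.array([1.5]))


class TestPhysioQuality:
    def test_absent_channel_is_missing(self):
        rec = PhysioRecording("cardiac", 50.0, 0.0, np.array([]),
                              present=False, quality="missing")
        assert physio_quality(rec) == "missing"

    def test_clean_generated_traces_classify_clean(self):
        cardiac, resp = generate_physio(SimParams(seed=1))
        assert physio_quality(cardiac) == "clean"
        assert physio_quality(resp) == "clean"

    @pytest.mark.parametrize("mode,expected", [
        ("dropout", "dropout"),
        ("motion_noise", "noisy"),
        ("position_noise", "noisy"),
    ])
    def test_corrupted_traces_classify_as_corrupted(self, mode, expected):
        cardiac, _ = generate_physio(SimParams(seed=2))
        bad = corrupt_physio(cardiac, mode, rng=np.random.default_rng(3))
        assert physio_quality(bad) == expected


@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_phase_range_invariants_hold_for_any_seed(seed):
    """Cardiac phase in [0, 2pi), respiratory in [-pi, pi], on generated
    event sequences."""
    rng = np.random.default_rng(seed)
    n = 8
    troughs = np.cumsum(rng.uniform(2.0, 5.0, n))
    peaks = troughs[:-1] + rng.uniform(0.3, 0.7, n - 1) * np.diff(troughs)
    t = np.linspace(troughs[0] - 2, troughs[-1] + 2, 101)
    phc = cardiac_phase(EventSeries("peak", peaks), t)
    assert np.all((phc.phase >= 0) & (phc.phase < 2 * np.pi))
    phr = respiratory_phase(EventSeries("peak", peaks),
                            EventSeries("trough", troughs), t)
    assert np.all((phr.phase >= -np.pi) & (phr.phase <= np.pi))
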