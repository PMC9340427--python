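import numpy as np
import pytest

from nirskinetics import (
    ButterworthSmoother,
    SessionProtocol,
    TSITrace,
    butterworth_lowpass,
    segment_session,
)


def _trace(values):
    values = np.asarray(values, dtype=float)
    return TSITrace(time=np.arange(values.size, dtype=float), tsi=values, sampling_rate=1.0)


def _sine_amplitude(x, freq, t):
    """Amplitude of the component at `freq` via sin/cos regression."""
    X = np.column_stack([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(X, x - x.mean(), rcond=None)
    return float(np.hypot(*coef))


class TestButterworth:
    def test_dc_passes_unchanged(self):
        out = butterworth_lowpass(_trace(np.full(300, 80.0)))
        np.testing.assert_allclose(out.tsi, 80.0, atol=1e-9)

    def test_output_length_equals_input(self):
        out = butterworth_lowpass(_trace(np.random.default_rng(0).normal(70, 1, 200)))
        assert len(out) == 200

    @pytest.mark.parametrize("freq, trim", [(0.1, 60), (0.4, 60)])
    def test_attenuation_matches_double_pass_magnitude(self, freq, trim):
        """Zero-phase = two passes: sinusoid amplitude shrinks by |H(f)|^2."""
        t = np.arange(1200, dtype=float)
        x = 70.0 + np.sin(2 * np.pi * freq * t)
        out = butterworth_lowpass(_trace(x), cutoff=0.1, order=2)
        sm = ButterworthSmoother(cutoff=0.1, order=2, sampling_rate=1.0).fit()
        expected = float(sm.gain(freq)[0])
        measured = _sine_amplitude(out.tsi[trim:-trim], freq, t[trim:-trim])
        assert measured == pytest.approx(expected, abs=0.01 * max(expected, 0.05))
        assert np.mean(out.tsi[trim:-trim]) == pytest.approx(70.0, abs=0.01)

    def test_half_power_at_cutoff(self):
        """At the design cutoff each pass is -3 dB, so the double pass halves."""
        t = np.arange(2000, dtype=float)
        x = 70.0 + np.sin(2 * np.pi * 0.1 * t)
        out = butterworth_lowpass(_trace(x), cutoff=0.1, order=2)
        measured = _sine_amplitude(out.tsi[100:-100], 0.1, t[100:-100])
        assert measured == pytest.approx(0.5, abs=0.005)

    def test_zero_phase_time_reversal_symmetry(self):
        # edge-padding transients are not reversal-symmetric; the property
        # holds once the filter transient (a few dozen samples) has decayed
        rng = np.random.default_rng(2)
        x = rng.normal(70, 2, 400)
        fwd = butterworth_lowpass(_trace(x)).tsi
        rev = butterworth_lowpass(_trace(x[::-1])).tsi[::-1]
        np.testing.assert_allclose(fwd[50:-50], rev[50:-50], atol=1e-9)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            butterworth_lowpass(_trace(np.full(8, 70.0)))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            butterworth_lowpass(_trace(np.full(100, 70.0)), cutoff=0.6)


class TestProtocol:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SessionProtocol(sprint_starts=[0.0, 200.0])

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SessionProtocol(sprint_starts=[270.0, 0.0])

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            SessionProtocol(sprint_starts=[0.0], condition="SEA-LEVEL")


class TestSegmentation:
    def test_five_sprint_protocol_layout(self, protocol):
        trace = _trace(np.random.default_rng(3).normal(70, 1, 1350))
        segments = segment_session(trace, protocol)
        kinds = [s.kind for s in segments]
        assert kinds.count("deoxy_window") == 5
        assert kinds.count("sprint") == 5
        assert kinds.count("recovery") == 5
        for s in segments:
            if s.kind == "deoxy_window":
                assert len(s) == 10
                np.testing.assert_allclose(s.time, np.arange(10.0))
            elif s.kind == "recovery":
                assert len(s) == 240
                assert s.time[0] == 0.0  # local time re-zeroed at recovery onset

    def test_deoxy_window_holds_first_ten_samples(self, protocol):
        values = np.arange(1350, dtype=float)
        segments = segment_session(_trace(values), protocol)
        win = [s for s in segments if s.kind == "deoxy_window" and s.sprint_index == 2][0]
        np.testing.assert_allclose(win.tsi, values[270:280])

    def test_recovery_slice_matches_global_indices(self, protocol):
        values = np.arange(1350, dtype=float)
        segments = segment_session(_trace(values), protocol)
        rec = [s for s in segments if s.kind == "recovery" and s.sprint_index == 1][0]
        np.testing.assert_allclose(rec.tsi, values[30:270])

    def test_filter_applied_globally_before_cutting(self, protocol):
        x = np.random.default_rng(4).normal(70, 2, 1350)
        filtered = butterworth_lowpass(_trace(x))
        segments = segment_session(filtered, protocol)
        rec = [s for s in segments if s.kind == "recovery" and s.sprint_index == 3][0]
        np.testing.assert_allclose(rec.tsi, filtered.tsi[570:810])

    def test_insufficient_coverage_reported(self, protocol):
        with pytest.raises(ValueError, match="sprint 5"):
            segment_session(_trace(np.full(1000, 70.0)), protocol)
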