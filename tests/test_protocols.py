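import numpy as np
import pytest

from cardiokit import StimulusProtocol, make_toy_cell, run
from cardiokit.engine import Trace
from cardiokit.protocols import (availability_curve, excitation_threshold,
                                 extract_ap_features, stabilize,
                                 strength_duration_curve,
                                 transmural_dispersion, _elicits_ap)


def _synthetic_trace(stim_times=(100.0,), ectopic_at=()):
    """A synthetic membrane-potential trace with rectangular-ish APs of known
    geometry: rest -80 mV, peak +20 mV, 2 ms linear upstroke, 200 ms plateau
    decay back to rest."""
    t = np.arange(0.0, 1000.0, 0.05)
    V = np.full_like(t, -80.0)
    for t0 in list(stim_times) + list(ectopic_at):
        up = (t >= t0) & (t < t0 + 2.0)
        V[up] = -80.0 + 100.0 * (t[up] - t0) / 2.0
        rep = (t >= t0 + 2.0) & (t < t0 + 202.0)
        V[rep] = 20.0 - 100.0 * (t[rep] - (t0 + 2.0)) / 200.0
    return Trace(t=t, V=V, currents={}, stim_times=np.asarray(stim_times),
                 final_state=np.zeros((1, 1)), dt=0.05)


class TestFeatureExtraction:
    def test_known_geometry(self):
        f = extract_ap_features(_synthetic_trace())
        assert f.upstroke_count == 1
        assert f.ectopic_count == 0
        assert f.resting_V == pytest.approx(-80.0)
        assert f.amplitude == pytest.approx(100.0, abs=1.0)
        # 90 % repolarization of the linear 200 ms ramp happens 180 ms after
        # its start; dV/dt_max sits in the middle of the 2 ms upstroke.
        assert f.apd90 == pytest.approx(181.0, abs=2.0)

    def test_ectopic_classification(self):
        f = extract_ap_features(_synthetic_trace(stim_times=(100.0,),
                                                 ectopic_at=(600.0,)))
        assert f.upstroke_count == 2
        assert f.stimulated_count == 1
        assert f.ectopic_count == 1

    def test_upstroke_within_latency_is_stimulated(self):
        tr = _synthetic_trace(stim_times=(100.0,))
        f = extract_ap_features(tr, stim_times=np.array([85.0]))
        assert f.stimulated_count == 1   # 15 ms latency <= 20 ms window
        f = extract_ap_features(tr, stim_times=np.array([70.0]))
        assert f.ectopic_count == 1      # 30 ms latency -> ectopic

    def test_quiescent_trace(self):
        t = np.arange(0.0, 100.0, 0.1)
        tr = Trace(t=t, V=np.full_like(t, -80.0), currents={},
                   stim_times=np.array([]), final_state=np.zeros((1, 1)),
                   dt=0.1)
        f = extract_ap_features(tr)
        assert f.upstroke_count == 0 and f.amplitude == 0.0

    def test_rejects_fiber_trace(self):
        t = np.arange(0.0, 10.0, 0.1)
        tr = Trace(t=t, V=np.zeros((t.size, 3)), currents={},
                   stim_times=np.array([]), final_state=np.zeros((3, 1)),
                   dt=0.1)
        with pytest.raises(ValueError):
            extract_ap_features(tr)


class TestAvailability:
    def test_bounded_normalized_and_monotone(self, atrial, vgrid):
        v, a = availability_curve(atrial, vgrid)
        assert a.max() == pytest.approx(1.0)
        assert np.all((a >= 0.0) & (a <= 1.0 + 1e-12))
        assert np.all(np.diff(a) <= 1e-3)          # decreasing with prepulse V

    def test_empty_grid_rejected(self, atrial):
        with pytest.raises(ValueError):
            availability_curve(atrial, [])

    def test_no_sodium_current_in_toy(self, toy):
        with pytest.raises(ValueError):
            availability_curve(toy, [-90.0])


class TestThresholds:
    def test_bisection_matches_fine_sweep(self, toy):
        s0 = stabilize(toy, 5.0, 2)
        th = excitation_threshold(toy, 1.0, 5.0, state0=s0, window_ms=30.0)
        amps = np.arange(0.5, 60.0, 0.25)
        sweep = next(a for a in amps
                     if _elicits_ap(toy, s0, a, 1.0, toy.dt, 30.0))
        assert abs(th - sweep) <= 0.25 + 0.01 * sweep

    def test_invalid_duration(self, toy):
        with pytest.raises(ValueError):
            excitation_threshold(toy, 0.0, 5.0)

    def test_cap_too_low(self, toy):
        s0 = stabilize(toy, 5.0, 2)
        with pytest.raises(RuntimeError, match="cap"):
            excitation_threshold(toy, 1.0, 5.0, state0=s0, amp_cap=1.0,
                                 window_ms=30.0)

    def test_sd_curve_non_increasing(self, toy):
        sd = strength_duration_curve(toy, [0.5, 1.0, 2.0, 4.0], 5.0,
                                     prepace_beats=2, window_ms=30.0)
        assert np.all(np.diff(sd.thresholds) <= 0.0)

    def test_sd_curve_rejects_bad_durations(self, toy):
        with pytest.raises(ValueError):
            strength_duration_curve(toy, [], 5.0)
        with pytest.raises(ValueError):
            strength_duration_curve(toy, [1.0, -2.0], 5.0)


class TestDispersion:
    def test_missing_trace_rejected(self):
        tr = _synthetic_trace()
        with pytest.raises(ValueError, match="missing"):
            transmural_dispersion(tr, None, tr)

    def test_identical_traces_have_zero_dispersion(self):
        tr = _synthetic_trace()
        assert transmural_dispersion(tr, tr, tr) == pytest.approx(0.0)

    def test_known_offset(self):
        a = _synthetic_trace(stim_times=(100.0,))
        b = _synthetic_trace(stim_times=(100.0,))
        # lengthen repolarization of b by shifting its plateau decay
        c = Trace(t=b.t, V=np.roll(b.V, 200), currents={},  # +10 ms shift
                  stim_times=b.stim_times, final_state=b.final_state, dt=b.dt)
        d = transmural_dispersion(a, c, a)
        assert d == pytest.approx(10.0, abs=1.0)
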