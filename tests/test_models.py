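import numpy as np
import pytest

from cardiokit import MODEL_NAMES, StimulusProtocol, build_model, make_toy_cell, run
from cardiokit.protocols import default_protocol, extract_ap_features, stabilize


class TestRegistry:
    def test_all_names_build(self):
        for name in MODEL_NAMES:
            m = build_model(name)
            assert m.name == name
            assert m.initial_state.shape == (m.n_state,)

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="atrial_MGTG"):
            build_model("nope")

    def test_toy_threshold_param_range(self):
        with pytest.raises(ValueError):
            make_toy_cell(threshold_param=0.1)
        with pytest.raises(ValueError):
            make_toy_cell(threshold_param=2.0)

    def test_oscillatory_toy_fires_unstimulated(self):
        tr = run(make_toy_cell(oscillatory=True), None, 200.0)
        assert tr.V.max() > 0.0

    def test_quiescent_toy_stays_at_rest(self):
        tr = run(make_toy_cell(), None, 200.0)
        assert tr.V.max() < -30.0


def _paced_features(model, n_beats=3):
    prot = default_protocol(model)
    period = prot.period
    tr = run(model, prot, n_beats * period, rec_interval=0.05)
    return extract_ap_features(tr)


class TestPhysiology:
    def test_ventricular_resting_and_upstroke(self, ventricular):
        f = _paced_features(ventricular)
        assert -88.0 < f.resting_V < -84.0
        assert 250.0 < f.dvdt_max < 420.0
        assert 100.0 < f.amplitude < 140.0
        assert 240.0 < f.apd90 < 330.0

    def test_ventricular_unstimulated_is_stable(self, ventricular):
        tr = run(ventricular, None, 1000.0, rec_interval=1.0)
        assert np.max(np.abs(tr.V - tr.V[0])) < 1.0

    def test_midmyocardial_apd_longest(self):
        apd = {}
        for sub in ("epi", "mid", "endo"):
            apd[sub] = _paced_features(build_model(f"ventricular_TNNP_{sub}")).apd90
        assert apd["mid"] > apd["epi"]
        assert apd["mid"] > apd["endo"]

    def test_atrial_resting_and_upstroke(self, atrial):
        f = _paced_features(atrial)
        assert -77.0 < f.resting_V < -72.0
        assert f.dvdt_max > 80.0
        assert f.amplitude > 100.0

    def test_purkinje_automaticity(self, purkinje):
        tr = run(purkinje, None, 3000.0, rec_interval=0.1)
        f = extract_ap_features(tr)
        assert f.upstroke_count >= 2
        assert f.ectopic_count == f.upstroke_count

    def test_purkinje_captures_pacing(self, purkinje):
        s0 = stabilize(purkinje, 2.5, 5)
        prot = StimulusProtocol(52.0, 1.0, 400.0, n_beats=3)
        tr = run(purkinje, prot, 1200.0, state0=s0, rec_interval=0.05)
        f = extract_ap_features(tr)
        assert f.stimulated_count == 3
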