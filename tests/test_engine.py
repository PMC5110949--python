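import numpy as np
import pytest

from cardiokit import SolverDivergence, StimulusProtocol, run
from cardiokit.engine import ICOEF_LEN, identity_icoef


class TestStimulusProtocol:
    def test_validation(self):
        with pytest.raises(ValueError):
            StimulusProtocol(-1.0, 1.0, 100.0)
        with pytest.raises(ValueError):
            StimulusProtocol(10.0, 0.0, 100.0)
        with pytest.raises(ValueError):
            StimulusProtocol(10.0, 200.0, 100.0)
        with pytest.raises(ValueError):
            StimulusProtocol(10.0, 1.0, 100.0, n_beats=-1)

    def test_stim_times(self):
        p = StimulusProtocol(10.0, 1.0, 100.0, n_beats=5, start=20.0)
        np.testing.assert_allclose(p.stim_times(350.0), [20, 120, 220, 320])

    def test_paced_constructor(self):
        p = StimulusProtocol.paced(10.0, 1.0, 2.5, 2000.0)
        assert p.period == 400.0 and p.n_beats == 5


class TestIdentityCoefficients:
    def test_layout(self):
        c = identity_icoef()
        assert c.shape == (ICOEF_LEN,)
        assert c[8] == 0.5 and c[9] == 1.0 and c[10] == 1.0
        assert np.all(c[:8] == 0.0)


class TestIntegrator:
    def test_returns_trace_with_consistent_shapes(self, toy):
        tr = run(toy, StimulusProtocol(30.0, 1.0, 200.0), 100.0,
                 rec_interval=0.5)
        assert tr.t.shape == tr.V.shape
        assert tr.final_state.shape == (1, toy.n_state)
        assert tr.n_cells == 1

    def test_rejects_nonpositive_time(self, toy):
        with pytest.raises(ValueError):
            run(toy, None, 0.0)

    def test_rejects_bad_state_shape(self, toy):
        with pytest.raises(ValueError):
            run(toy, None, 10.0, state0=np.zeros(5))

    def test_divergence_raises_with_failure_time(self, toy):
        with pytest.raises(SolverDivergence) as err:
            run(toy, StimulusProtocol(500.0, 5.0, 100.0, n_beats=5),
                500.0, dt=5.0)
        assert 0.0 <= err.value.t_fail <= 500.0

    def test_step_halving_convergence_toy(self, toy):
        """Halving the step changes the solution by < 1 % of the AP range."""
        prot = StimulusProtocol(30.0, 1.0, 50.0, n_beats=2)
        t1 = run(toy, prot, 100.0, dt=0.01, rec_interval=0.5)
        t2 = run(toy, prot, 100.0, dt=0.005, rec_interval=0.5)
        rng = t1.V.max() - t1.V.min()
        assert np.max(np.abs(t1.V - t2.V)) < 0.01 * rng

    def test_gates_stay_in_unit_interval(self, ventricular):
        # The calcium-sensing gates (fCa, g) have steady states whose
        # normalization deliberately exceeds 1 at diastolic calcium; all
        # voltage-dependent HH gates must stay in [0, 1].
        ca_gates = {"fCa", "g"}
        tr = run(ventricular, StimulusProtocol(52.0, 1.0, 1000.0), 300.0,
                 rec_interval=1.0)
        final = tr.final_state[0]
        for g in ventricular.gate_idx:
            if ventricular.state_labels[g] in ca_gates:
                continue
            assert 0.0 <= final[g] <= 1.0, ventricular.state_labels[g]

    def test_rhs_matches_kernel_contract(self, ventricular):
        dy = ventricular.rhs(0.0, ventricular.initial_state)
        assert dy.shape == ventricular.initial_state.shape
        assert np.all(np.isfinite(dy))
        cur = ventricular.currents(ventricular.initial_state)
        assert set(cur) == set(ventricular.current_labels)

    def test_multicell_broadcast(self, toy):
        tr = run(toy, StimulusProtocol(30.0, 1.0, 200.0), 50.0, n_cells=5,
                 gj=1.0, stim_cells=[0], rec_interval=0.5)
        assert tr.V.shape[1] == 5
        assert tr.n_cells == 5
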