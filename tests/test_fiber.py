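import numpy as np
import pytest

from cardiokit import apply, build_model, genotype_intervention, make_toy_cell
from cardiokit.fiber import (ConductionBlock, FiberConfig,
                             calibrate_cell_length, conduction_velocity,
                             default_span, fiber_activation_times, measure_cv)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            FiberConfig(n_cells=5)
        with pytest.raises(ValueError):
            FiberConfig(n_stim_cells=0)
        with pytest.raises(ValueError):
            FiberConfig(prepace_beats=-1)

    def test_default_span_is_interior(self):
        i, j = default_span(100)
        assert (i, j) == (20, 80)
        i, j = default_span(60)
        assert 0 < i < j < 60


class TestConductionVelocity:
    def test_linear_activation_gives_exact_cv(self):
        act = np.arange(100) * 0.2            # 0.2 ms per cell
        cv = conduction_velocity(act, 0.01)   # 0.01 cm / 0.2 ms
        assert cv == pytest.approx(50.0)

    def test_block_raises(self):
        act = np.full(100, np.nan)
        with pytest.raises(ConductionBlock):
            conduction_velocity(act, 0.01)

    def test_retrograde_raises(self):
        act = -np.arange(100) * 0.2
        with pytest.raises(ConductionBlock):
            conduction_velocity(act, 0.01)


@pytest.fixture(scope="module")
def toy_cfg():
    return dict(n_cells=40, prepace_beats=2, conditioning_beats=1,
                measure_window_ms=60.0)


class TestToyFiber:
    def test_wave_propagates_with_ordered_activation(self, toy, toy_cfg):
        act = fiber_activation_times(toy, FiberConfig(**toy_cfg))
        i, j = default_span(40)
        assert np.all(np.isfinite(act[i:j + 1]))
        assert np.all(np.diff(act[i:j + 1]) >= 0.0)

    def test_cv_scales_like_sqrt_of_coupling(self, toy, toy_cfg):
        """Cable theory: conduction speed grows as the square root of the
        intercellular coupling; check the factor-4 ratio within 15 %."""
        cvs = {}
        for g in (1.0, 4.0):
            cfg = FiberConfig(g_intercell=g, **toy_cfg)
            cvs[g] = conduction_velocity(
                fiber_activation_times(toy, cfg), 0.01)
        assert cvs[4.0] / cvs[1.0] == pytest.approx(2.0, rel=0.15)

    def test_calibration_is_self_consistent(self, toy, toy_cfg):
        cfg = FiberConfig(**toy_cfg)
        L = calibrate_cell_length(toy, cfg, target_cv=30.0)
        assert measure_cv(toy, L, cfg) == pytest.approx(30.0, rel=1e-9)


class TestAtrialFiber:
    def test_calibration_rejects_modified_model(self, atrial):
        mut = apply(atrial, genotype_intervention("R222Q", "MGTG"))
        with pytest.raises(ValueError, match="wild-type"):
            calibrate_cell_length(mut)

    def test_gain_of_function_speeds_conduction(self, atrial):
        cfg = FiberConfig(n_cells=40, prepace_beats=4)
        L = calibrate_cell_length(atrial, cfg)
        cv_wt = measure_cv(atrial, L, cfg)
        mut = apply(atrial, genotype_intervention("I141V", "MGTG"))
        cv_mut = measure_cv(mut, L, cfg)
        assert cv_mut > cv_wt
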