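"""High-precision oracle for the GHK sodium-current equation."""
import mpmath as mp
import numpy as np
import pytest

from cardiokit import INaParams, ina_ghk


def _ghk_mp(V, m, h1, h2, p: INaParams):
    """Direct 50-digit evaluation of the GHK current form."""
    mp.mp.dps = 50
    V, m, h1, h2 = map(mp.mpf, (V, m, h1, h2))
    F, R, T = map(mp.mpf, (p.F, p.R, p.T))
    fort = F / (R * T)
    ena = mp.mpf(p.E_Na)
    hh = mp.mpf("0.9") * h1 + mp.mpf("0.1") * h2
    num = mp.expm1((V - ena) * fort)
    if V == 0:
        ratio = 1 / fort
    else:
        ratio = V / mp.expm1(V * fort)
    return float(mp.mpf(p.P_Na) * m ** 3 * hh * mp.mpf(p.Na_c) * F * fort
                 * ratio * num / mp.mpf(p.Cm))


@pytest.fixture(scope="module")
def params():
    return INaParams(P_Na=0.0016, Na_c=130.0, E_Na=60.0, Cm=50.0)


class TestGHKOracle:
    def test_matches_high_precision_on_grid(self, params):
        for V in (-120.0, -80.0, -40.0, -0.5, 0.5, 20.0, 59.9, 80.0):
            got = float(ina_ghk(V, 0.9, 0.5, 0.4, params))
            want = _ghk_mp(V, 0.9, 0.5, 0.4, params)
            assert got == pytest.approx(want, rel=1e-10), V

    def test_removable_singularity_at_zero(self, params):
        at0 = float(ina_ghk(0.0, 0.9, 0.5, 0.4, params))
        want = _ghk_mp(0, 0.9, 0.5, 0.4, params)
        assert at0 == pytest.approx(want, rel=1e-10)
        near = float(ina_ghk(1e-9, 0.9, 0.5, 0.4, params))
        assert near == pytest.approx(at0, rel=1e-6)

    def test_vectorized_consistency(self, params):
        V = np.linspace(-100, 40, 29)
        vec = ina_ghk(V, 0.5, 0.5, 0.5, params)
        sca = np.array([float(ina_ghk(v, 0.5, 0.5, 0.5, params)) for v in V])
        np.testing.assert_allclose(vec, sca, rtol=1e-12)

    def test_inward_below_reversal(self, params):
        assert float(ina_ghk(-20.0, 0.9, 0.9, 0.9, params)) < 0.0
        assert float(ina_ghk(80.0, 0.9, 0.9, 0.9, params)) > 0.0
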