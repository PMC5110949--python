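"""Two-variable toy excitable cell (FitzHugh-Nagumo dynamics).

A fast cubic variable and a linear recovery variable, mapped onto the
membrane-potential scale (rest near -70 mV, pulse overshoot above 0 mV) so
that every protocol and the cable solver can be exercised in milliseconds.
No claim of cardiac realism is made.

    du/dt = (u - u^3/3 - w + I_bias)/tau_u + I_stim/V_SCALE
    dw/dt = (u + a - b*w)/tau_w

with V = V_SCALE*u + V_OFFSET.  ``a`` sets the excitation threshold; a
positive ``I_bias`` pushes the rest point onto the unstable middle branch and
gives a self-oscillatory cell (mimicking Purkinje automaticity).
"""
from __future__ import annotations

import numpy as np
from numba import njit

V_SCALE = 25.0
V_OFFSET = -40.0
TAU_U = 0.3   # ms
TAU_W = 8.0   # ms
B = 0.8

STATE_LABELS = ("V", "w")
GATE_IDX = ()
CURRENT_LABELS = ("I_fast",)
DT = 0.01


@njit(cache=True)
def kernel(S, istim, icoef, pvec, dS, yinf, ytau, cur):
    a = pvec[0]
    bias = pvec[1]
    u = (S[0] - V_OFFSET) / V_SCALE
    w = S[1]
    du = (u - u ** 3 / 3.0 - w + bias) / TAU_U
    dS[0] = V_SCALE * du              # stimulus is added by the integrator
    dS[1] = (u + a - B * w) / TAU_W
    cur[0] = -V_SCALE * du


def rest_point(a: float, bias: float) -> tuple:
    """Fixed point of the toy dynamics (u*, w*)."""
    # u - u^3/3 - (u + a)/B + bias = 0
    coeffs = [-1.0 / 3.0, 0.0, 1.0 - 1.0 / B, bias - a / B]
    roots = np.roots(coeffs)
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    u = real[0]                       # leftmost branch (resting for excitable a)
    return float(u), float((u + a) / B)
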