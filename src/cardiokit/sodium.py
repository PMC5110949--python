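"""Goldman-Hodgkin-Katz form of the fast sodium current.

The atrial model expresses I_Na through a permeability rather than a
conductance:

    I_Na = P_Na m^3 (0.9 h1 + 0.1 h2) [Na+]_c V F^2/(R T)
           * (e^{(V - E_Na) F/RT} - 1) / (e^{V F/RT} - 1)

The function below is a total function of real V: the removable singularity
at V = 0 is evaluated through its analytic limit V/(e^{VF/RT}-1) -> RT/F.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["INaParams", "ina_ghk"]


@dataclass(frozen=True)
class INaParams:
    """Parameters of the GHK sodium current.

    With P_Na in nL/s, [Na+]_c in mM, V and E_Na in mV and F, R, T in
    C/mol, mJ/(mol K), K, the raw equation yields pA; ``Cm`` (pF) converts
    to uA/uF (leave at 1.0 for the raw pA value).
    """

    P_Na: float          # nL/s
    Na_c: float          # mM, cleft/extracellular sodium
    E_Na: float          # mV
    F: float = 96487.0   # C/mol
    R: float = 8314.0    # mJ/(mol K)
    T: float = 306.15    # K
    Cm: float = 1.0      # pF


def ina_ghk(V, m, h1, h2, p: INaParams):
    """Evaluate the GHK sodium current at membrane potential ``V`` (mV).

    Vectorized over ``V`` and the gate values; gates are expected in [0, 1].
    Returns the current in pA / ``p.Cm``.
    """
    V = np.asarray(V, dtype=float)
    fort = p.F / (p.R * p.T)             # 1/mV
    occ = m ** 3 * (0.9 * h1 + 0.1 * h2)
    drive = np.exp((V - p.E_Na) * fort) - 1.0
    small = np.abs(V) < 1e-6
    Vsafe = np.where(small, 1.0, V)
    ratio = np.where(small, 1.0 / fort, Vsafe / np.expm1(Vsafe * fort))
    out = p.P_Na * occ * p.Na_c * p.F * fort * ratio * drive / p.Cm
    return float(out) if out.ndim == 0 else out
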