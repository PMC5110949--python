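"""Simulation engine: cell-model container, stimulus protocols and the
fixed-step integrator.

All models share one integration contract: a numba kernel evaluates, for a
single cell, the state derivatives, the steady state/time constant of every
Hodgkin-Huxley-type gate, and a small set of recorded currents.  The
integrator advances non-gating states with forward Euler and gating states
with the Rush-Larsen exponential update, which keeps gates in [0, 1] by
construction.  A 1D fiber is the same loop over ``n`` cells plus a discrete
Laplacian coupling term on the membrane potential with sealed (no-flux) ends.

Units: time ms, voltage mV, transmembrane currents uA/uF (= mV/ms),
intercellular conductance mS/uF.  Stimulus amplitudes are positive
depolarizing.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "ICOEF_LEN",
    "identity_icoef",
    "CellModel",
    "StimulusProtocol",
    "Trace",
    "SolverDivergence",
    "run",
]

# Layout of the intervention-coefficient vector threaded through every kernel.
# Two independent I_Na "alleles" (A and B) are always integrated; a plain WT
# cell simply carries two identical copies.  Shifts are mV added to the
# voltage argument of the named gate function.
ICOEF_LEN = 12
MINF_A, MKIN_A, HINF_A, HKIN_A = 0, 1, 2, 3
MINF_B, MKIN_B, HINF_B, HKIN_B = 4, 5, 6, 7
MIX_A = 8          # weight of allele A in the summed I_Na (0.5 = heterozygous mixing)
SCALE_CAL = 9      # multiplicative scale on I_CaL
SCALE_KS = 10      # multiplicative scale on I_Ks


def identity_icoef() -> np.ndarray:
    """Coefficient vector that leaves the model bit-identical to baseline."""
    c = np.zeros(ICOEF_LEN)
    c[MIX_A] = 0.5
    c[SCALE_CAL] = 1.0
    c[SCALE_KS] = 1.0
    return c


class SolverDivergence(RuntimeError):
    """Raised when the state becomes non-finite; carries the failure time."""

    def __init__(self, t_fail: float):
        self.t_fail = t_fail
        super().__init__(f"solver diverged (non-finite state) at t = {t_fail:.3f} ms")


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic rectangular current stimulus.

    amplitude in uA/uF (depolarizing positive), duration and period in ms,
    ``n_beats`` pulses starting at ``start`` ms.
    """

    amplitude: float
    duration: float
    period: float
    n_beats: int = 1
    start: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be >= 0")
        if self.duration <= 0 or self.period <= 0:
            raise ValueError("stimulus duration and period must be > 0")
        if self.duration >= self.period:
            raise ValueError("stimulus duration must be shorter than the period")
        if self.n_beats < 0:
            raise ValueError("n_beats must be >= 0")

    def stim_times(self, t_total: float) -> np.ndarray:
        """Onset times of the pulses that fall inside [0, t_total)."""
        k = np.arange(self.n_beats)
        t = self.start + k * self.period
        return t[t < t_total]

    @classmethod
    def paced(cls, amplitude: float, duration: float, rate_hz: float,
              t_total: float, start: float = 0.0) -> "StimulusProtocol":
        period = 1000.0 / rate_hz
        n = int(np.ceil((t_total - start) / period))
        return cls(amplitude, duration, period, n_beats=max(n, 0), start=start)


@dataclass
class CellModel:
    """A named ODE cell model with a uniform simulation contract.

    ``kernel`` has the numba signature
    ``kernel(state, istim, icoef, pvec, dstate, yinf, ytau, cur)`` where
    ``dstate`` receives derivatives (used for non-gating states), ``yinf`` and
    ``ytau`` receive the gate steady states / time constants for the indices
    in ``gate_idx``, and ``cur`` receives the recorded currents.
    """

    name: str
    family: str
    state_labels: tuple
    params: dict
    initial_state: np.ndarray
    kernel: Callable
    gate_idx: tuple
    current_labels: tuple
    dt: float                      # reference fixed step (ms)
    pvec: np.ndarray = field(default_factory=lambda: np.zeros(1))
    icoef: np.ndarray = field(default_factory=identity_icoef)
    meta: dict = field(default_factory=dict)

    @property
    def n_state(self) -> int:
        return len(self.state_labels)

    def copy(self) -> "CellModel":
        return replace(
            self,
            initial_state=self.initial_state.copy(),
            pvec=self.pvec.copy(),
            icoef=self.icoef.copy(),
            params=dict(self.params),
            meta=dict(self.meta),
        )

    def rhs(self, t: float, state: np.ndarray, istim: float = 0.0) -> np.ndarray:
        """Exact right-hand side dy/dt at ``state`` (gates via (y_inf-y)/tau)."""
        state = np.asarray(state, dtype=float)
        dS = np.zeros(self.n_state)
        yinf = np.zeros(self.n_state)
        ytau = np.ones(self.n_state)
        cur = np.zeros(len(self.current_labels))
        self.kernel(state, istim, self.icoef, self.pvec, dS, yinf, ytau, cur)
        out = dS.copy()
        for g in self.gate_idx:
            out[g] = (yinf[g] - state[g]) / ytau[g]
        out[0] += istim
        return out

    def currents(self, state: np.ndarray, istim: float = 0.0) -> dict:
        state = np.asarray(state, dtype=float)
        dS = np.zeros(self.n_state)
        yinf = np.zeros(self.n_state)
        ytau = np.ones(self.n_state)
        cur = np.zeros(len(self.current_labels))
        self.kernel(state, istim, self.icoef, self.pvec, dS, yinf, ytau, cur)
        return dict(zip(self.current_labels, cur))


@dataclass
class Trace:
    """Recorded time series from one simulation (single cell or fiber)."""

    t: np.ndarray                    # (n_rec,) ms
    V: np.ndarray                    # (n_rec,) or (n_rec, n_cells) mV
    currents: dict                   # label -> array shaped like V
    stim_times: np.ndarray           # onset times of delivered stimuli (ms)
    final_state: np.ndarray          # (n_cells, n_state) at the end of the run
    dt: float
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return 1 if self.V.ndim == 1 else self.V.shape[1]

    def dvdt(self) -> np.ndarray:
        return np.gradient(self.V, self.t, axis=0)


# ---------------------------------------------------------------------------
# Integrator factory: one compiled loop per model kernel.

_RUNNERS: dict = {}


def _build_runner(kernel, n_state: int, gate_idx: tuple, n_cur: int):
    gate_arr = np.asarray(gate_idx, dtype=np.int64)
    euler = [k for k in range(1, n_state) if k not in gate_idx]
    euler_arr = np.asarray(euler, dtype=np.int64)

    @njit(cache=False)
    def _run(S, dt, n_steps, t0, pvec, icoef, gj, stim_mask,
             amp, dur, period, start, n_beats,
             rec_every, recV, recC, record_cur):
        n_cells = S.shape[0]
        dS = np.empty((n_cells, n_state))
        yinf = np.empty((n_cells, n_state))
        ytau = np.empty((n_cells, n_state))
        cur = np.empty((n_cells, n_cur))
        Vnew = np.empty(n_cells)
        irec = 0
        for k in range(n_steps):
            t = t0 + k * dt
            istim = 0.0
            ph = t - start
            if ph >= -1e-12 and amp > 0.0:
                b = int(ph // period) if ph > 0 else 0
                if b < n_beats and (ph - b * period) < dur:
                    istim = amp
            for i in range(n_cells):
                ist = istim if stim_mask[i] else 0.0
                kernel(S[i], ist, icoef, pvec, dS[i], yinf[i], ytau[i], cur[i])
            if k % rec_every == 0:
                for i in range(n_cells):
                    recV[irec, i] = S[i, 0]
                if record_cur:
                    for i in range(n_cells):
                        for c in range(n_cur):
                            recC[irec, i, c] = cur[i, c]
                irec += 1
            for i in range(n_cells):
                lap = 0.0
                if n_cells > 1:
                    if i > 0:
                        lap += S[i - 1, 0] - S[i, 0]
                    if i < n_cells - 1:
                        lap += S[i + 1, 0] - S[i, 0]
                ist = istim if stim_mask[i] else 0.0
                Vnew[i] = S[i, 0] + dt * (dS[i, 0] + ist + gj * lap)
            for i in range(n_cells):
                for gi in range(gate_arr.shape[0]):
                    g = gate_arr[gi]
                    yi = yinf[i, g]
                    S[i, g] = yi + (S[i, g] - yi) * np.exp(-dt / ytau[i, g])
                for ei in range(euler_arr.shape[0]):
                    e = euler_arr[ei]
                    S[i, e] += dt * dS[i, e]
                S[i, 0] = Vnew[i]
            if (k & 2047) == 2047 or k == n_steps - 1:
                for i in range(n_cells):
                    if not np.isfinite(S[i, 0]):
                        return t
        return -1.0

    return _run


def get_runner(model: CellModel):
    key = (model.family, model.n_state, model.gate_idx)
    if key not in _RUNNERS:
        _RUNNERS[key] = _build_runner(
            model.kernel, model.n_state, model.gate_idx, len(model.current_labels)
        )
    return _RUNNERS[key]


def run(model: CellModel,
        protocol: StimulusProtocol | None,
        t_total: float,
        *,
        dt: float | None = None,
        rec_interval: float = 0.1,
        record_currents: bool = False,
        state0: np.ndarray | None = None,
        n_cells: int = 1,
        gj: float = 0.0,
        stim_cells: Sequence[int] | None = None,
        t0: float = 0.0) -> Trace:
    """Advance the model for ``t_total`` ms and return a :class:`Trace`.

    ``state0`` may be a single-cell state (broadcast to all cells) or a full
    ``(n_cells, n_state)`` array.  ``rec_interval`` decouples the output
    sampling from the integration step.
    """
    if t_total <= 0:
        raise ValueError("t_total must be > 0")
    dt = model.dt if dt is None else float(dt)
    if state0 is None:
        S = np.tile(model.initial_state, (n_cells, 1)).astype(float)
    else:
        state0 = np.asarray(state0, dtype=float)
        S = (np.tile(state0, (n_cells, 1)) if state0.ndim == 1
             else state0.copy())
        n_cells = S.shape[0]
    if S.shape != (n_cells, model.n_state):
        raise ValueError("state0 has the wrong shape for this model")

    stim_mask = np.zeros(n_cells, dtype=np.bool_)
    if protocol is not None and protocol.amplitude > 0:
        idx = list(range(n_cells)) if stim_cells is None else list(stim_cells)
        stim_mask[idx] = True
        amp, dur, period = protocol.amplitude, protocol.duration, protocol.period
        n_beats, start = protocol.n_beats, protocol.start
    else:
        amp = dur = 0.0
        period = 1.0
        n_beats = 0
        start = 0.0

    n_steps = int(round(t_total / dt))
    rec_every = max(int(round(rec_interval / dt)), 1)
    n_rec = (n_steps - 1) // rec_every + 1
    recV = np.empty((n_rec, n_cells))
    n_cur = len(model.current_labels)
    recC = np.empty((n_rec, n_cells, n_cur) if record_currents else (1, 1, n_cur))

    runner = get_runner(model)
    t_fail = runner(S, dt, n_steps, t0, model.pvec, model.icoef, gj, stim_mask,
                    amp, dur, period, start, n_beats,
                    rec_every, recV, recC, record_currents)
    if t_fail >= 0.0:
        raise SolverDivergence(t_fail)

    t = t0 + np.arange(n_rec) * rec_every * dt
    V = recV[:, 0] if n_cells == 1 else recV
    currents = {}
    if record_currents:
        for c, lab in enumerate(model.current_labels):
            currents[lab] = recC[:, 0, c] if n_cells == 1 else recC[:, :, c]
    stim_times = (protocol.stim_times(t0 + t_total) if protocol is not None
                  and protocol.amplitude > 0 else np.array([]))
    stim_times = stim_times[stim_times >= t0] if stim_times.size else stim_times
    return Trace(t=t, V=V, currents=currents, stim_times=stim_times,
                 final_state=S, dt=dt,
                 meta={"model": model.name, "gj": gj, "n_cells": n_cells})
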