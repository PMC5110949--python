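"""Single-cell experiment battery.

Voltage-clamp protocols exploit that, at a clamped potential, every I_Na gate
relaxes exponentially to its steady state: the prepulse and test-step gate
trajectories are evaluated in closed form and only the current waveform is
sampled.  Action-potential protocols run the full model and extract features
from the recorded membrane potential.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CellModel, SolverDivergence, StimulusProtocol, run
from .models import maleckar, stewart, tnnp

__all__ = [
    "APFeatures", "SDCurve",
    "availability_curve", "clamp_peak_ina",
    "extract_ap_features", "stabilize",
    "excitation_threshold", "strength_duration_curve",
    "transmural_dispersion",
]

# Upstroke detector convention: dV/dt > 10 V/s marks an upstroke, upstrokes
# closer than 50 ms are one event, and an upstroke is "stimulated" when it
# starts within 20 ms of a stimulus onset -- otherwise it is ectopic.
DVDT_THRESHOLD = 10.0    # mV/ms
REFRACTORY_MS = 50.0
STIM_LATENCY_MS = 20.0


@dataclass
class APFeatures:
    """Features of the analyzed (by default last stimulated) action potential."""

    resting_V: float        # mV, V at the stimulus onset of the analyzed beat
    amplitude: float        # mV, peak minus resting_V
    dvdt_max: float         # V/s
    apd90: float            # ms, from dV/dt_max time to 90 % repolarization
    upstroke_count: int
    ectopic_count: int
    stimulated_count: int = 0
    peak_V: float = float("nan")
    repol_time: float = float("nan")   # absolute time of 90 % repolarization


@dataclass
class SDCurve:
    """Strength-duration curve: threshold amplitude per stimulus duration."""

    points: list            # [(duration ms, threshold uA/uF), ...]
    pacing_rate: float      # Hz

    @property
    def durations(self):
        return np.array([p[0] for p in self.points])

    @property
    def thresholds(self):
        return np.array([p[1] for p in self.points])


# ---------------------------------------------------------------------------
# closed-form I_Na clamp machinery

def _na_system(model: CellModel):
    """Per-allele gate tables and the mixed I_Na evaluator for a model."""
    ic = model.icoef
    alleles = [dict(s_minf=ic[4 * a + 0], s_mkin=ic[4 * a + 1],
                    s_hinf=ic[4 * a + 2], s_hkin=ic[4 * a + 3],
                    w=ic[8] if a == 0 else 1.0 - ic[8]) for a in (0, 1)]
    if model.family in ("tnnp", "sannbz"):
        mod = tnnp if model.family == "tnnp" else stewart

        def gates(V, al):
            return {
                "m": (tnnp.m_inf(V + al["s_minf"]), tnnp.tau_m(V, al["s_mkin"])),
                "h": (tnnp.h_inf(V + al["s_hinf"]), tnnp.tau_h(V, al["s_hkin"])),
                "j": (tnnp.j_inf(V), tnnp.tau_j(V)),
            }

        def current(V, g, al):
            return al["w"] * mod.i_na(V, g["m"], g["h"], g["j"])
    elif model.family == "mgtg":
        def gates(V, al):
            return {
                "m": (maleckar.m_inf(V + al["s_minf"]), maleckar.tau_m(V, al["s_mkin"])),
                "h1": (maleckar.h_inf(V + al["s_hinf"]), maleckar.tau_h1(V, al["s_hkin"])),
                "h2": (maleckar.h_inf(V + al["s_hinf"]), maleckar.tau_h2(V, al["s_hkin"])),
            }

        def current(V, g, al):
            return al["w"] * maleckar.i_na(V, g["m"], g["h1"], g["h2"])
    else:
        raise ValueError(f"model family {model.family!r} exposes no I_Na")
    return alleles, gates, current


def _relax(y0, inf, tau, t):
    return inf + (y0 - inf) * np.exp(-t / tau)


def clamp_peak_ina(model: CellModel, holding_V: float, step_V: float = -20.0,
                   hold_ms: float = 500.0, step_ms: float = 30.0,
                   dt: float = 0.01):
    """Peak inward I_Na elicited by a step from a holding potential.

    Gates start from their steady state at a fully repolarized potential
    (-120 mV), relax at ``holding_V`` for ``hold_ms`` and are then stepped to
    ``step_V``; the current time course during the step is returned together
    with the peak (most negative) value, in uA/uF.
    """
    alleles, gates, current = _na_system(model)
    t = np.arange(0.0, step_ms + dt, dt)
    total = np.zeros_like(t)
    for al in alleles:
        g0 = {k: v[0] for k, v in gates(-120.0, al).items()}
        gh = gates(holding_V, al)
        ghold = {k: _relax(g0[k], gh[k][0], gh[k][1], hold_ms) for k in g0}
        gs = gates(step_V, al)
        gstep = {k: _relax(ghold[k], gs[k][0], gs[k][1], t) for k in ghold}
        total += current(step_V, gstep, al)
    ipk = float(total[np.argmax(np.abs(total))])
    return ipk, (t, total)


def availability_curve(model: CellModel, prepulse_range, test_V: float = -20.0,
                       prepulse_ms: float = 500.0, step_ms: float = 30.0,
                       dt: float = 0.01):
    """Steady-state availability: normalized peak I_Na vs prepulse voltage."""
    prepulse_range = np.asarray(prepulse_range, dtype=float)
    if prepulse_range.size == 0:
        raise ValueError("empty prepulse grid")
    peaks = np.array([
        abs(clamp_peak_ina(model, vp, step_V=test_V, hold_ms=prepulse_ms,
                           step_ms=step_ms, dt=dt)[0])
        for vp in prepulse_range
    ])
    return prepulse_range, peaks / peaks.max()


# ---------------------------------------------------------------------------
# AP features and ectopy

def _upstroke_onsets(t, V):
    dvdt = np.gradient(V, t)
    above = dvdt > DVDT_THRESHOLD
    onsets = []
    last = -np.inf
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:                      # already rising at the first sample
        idx = np.concatenate(([0], idx))
    for i in idx:
        if t[i] - last >= REFRACTORY_MS:
            onsets.append(i)
            last = t[i]
    return np.array(onsets, dtype=int), dvdt


def extract_ap_features(trace, stim_times=None, beat: str | int = "last") -> APFeatures:
    """Detect upstrokes, classify them as stimulated or ectopic, and measure
    the analyzed beat.

    APD90 runs from the time of maximum dV/dt to 90 % repolarization toward
    the membrane potential at the stimulus onset of that beat.
    """
    t, V = trace.t, np.asarray(trace.V)
    if V.ndim != 1:
        raise ValueError("extract_ap_features expects a single-cell trace")
    stim_times = np.asarray(trace.stim_times if stim_times is None else stim_times,
                            dtype=float)
    onsets, dvdt = _upstroke_onsets(t, V)
    if onsets.size == 0:
        return APFeatures(resting_V=float(V[0]), amplitude=0.0, dvdt_max=0.0,
                          apd90=float("nan"), upstroke_count=0, ectopic_count=0)

    assigned = np.full(onsets.size, -1, dtype=int)
    for k, i in enumerate(onsets):
        if stim_times.size:
            dtm = t[i] - stim_times
            ok = (dtm >= 0) & (dtm <= STIM_LATENCY_MS + 1e-9)
            if ok.any():
                assigned[k] = int(np.flatnonzero(ok)[-1])
    stimulated = assigned >= 0
    n_ect = int((~stimulated).sum())

    cand = np.flatnonzero(stimulated)
    if cand.size == 0:
        cand = np.arange(onsets.size)
    k = cand[-1] if beat == "last" else cand[int(beat)]
    i0 = onsets[k]
    # analysis window: up to the next upstroke (or end of trace)
    i1 = onsets[k + 1] if k + 1 < onsets.size else V.size
    if assigned[k] >= 0:
        v_rest = float(np.interp(stim_times[assigned[k]], t, V))
        t_ref = stim_times[assigned[k]]
    else:
        v_rest = float(V[max(i0 - 1, 0)])
        t_ref = t[i0]
    seg = slice(i0, i1)
    ipk = i0 + int(np.argmax(V[seg]))
    v_peak = float(V[ipk])
    idv = i0 + int(np.argmax(dvdt[seg]))
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.flatnonzero(V[ipk:i1] <= v90)
    if below.size:
        j = ipk + below[0]
        # linear interpolation of the crossing time
        if j > ipk and V[j - 1] > v90:
            t_repol = float(np.interp(v90, [V[j], V[j - 1]], [t[j], t[j - 1]]))
        else:
            t_repol = float(t[j])
        apd90 = t_repol - float(t[idv])
    else:
        t_repol = float("nan")
        apd90 = float("nan")
    return APFeatures(
        resting_V=v_rest,
        amplitude=v_peak - v_rest,
        dvdt_max=float(dvdt[idv]),
        apd90=apd90,
        upstroke_count=int(onsets.size),
        ectopic_count=n_ect,
        stimulated_count=int(stimulated.sum()),
        peak_V=v_peak,
        repol_time=t_repol,
    )


# ---------------------------------------------------------------------------
# pacing, thresholds, strength-duration

def default_protocol(model: CellModel, rate_hz: float | None = None,
                     t_total: float | None = None) -> StimulusProtocol:
    """The figure-caption pacing stimulus of the model's family."""
    meta = model.meta
    rate = meta["pacing_hz"] if rate_hz is None else rate_hz
    period = 1000.0 / rate
    n = 10 ** 6 if t_total is None else int(np.ceil(t_total / period))
    return StimulusProtocol(meta["stim_amplitude"], meta["stim_duration"],
                            period, n_beats=n)


def stabilize(model: CellModel, pacing_rate: float, n_beats: int,
              dt: float | None = None, amplitude: float | None = None,
              duration: float | None = None) -> np.ndarray:
    """Pace for ``n_beats`` and return the state at the end of the last cycle
    (immediately before the next stimulus would be delivered)."""
    period = 1000.0 / pacing_rate
    amp = model.meta["stim_amplitude"] if amplitude is None else amplitude
    dur = model.meta["stim_duration"] if duration is None else duration
    prot = StimulusProtocol(amp, dur, period, n_beats=n_beats)
    tr = run(model, prot, n_beats * period, dt=dt, rec_interval=1.0)
    return tr.final_state[0]


def _elicits_ap(model, state0, amplitude, duration, dt, window_ms) -> bool:
    prot = StimulusProtocol(amplitude, duration, period=10 * window_ms, n_beats=1)
    try:
        tr = run(model, prot, window_ms, dt=dt, state0=state0, rec_interval=0.1)
    except SolverDivergence:
        if amplitude > 0.0:
            # a stimulus strong enough to push the model out of its validity
            # domain certainly excited the cell; the bisection then retreats
            # to amplitudes where the model is well-behaved
            return True
        raise
    return bool(np.max(tr.V) > 0.0)       # propagated-upstroke criterion


def excitation_threshold(model: CellModel, duration: float, pacing_rate: float,
                         state0: np.ndarray | None = None,
                         amp_cap: float = 400.0, rel_tol: float = 0.01,
                         prepace_beats: int = 10, dt: float | None = None,
                         window_ms: float = 40.0) -> float:
    """Minimal stimulus amplitude (uA/uF) eliciting an AP on the test beat.

    Bisection over amplitude after stabilization pacing; an AP is an
    overshoot above 0 mV within ``window_ms`` of the test stimulus.  The
    window is kept short (twice the 20 ms stimulated-upstroke latency
    convention) so that spontaneous diastolic firing of automatic cells
    later in the cycle does not masquerade as a stimulated response; if the
    cell fires within the window at zero amplitude the threshold is
    undefined and an error is raised.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    dt = model.dt if dt is None else dt
    if state0 is None:
        state0 = stabilize(model, pacing_rate, prepace_beats, dt=dt)
    if _elicits_ap(model, state0, 0.0, duration, dt, window_ms):
        raise RuntimeError("cell fires without stimulus; threshold undefined")
    if not _elicits_ap(model, state0, amp_cap, duration, dt, window_ms):
        raise RuntimeError(f"no AP even at the amplitude cap {amp_cap} uA/uF")
    lo, hi = 0.0, amp_cap
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _elicits_ap(model, state0, mid, duration, dt, window_ms):
            hi = mid
        else:
            lo = mid
    return hi


def strength_duration_curve(model: CellModel, durations, pacing_rate: float,
                            prepace_beats: int = 10, dt: float | None = None,
                            **kwargs) -> SDCurve:
    """Excitation threshold for each stimulus duration (one stabilization)."""
    durations = list(durations)
    if not durations or any(d <= 0 for d in durations):
        raise ValueError("durations must be a non-empty list of positive values")
    dt = model.dt if dt is None else dt
    state0 = stabilize(model, pacing_rate, prepace_beats, dt=dt)
    pts = [(float(d),
            excitation_threshold(model, d, pacing_rate, state0=state0, dt=dt,
                                 **kwargs))
           for d in durations]
    return SDCurve(points=pts, pacing_rate=pacing_rate)


# ---------------------------------------------------------------------------
# transmural dispersion

def transmural_dispersion(epi, mid, endo, stim_times=None) -> float:
    """Spread (max - min, ms) of the 90 % repolarization times of the three
    ventricular subtypes under an identical protocol."""
    traces = {"epi": epi, "mid": mid, "endo": endo}
    missing = [k for k, v in traces.items() if v is None]
    if missing:
        raise ValueError(f"missing ventricular subtype trace(s): {missing}")
    reps = {}
    for k, tr in traces.items():
        f = extract_ap_features(tr, stim_times=stim_times)
        if not np.isfinite(f.repol_time):
            raise ValueError(f"could not measure repolarization time for {k}")
        reps[k] = f.repol_time
    vals = np.array(list(reps.values()))
    return float(vals.max() - vals.min())
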