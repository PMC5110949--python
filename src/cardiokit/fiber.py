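"""1D homogeneous fiber simulations and conduction velocity.

A fiber is ``n_cells`` copies of one cell model coupled through a discrete
Laplacian on the membrane potential with sealed ends; a stimulus applied to
the first few cells launches a wave whose conduction velocity is measured
from the activation times (time of maximal dV/dt) over an interior span of
cells, away from both boundaries.

The discrete model has no intrinsic length scale, so the physical cell
length is a calibration constant: it is fixed once per model family by
requiring that the wild-type fiber without drug reproduces that family's
reference conduction velocity, and then held fixed across all genotype and
drug conditions.  The pipeline is: pace a single cell to its limit cycle,
seed every fiber cell with that state, run one conditioning fiber beat, and
measure the following beat.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import CellModel, StimulusProtocol, run
from .protocols import stabilize

__all__ = [
    "FiberConfig", "ConductionBlock",
    "fiber_activation_times", "conduction_velocity", "measure_cv",
    "calibrate_cell_length", "REFERENCE_CV", "REFERENCE_TABLE4", "default_span",
]

# Reference wild-type (no drug) conduction velocities, cm/s, used only to
# calibrate the cell length of each family.
REFERENCE_CV = {"mgtg": 55.07, "tnnp": 49.91, "sannbz": 67.68}

# Published reference conduction velocities (cm/s) for the full condition
# grid, keyed (family, genotype) -> (control, 30 uM E3G); ``None`` marks a
# reported conduction block.  Only the WT control column is ever used for
# calibration; the rest serve as comparison references.
REFERENCE_TABLE4 = {
    ("mgtg", "WT"): (55.07, 50.84),
    ("mgtg", "I141V"): (57.44, 53.93),
    ("mgtg", "R222Q"): (60.93, 56.23),
    ("tnnp", "WT"): (49.91, 45.72),
    ("tnnp", "I141V"): (53.63, 49.11),
    ("tnnp", "R222Q"): (51.93, 45.56),
    ("sannbz", "WT"): (67.68, 37.20),
    ("sannbz", "I141V"): (72.43, 42.92),
    ("sannbz", "R222Q"): (62.72, None),
}

# Interior span used for the CV measurement: by default the middle 20-80 %
# of the fiber (excludes the stimulus site and both sealed ends).
def default_span(n_cells: int) -> tuple:
    return (n_cells // 5, (4 * n_cells) // 5)


class ConductionBlock(RuntimeError):
    """The wave failed to propagate across the measurement span."""


@dataclass(frozen=True)
class FiberConfig:
    """Geometry, coupling and stimulation of a 1D fiber experiment."""

    n_cells: int = 100
    g_intercell: float | None = None     # mS/uF; None = family default
    dt: float | None = None              # ms; None = family default
    n_stim_cells: int = 3
    stim_scale: float = 2.0              # x the family caption amplitude
    prepace_beats: int = 10              # single-cell limit-cycle pacing
    conditioning_beats: int | None = None  # fiber beats before the measured
                                           # one; None = family default
    pacing_rate: float | None = None     # Hz; None = family default
    measure_window_ms: float = 100.0     # recording window of the measured beat

    def __post_init__(self):
        if self.n_cells < 10:
            raise ValueError("a fiber needs at least 10 cells")
        if not 0 < self.n_stim_cells < self.n_cells:
            raise ValueError("invalid number of stimulated cells")
        if ((self.conditioning_beats is not None and self.conditioning_beats < 0)
                or self.prepace_beats < 0):
            raise ValueError("beat counts must be >= 0")


def _resolved(model: CellModel, cfg: FiberConfig):
    meta = model.meta
    g = meta["fiber_g"] if cfg.g_intercell is None else cfg.g_intercell
    dt = meta["fiber_dt"] if cfg.dt is None else cfg.dt
    rate = meta["pacing_hz"] if cfg.pacing_rate is None else cfg.pacing_rate
    amp = cfg.stim_scale * meta["stim_amplitude"]
    dur = meta["stim_duration"]
    n_cond = (meta.get("fiber_cond_beats", 1) if cfg.conditioning_beats is None
              else cfg.conditioning_beats)
    return g, dt, rate, amp, dur, n_cond


def fiber_activation_times(model: CellModel, cfg: FiberConfig = FiberConfig(),
                           rec_interval: float = 0.05) -> np.ndarray:
    """Activation time of every cell (ms, relative to the measured-beat
    stimulus onset) for a planar wave launched from one fiber end.

    Cells whose potential never overshoots 0 mV during the measurement
    window are reported as ``nan`` (blocked).
    """
    g, dt, rate, amp, dur, n_cond = _resolved(model, cfg)
    period = 1000.0 / rate
    if cfg.prepace_beats > 0:
        s0 = stabilize(model, rate, cfg.prepace_beats, dt=dt)
    else:
        s0 = model.initial_state
    state = np.tile(s0, (cfg.n_cells, 1))
    stim_cells = list(range(cfg.n_stim_cells))
    if n_cond > 0:
        prot = StimulusProtocol(amp, dur, period, n_beats=n_cond)
        tr = run(model, prot, n_cond * period, dt=dt,
                 rec_interval=5.0, state0=state, gj=g, stim_cells=stim_cells)
        state = tr.final_state
    prot = StimulusProtocol(amp, dur, period, n_beats=1)
    tr = run(model, prot, cfg.measure_window_ms, dt=dt,
             rec_interval=rec_interval, state0=state, gj=g,
             stim_cells=stim_cells)
    dvdt = np.gradient(tr.V, tr.t, axis=0)
    act = tr.t[np.argmax(dvdt, axis=0)].astype(float)
    act[np.max(tr.V, axis=0) <= 0.0] = np.nan
    return act


def conduction_velocity(activation_times: np.ndarray, cell_length_cm: float,
                        span: tuple | None = None) -> float:
    """Conduction velocity (cm/s) from per-cell activation times.

    Uses the two ends of the interior ``span``; raises
    :class:`ConductionBlock` if either end never activates or the wave does
    not advance across the span.
    """
    i, j = default_span(len(activation_times)) if span is None else span
    ti, tj = activation_times[i], activation_times[j]
    if not (np.isfinite(ti) and np.isfinite(tj)) or tj <= ti:
        raise ConductionBlock(
            f"no propagated activation across cells {i}..{j}"
        )
    return cell_length_cm * (j - i) / (tj - ti) * 1000.0


def calibrate_cell_length(model_wt: CellModel, cfg: FiberConfig = FiberConfig(),
                          target_cv: float | None = None,
                          span: tuple | None = None) -> float:
    """Cell length (cm) that makes the wild-type control fiber conduct at the
    family's reference velocity.  ``model_wt`` must be the unmodified model."""
    if model_wt.meta.get("interventions"):
        raise ValueError("calibration requires the unmodified wild-type model")
    if target_cv is None:
        target_cv = REFERENCE_CV[model_wt.family]
    act = fiber_activation_times(model_wt, cfg)
    i, j = default_span(len(act)) if span is None else span
    if not (np.isfinite(act[i]) and np.isfinite(act[j])) or act[j] <= act[i]:
        raise ConductionBlock("wild-type fiber did not conduct; cannot calibrate")
    return target_cv * (act[j] - act[i]) / 1000.0 / (j - i)


def measure_cv(model: CellModel, cell_length_cm: float,
               cfg: FiberConfig = FiberConfig(),
               span: tuple | None = None) -> float:
    """Conduction velocity (cm/s) of the model in a 1D fiber."""
    act = fiber_activation_times(model, cfg)
    return conduction_velocity(act, cell_length_cm, span=span)
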