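"""Model registry: the three human cardiac cell models plus the toy cell.

``build_model(name)`` is the single entry point; each returned
:class:`~cardiokit.engine.CellModel` carries, in ``meta``, the default pacing
stimulus used in the source figures and the fiber parameters (intercellular
conductance, step size) associated with its family.
"""
from __future__ import annotations

import numpy as np

from ..engine import CellModel
from . import maleckar, stewart, tnnp, toy

__all__ = ["MODEL_NAMES", "build_model", "make_toy_cell"]

MODEL_NAMES = (
    "atrial_MGTG",
    "ventricular_TNNP_epi",
    "ventricular_TNNP_mid",
    "ventricular_TNNP_endo",
    "purkinje_SANNBZ",
    "toy",
)

# Default pacing stimulus (amplitude uA/uF, duration ms, rate Hz) from the
# source figure captions, and fiber parameters (g mS/uF, dt ms, number of
# entrainment beats before the measured fiber beat) per family.  The
# self-oscillatory Purkinje fiber needs several paced beats to entrain to the
# 2.5 Hz drive; the quiescent families settle within one.
_FAMILY_META = {
    "mgtg": dict(stim_amplitude=15.0, stim_duration=6.0, pacing_hz=1.0,
                 fiber_g=17.0, fiber_dt=0.01, fiber_cond_beats=1),
    "tnnp": dict(stim_amplitude=52.0, stim_duration=1.0, pacing_hz=1.0,
                 fiber_g=7.0, fiber_dt=0.001, fiber_cond_beats=1),
    "sannbz": dict(stim_amplitude=52.0, stim_duration=1.0, pacing_hz=2.5,
                   fiber_g=17.0, fiber_dt=0.01, fiber_cond_beats=10),
    "toy": dict(stim_amplitude=30.0, stim_duration=1.0, pacing_hz=5.0,
                fiber_g=1.0, fiber_dt=0.01, fiber_cond_beats=1),
}


def make_toy_cell(threshold_param: float = 0.7, oscillatory: bool = False) -> CellModel:
    """Build the toy excitable cell.

    ``threshold_param`` (the FitzHugh-Nagumo ``a``) must lie in [0.4, 1.2],
    the documented excitable range; ``oscillatory=True`` adds a bias current
    that makes the cell fire spontaneously.
    """
    if not 0.4 <= threshold_param <= 1.2:
        raise ValueError(
            f"threshold_param={threshold_param} outside the excitable range [0.4, 1.2]"
        )
    bias = 0.8 if oscillatory else 0.0
    u0, w0 = toy.rest_point(threshold_param, bias)
    state0 = np.array([toy.V_SCALE * u0 + toy.V_OFFSET, w0 + (0.05 if oscillatory else 0.0)])
    meta = dict(_FAMILY_META["toy"])
    meta["oscillatory"] = oscillatory
    return CellModel(
        name="toy",
        family="toy",
        state_labels=toy.STATE_LABELS,
        params={"threshold_param": threshold_param, "bias": bias},
        initial_state=state0,
        kernel=toy.kernel,
        gate_idx=toy.GATE_IDX,
        current_labels=toy.CURRENT_LABELS,
        dt=toy.DT,
        pvec=np.array([threshold_param, bias]),
        meta=meta,
    )


def build_model(name: str) -> CellModel:
    """Return a fully parameterized cell model for ``name``.

    Raises ``ValueError`` listing the valid identifiers for an unknown name.
    """
    if name == "atrial_MGTG":
        return CellModel(
            name=name, family="mgtg",
            state_labels=maleckar.STATE_LABELS,
            params=dict(maleckar._P),
            initial_state=maleckar.INITIAL_STATE.copy(),
            kernel=maleckar.kernel,
            gate_idx=maleckar.GATE_IDX,
            current_labels=maleckar.CURRENT_LABELS,
            dt=maleckar.DT,
            pvec=np.zeros(1),
            meta=dict(_FAMILY_META["mgtg"]),
        )
    if name.startswith("ventricular_TNNP_"):
        subtype = name.rsplit("_", 1)[-1]
        if subtype in tnnp.SUBTYPES:
            meta = dict(_FAMILY_META["tnnp"])
            meta["subtype"] = subtype
            return CellModel(
                name=name, family="tnnp",
                state_labels=tnnp.STATE_LABELS,
                params=dict(tnnp._P, **tnnp.SUBTYPES[subtype]),
                initial_state=tnnp.INITIAL_STATE.copy(),
                kernel=tnnp.kernel,
                gate_idx=tnnp.GATE_IDX,
                current_labels=tnnp.CURRENT_LABELS,
                dt=tnnp.DT,
                pvec=tnnp.pvec_for(subtype),
                meta=meta,
            )
    if name == "purkinje_SANNBZ":
        return CellModel(
            name=name, family="sannbz",
            state_labels=stewart.STATE_LABELS,
            params=dict(stewart._P),
            initial_state=stewart.INITIAL_STATE.copy(),
            kernel=stewart.kernel,
            gate_idx=stewart.GATE_IDX,
            current_labels=stewart.CURRENT_LABELS,
            dt=stewart.DT,
            pvec=np.zeros(1),
            meta=dict(_FAMILY_META["sannbz"]),
        )
    if name == "toy":
        return make_toy_cell()
    raise ValueError(
        f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
    )
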