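"""Declarative genotype and drug interventions on the fast sodium current.

An :class:`Intervention` is a set of voltage-argument shifts of named I_Na
gate functions plus multiplicative scalings of other currents.  Shifts follow
the convention ``x_modified(V) = x_WT(V + shift)``, so a positive shift moves
the curve toward more negative potentials (a hyperpolarizing shift).

Genotypes
---------
* **p.R222Q** (MEPPC): activation midpoint 6.3 mV hyperpolarized (steady
  state and, in the ventricular/Purkinje formulation, the alpha_m/beta_m
  rates), inactivation midpoint 6.2 mV hyperpolarized.
* **p.I141V** (EPVT): activation midpoint 7 mV hyperpolarized with the same
  7 mV acceleration of activation kinetics and of the inactivation rate
  (beta_h in the ventricular/Purkinje form, the h factor in the atrial
  form); the inactivation steady state is unchanged.

Heterozygous states are the summation of half WT and half mutant current,
each allele carrying its own, independently integrated gate variables.

Drug
----
**30 uM E3G** shifts the steady-state inactivation curve h_inf 6 mV
hyperpolarized on both alleles (m and j gates untouched) and scales I_CaL to
80 % and I_Ks to 50 % of control.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CellModel, ICOEF_LEN

__all__ = [
    "GateShift", "Intervention",
    "e3g_intervention", "genotype_intervention", "apply",
]

# gate-function name -> icoef slot offset within an allele block
_SLOT = {
    "m_inf": 0,
    "alpha_m": 1,
    "beta_m": 1,
    "m_factor": 1,
    "h_inf": 2,
    "beta_h": 3,
    "h_factor": 3,
}

_SCALABLE = {"I_CaL": 9, "I_Ks": 10}

_FAMILY_OF = {"tnnp": "TNNP_SANNBZ", "sannbz": "TNNP_SANNBZ", "mgtg": "MGTG"}


@dataclass(frozen=True)
class GateShift:
    """Voltage-argument shift of one I_Na gate function.

    ``shift`` is added to the voltage argument (mV); ``shift = 0`` with no
    substitution is the identity.  ``substitute`` names a replacement gate
    function; only native-function shifts are supported (the published
    rate-substitution rows are treated as shifted native rates).
    """

    target: str
    shift: float
    substitute: str | None = None

    def __post_init__(self):
        if self.target not in _SLOT:
            raise ValueError(
                f"unknown gate function {self.target!r}; known: {sorted(_SLOT)}"
            )
        if self.substitute is not None and self.substitute != self.target:
            raise NotImplementedError(
                "rate-function substitution is not supported; express the "
                "modification as a voltage shift of the native function"
            )


@dataclass(frozen=True)
class Intervention:
    """A genotype and/or drug effect on a cell model."""

    label: str
    gate_shifts: tuple = ()
    current_scales: dict = field(default_factory=dict)
    zygosity: str = "none"          # none | heterozygous | homozygous
    family: str | None = None       # None = applies to any model family

    def __post_init__(self):
        if self.zygosity not in ("none", "heterozygous", "homozygous"):
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        for cur, s in self.current_scales.items():
            if cur not in _SCALABLE:
                raise ValueError(f"scaling not supported for current {cur!r}")
            if not 0.0 < s <= 1.0:
                raise ValueError(f"current scale for {cur} must be in (0, 1], got {s}")


def e3g_intervention() -> Intervention:
    """30 uM Epigallocatechin-3-Gallate.

    h_inf availability curve moved 6 mV hyperpolarized (argument V + 6) on
    both alleles, I_CaL scaled to 0.8 and I_Ks to 0.5 of control; m and j
    gates untouched.
    """
    return Intervention(
        label="E3G_30uM",
        gate_shifts=(GateShift("h_inf", 6.0),),
        current_scales={"I_CaL": 0.8, "I_Ks": 0.5},
        zygosity="none",
    )


def genotype_intervention(which: str, model_family: str,
                          zygosity: str = "heterozygous",
                          include_inactivation_shift: bool = True) -> Intervention:
    """Gate modifications of the Na_v1.5 p.R222Q or p.I141V mutation.

    ``model_family`` is ``"TNNP_SANNBZ"`` (conductance-form I_Na with
    alpha/beta rate functions) or ``"MGTG"`` (GHK-form I_Na with m/h
    factors).  ``include_inactivation_shift=False`` drops the R222Q h_inf
    shift only (mechanistic ablation of the inactivation component).
    """
    if model_family not in ("TNNP_SANNBZ", "MGTG"):
        raise ValueError("model_family must be 'TNNP_SANNBZ' or 'MGTG'")
    if which == "R222Q":
        if model_family == "TNNP_SANNBZ":
            shifts = [GateShift("m_inf", 6.3), GateShift("alpha_m", 6.3),
                      GateShift("beta_m", 6.3)]
        else:
            shifts = [GateShift("m_inf", 6.3)]
        if include_inactivation_shift:
            shifts.append(GateShift("h_inf", 6.2))
    elif which == "I141V":
        if not include_inactivation_shift:
            raise ValueError("I141V has no inactivation steady-state shift to ablate")
        if model_family == "TNNP_SANNBZ":
            shifts = [GateShift("m_inf", 7.0), GateShift("alpha_m", 7.0),
                      GateShift("beta_m", 7.0), GateShift("beta_h", 7.0)]
        else:
            shifts = [GateShift("m_inf", 7.0), GateShift("m_factor", 7.0),
                      GateShift("h_factor", 7.0)]
    else:
        raise ValueError(f"unknown genotype {which!r}; valid: R222Q, I141V")
    label = f"{which}_{zygosity}"
    if not include_inactivation_shift:
        label += "_no_hinf_shift"
    return Intervention(label=label, gate_shifts=tuple(shifts),
                        zygosity=zygosity, family=model_family)


def apply(model: CellModel, interventions) -> CellModel:
    """Return a new CellModel with the interventions applied (out-of-place).

    Genotype interventions with heterozygous zygosity place the mutation on
    allele B only (allele A stays WT, 0.5/0.5 mixing); homozygous mutations
    and drug effects go to both alleles.  Interventions compose additively
    (shifts) and multiplicatively (scales).  Applying a non-trivial zygosity
    twice is an error.
    """
    if isinstance(interventions, Intervention):
        interventions = [interventions]
    new = model.copy()
    fam = _FAMILY_OF.get(model.family)
    icoef = new.icoef
    for iv in interventions:
        if iv.family is not None and iv.family != fam:
            raise ValueError(
                f"intervention {iv.label!r} targets family {iv.family}, "
                f"model {model.name} is {fam}"
            )
        if iv.zygosity != "none":
            if new.meta.get("zygosity") not in (None, "none"):
                raise ValueError(
                    f"model already carries zygosity {new.meta['zygosity']!r}"
                )
            new.meta["zygosity"] = iv.zygosity
        alleles = (1,) if iv.zygosity == "heterozygous" else (0, 1)
        # collect shifts per slot, checking rate-pair consistency
        slot_shift: dict = {}
        for gs in iv.gate_shifts:
            slot = _SLOT[gs.target]
            if slot in slot_shift and slot_shift[slot] != gs.shift:
                raise ValueError(
                    f"inconsistent shifts for kinetics slot of {gs.target!r}"
                )
            slot_shift[slot] = gs.shift
        for al in alleles:
            for slot, shift in slot_shift.items():
                icoef[4 * al + slot] += shift
        for cur, s in iv.current_scales.items():
            icoef[_SCALABLE[cur]] *= s
        new.meta.setdefault("interventions", []).append(iv.label)
    assert icoef.shape == (ICOEF_LEN,)
    return new
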