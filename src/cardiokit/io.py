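"""Experiment configuration, orchestration and results serialization.

A :class:`RunConfig` names one experiment (AP features, I_Na availability
clamp, strength-duration curve, conduction velocity, or transmural
dispersion) on one condition (model x genotype x zygosity x drug).
``run_experiment`` validates the whole config up front (reporting every
problem at once), dispatches to the protocol layer and returns a tidy
pandas table; ``write_results`` serializes it deterministically.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import interventions as iv
from . import protocols as pr
from .engine import run
from .fiber import (ConductionBlock, FiberConfig, calibrate_cell_length,
                    measure_cv)
from .models import MODEL_NAMES, build_model

__all__ = ["RunConfig", "run_experiment", "write_results", "table4", "GENOTYPES"]

EXPERIMENTS = ("ap", "clamp", "sd_curve", "cv", "dispersion")
GENOTYPES = ("WT", "R222Q", "I141V")
ZYGOSITIES = ("heterozygous", "homozygous")
SCHEDULES = ("paper", "scaled")

# Stabilization/size presets.  "paper" is the full published protocol;
# "scaled" is a documented smaller preset for quick runs and the test suite
# (shorter stabilization, shorter fiber) -- same physics, coarser statistics.
_SCHED = {
    "paper": dict(prepace=10, n_cells=100, analyze_beats=2),
    "scaled": dict(prepace=4, n_cells=60, analyze_beats=2),
}

_FAMILY_OF_MODEL = {
    "mgtg": "MGTG", "tnnp": "TNNP_SANNBZ", "sannbz": "TNNP_SANNBZ",
}


@dataclass(frozen=True)
class RunConfig:
    """One experiment on one condition."""

    experiment: str
    model: str = "ventricular_TNNP_epi"
    genotype: str = "WT"
    zygosity: str = "heterozygous"
    e3g: bool = False
    pacing_hz: float | None = None        # None = family default
    stim_amplitude: float | None = None
    stim_duration: float | None = None
    schedule: str = "paper"
    out_csv: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        """Check every field; raise one ValueError listing all problems."""
        errs = []
        if self.experiment not in EXPERIMENTS:
            errs.append(f"experiment {self.experiment!r} not in {EXPERIMENTS}")
        if self.model not in MODEL_NAMES:
            errs.append(f"model {self.model!r} not in {MODEL_NAMES}")
        if self.genotype not in GENOTYPES:
            errs.append(f"genotype {self.genotype!r} not in {GENOTYPES}")
        if self.zygosity not in ZYGOSITIES:
            errs.append(f"zygosity {self.zygosity!r} not in {ZYGOSITIES}")
        if self.schedule not in SCHEDULES:
            errs.append(f"schedule {self.schedule!r} not in {SCHEDULES}")
        for name in ("pacing_hz", "stim_amplitude", "stim_duration"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                errs.append(f"{name} must be > 0, got {v}")
        if self.model == "toy" and self.genotype != "WT":
            errs.append("the toy cell has no sodium-channel genotypes")
        if errs:
            raise ValueError("invalid config:\n  " + "\n  ".join(errs))


def _condition(cfg: RunConfig, model_name: str | None = None):
    model = build_model(model_name or cfg.model)
    ivs = []
    if cfg.genotype != "WT":
        fam = _FAMILY_OF_MODEL[model.family]
        ivs.append(iv.genotype_intervention(cfg.genotype, fam, cfg.zygosity))
    if cfg.e3g:
        ivs.append(iv.e3g_intervention())
    return iv.apply(model, ivs) if ivs else model


def _label_cols(cfg: RunConfig) -> dict:
    return {
        "model": cfg.model,
        "genotype": cfg.genotype if cfg.genotype == "WT"
        else f"{cfg.genotype}_{cfg.zygosity[:3]}",
        "e3g": "30uM" if cfg.e3g else "control",
    }


def _pacing(cfg: RunConfig, model):
    rate = cfg.pacing_hz or model.meta["pacing_hz"]
    amp = cfg.stim_amplitude or model.meta["stim_amplitude"]
    dur = cfg.stim_duration or model.meta["stim_duration"]
    return rate, amp, dur


def _exp_ap(cfg: RunConfig) -> pd.DataFrame:
    sched = _SCHED[cfg.schedule]
    model = _condition(cfg)
    rate, amp, dur = _pacing(cfg, model)
    period = 1000.0 / rate
    s0 = pr.stabilize(model, rate, sched["prepace"], amplitude=amp, duration=dur)
    nb = sched["analyze_beats"]
    prot = pr.StimulusProtocol(amp, dur, period, n_beats=nb)
    tr = run(model, prot, nb * period, state0=s0, rec_interval=0.05)
    f = pr.extract_ap_features(tr)
    row = {**_label_cols(cfg), "pacing_hz": rate,
           "resting_V_mV": f.resting_V, "amplitude_mV": f.amplitude,
           "dvdt_max_V_per_s": f.dvdt_max, "apd90_ms": f.apd90,
           "upstrokes": f.upstroke_count, "ectopic": f.ectopic_count}
    return pd.DataFrame([row])


def _exp_clamp(cfg: RunConfig) -> pd.DataFrame:
    model = _condition(cfg)
    vgrid = np.arange(-120.0, -29.9, 2.5)
    v, a = pr.availability_curve(model, vgrid)
    df = pd.DataFrame({"prepulse_mV": v, "availability": a})
    for k, val in _label_cols(cfg).items():
        df.insert(0, k, val)
    return df


def _exp_sd(cfg: RunConfig) -> pd.DataFrame:
    sched = _SCHED[cfg.schedule]
    model = _condition(cfg)
    rate, _, _ = _pacing(cfg, model)
    durations = (0.5, 1.0, 2.0, 4.0, 8.0)
    sd = pr.strength_duration_curve(model, durations, rate,
                                    prepace_beats=sched["prepace"])
    df = pd.DataFrame({"duration_ms": sd.durations,
                       "threshold_uA_per_uF": sd.thresholds})
    for k, val in _label_cols(cfg).items():
        df.insert(0, k, val)
    return df


def _fiber_cfg(cfg: RunConfig) -> FiberConfig:
    sched = _SCHED[cfg.schedule]
    return FiberConfig(n_cells=sched["n_cells"], prepace_beats=sched["prepace"],
                       pacing_rate=cfg.pacing_hz)


def _exp_cv(cfg: RunConfig) -> pd.DataFrame:
    fcfg = _fiber_cfg(cfg)
    wt = build_model(cfg.model)
    L = calibrate_cell_length(wt, fcfg)
    model = _condition(cfg)
    try:
        cv = measure_cv(model, L, fcfg)
        blocked = False
    except ConductionBlock:
        cv, blocked = np.nan, True
    row = {**_label_cols(cfg), "cell_length_cm": L,
           "cv_cm_per_s": cv, "conduction_block": blocked}
    return pd.DataFrame([row])


def _exp_dispersion(cfg: RunConfig) -> pd.DataFrame:
    if not cfg.model.startswith("ventricular_TNNP"):
        raise ValueError("dispersion is defined for the ventricular model family")
    sched = _SCHED[cfg.schedule]
    traces, rate0 = {}, None
    for sub in ("epi", "mid", "endo"):
        model = _condition(cfg, model_name=f"ventricular_TNNP_{sub}")
        rate, amp, dur = _pacing(cfg, model)
        rate0 = rate
        period = 1000.0 / rate
        s0 = pr.stabilize(model, rate, sched["prepace"], amplitude=amp,
                          duration=dur)
        prot = pr.StimulusProtocol(amp, dur, period, n_beats=1)
        traces[sub] = run(model, prot, period, state0=s0, rec_interval=0.05)
    disp = pr.transmural_dispersion(traces["epi"], traces["mid"], traces["endo"])
    feats = {s: pr.extract_ap_features(t) for s, t in traces.items()}
    row = {**_label_cols(cfg), "pacing_hz": rate0,
           "apd90_epi_ms": feats["epi"].apd90,
           "apd90_mid_ms": feats["mid"].apd90,
           "apd90_endo_ms": feats["endo"].apd90,
           "dispersion_ms": disp}
    return pd.DataFrame([row])


_DISPATCH = {"ap": _exp_ap, "clamp": _exp_clamp, "sd_curve": _exp_sd,
             "cv": _exp_cv, "dispersion": _exp_dispersion}


def run_experiment(cfg: RunConfig) -> pd.DataFrame:
    """Validate, run and (if ``out_csv`` is set) serialize one experiment."""
    cfg.validate()
    table = _DISPATCH[cfg.experiment](cfg)
    if cfg.out_csv:
        write_results(table, cfg.out_csv)
    return table


def write_results(table: pd.DataFrame, path: str) -> None:
    """Deterministic CSV: fixed column order, floats at fixed precision."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    table.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def table4(schedule: str = "paper", models=None, out_csv: str | None = None,
           progress=None) -> pd.DataFrame:
    """Conduction velocity over the full grid: each model family x
    {WT, R222Q het, I141V het} x {control, 30 uM E3G}, one cell-length
    calibration per family."""
    if models is None:
        models = ("atrial_MGTG", "ventricular_TNNP_epi", "purkinje_SANNBZ")
    rows = []
    for name in models:
        base = RunConfig(experiment="cv", model=name, schedule=schedule)
        base.validate()
        fcfg = _fiber_cfg(base)
        wt = build_model(name)
        L = calibrate_cell_length(wt, fcfg)
        for gen in GENOTYPES:
            for drug in (False, True):
                cfg = dataclasses.replace(base, genotype=gen, e3g=drug)
                model = _condition(cfg)
                try:
                    cv = measure_cv(model, L, fcfg)
                    blocked = False
                except ConductionBlock:
                    cv, blocked = np.nan, True
                row = {**_label_cols(cfg), "cell_length_cm": L,
                       "cv_cm_per_s": cv, "conduction_block": blocked}
                rows.append(row)
                if progress is not None:
                    progress(row)
    table = pd.DataFrame(rows)
    if out_csv:
        write_results(table, out_csv)
    return table
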