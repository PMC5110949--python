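"""Voltage-clamp view of the interventions on the fast sodium current.

Reproduces the availability (steady-state inactivation) protocol: a long
prepulse at each holding potential followed by a test step, peak I_Na
normalized to its maximum.  E3G shifts availability toward more negative
potentials; the atrial resting potential (~ -74 mV) sits on the steep part
of the curve, the ventricular one (~ -86 mV) near its plateau — which is
why the drug's effect on the upstroke is so much milder in atrium.
"""
import numpy as np

from cardiokit import (apply, availability_curve, build_model, clamp_peak_ina,
                       e3g_intervention, genotype_intervention)

vgrid = np.arange(-120.0, -29.9, 10.0)

for name, family in (("atrial_MGTG", "MGTG"),
                     ("ventricular_TNNP_epi", "TNNP_SANNBZ")):
    wt = build_model(name)
    conditions = {
        "WT": wt,
        "R222Q het": apply(wt, genotype_intervention("R222Q", family)),
        "WT + E3G": apply(wt, e3g_intervention()),
    }
    print(f"\n=== {name}: availability vs prepulse voltage ===")
    print("V_pre " + "".join(f"{lbl:>12s}" for lbl in conditions))
    curves = {lbl: availability_curve(m, vgrid)[1]
              for lbl, m in conditions.items()}
    for k, v in enumerate(vgrid):
        print(f"{v:5.0f} " + "".join(f"{curves[lbl][k]:12.3f}"
                                     for lbl in conditions))
    for hv in (-90.0, -70.0):
        pc, _ = clamp_peak_ina(wt, hv)
        pd, _ = clamp_peak_ina(conditions["WT + E3G"], hv)
        print(f"peak I_Na ratio (E3G/control) from holding {hv:.0f} mV: "
              f"{abs(pd) / abs(pc):.3f}")
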