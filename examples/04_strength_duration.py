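"""Strength-duration (excitability) curves.

The threshold stimulus amplitude falls with pulse duration toward the
rheobase.  Gain-of-function sodium mutations lower the threshold at every
duration (the cell is easier to excite); E3G raises it back — one mechanism
of its antiarrhythmic effect.
"""
from cardiokit import (apply, build_model, e3g_intervention,
                       genotype_intervention, strength_duration_curve)

DURATIONS = (0.5, 1.0, 2.0, 4.0, 8.0)

for name, family in (("purkinje_SANNBZ", "TNNP_SANNBZ"),
                     ("atrial_MGTG", "MGTG")):
    wt = build_model(name)
    rate = wt.meta["pacing_hz"]
    conditions = {
        "WT": wt,
        "I141V het": apply(wt, genotype_intervention("I141V", family)),
        "WT + E3G": apply(wt, e3g_intervention()),
    }
    print(f"\n=== {name} thresholds (uA/uF), pacing {rate} Hz ===")
    print("dur ms " + "".join(f"{lbl:>12s}" for lbl in conditions))
    curves = {lbl: strength_duration_curve(m, DURATIONS, rate,
                                           prepace_beats=6).thresholds
              for lbl, m in conditions.items()}
    for k, d in enumerate(DURATIONS):
        print(f"{d:6.1f} " + "".join(f"{curves[lbl][k]:12.2f}"
                                     for lbl in conditions))
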