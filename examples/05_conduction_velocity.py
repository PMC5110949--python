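"""Conduction velocity in a 1D atrial fiber (scaled-down demo).

The cell length is calibrated once so the wild-type control fiber conducts
at the family's reference velocity; it is then held fixed while genotype
and drug are varied, so every other number is a prediction.  Uses a short
fiber (60 cells) and few stabilization beats to finish in about a minute;
see 06_full_cv_table.py for the full-size grid.
"""
from cardiokit import (FiberConfig, apply, build_model, calibrate_cell_length,
                       e3g_intervention, genotype_intervention, measure_cv)
from cardiokit.fiber import ConductionBlock

cfg = FiberConfig(n_cells=60, prepace_beats=6)
wt = build_model("atrial_MGTG")
L = calibrate_cell_length(wt, cfg)
print(f"calibrated atrial cell length: {L * 1e4:.1f} um")

print(f"{'condition':22s} {'CV cm/s':>8s}")
for gen in (None, "R222Q", "I141V"):
    for drug in (False, True):
        ivs = []
        if gen:
            ivs.append(genotype_intervention(gen, "MGTG"))
        if drug:
            ivs.append(e3g_intervention())
        model = apply(wt, ivs) if ivs else wt
        label = f"{gen or 'WT'}{' + E3G' if drug else ''}"
        try:
            cv = measure_cv(model, L, cfg)
            print(f"{label:22s} {cv:8.2f}")
        except ConductionBlock:
            print(f"{label:22s} {'block':>8s}")
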