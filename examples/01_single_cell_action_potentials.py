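"""Single-cell action potentials and what 30 uM E3G does to them.

Builds the three human cell models (atrial, ventricular epicardial,
Purkinje), paces each at its native rate, and compares AP features with and
without the drug.  The expected pattern: E3G depresses the upstroke
(amplitude and dV/dt_max fall everywhere), prolongs the Purkinje AP, and
shortens the midmyocardial AP.
"""
from cardiokit import (StimulusProtocol, apply, build_model, e3g_intervention,
                       extract_ap_features, run, stabilize)

MODELS = ("atrial_MGTG", "ventricular_TNNP_epi", "ventricular_TNNP_mid",
          "purkinje_SANNBZ")


def paced_features(model, prepace=6, n_beats=2):
    rate = model.meta["pacing_hz"]
    period = 1000.0 / rate
    s0 = stabilize(model, rate, prepace)
    prot = StimulusProtocol(model.meta["stim_amplitude"],
                            model.meta["stim_duration"], period, n_beats)
    trace = run(model, prot, n_beats * period, state0=s0, rec_interval=0.05)
    return extract_ap_features(trace)


print(f"{'model':24s} {'drug':8s} {'rest mV':>8s} {'amp mV':>7s} "
      f"{'dV/dt V/s':>10s} {'APD90 ms':>9s}")
for name in MODELS:
    for drugged in (False, True):
        model = build_model(name)
        if drugged:
            model = apply(model, e3g_intervention())
        f = paced_features(model)
        print(f"{name:24s} {'E3G' if drugged else 'control':8s} "
              f"{f.resting_V:8.1f} {f.amplitude:7.1f} "
              f"{f.dvdt_max:10.0f} {f.apd90:9.1f}")
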