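# cardiokit

In-silico cardiac electrophysiology of sodium channelopathies: human
atrial, ventricular and Purkinje cell models with declarative interventions
for the Na_v1.5 gain-of-function mutations **p.R222Q** (MEPPC) and
**p.I141V** (EPVT) and for **30 µM Epigallocatechin-3-Gallate (E3G)**, the
major green-tea catechin, plus the protocols to measure what they do:
action-potential features, ectopy, sodium-current availability, excitation
thresholds, transmural dispersion, and conduction velocity in 1D fibers.

## Quick start

```python
from cardiokit import (build_model, apply, genotype_intervention,
                       e3g_intervention, FiberConfig,
                       calibrate_cell_length, measure_cv)

cfg = FiberConfig(n_cells=60, prepace_beats=6)       # scaled-down demo size
wt = build_model("atrial_MGTG")
L = calibrate_cell_length(wt, cfg)                   # one-time WT calibration

mut = apply(wt, genotype_intervention("R222Q", "MGTG"))        # heterozygous
drugged = apply(mut, e3g_intervention())

print(measure_cv(wt, L, cfg), measure_cv(mut, L, cfg), measure_cv(drugged, L, cfg))
```

prints (cm/s):

```
55.07000000000001 59.65916666666666 47.43981927710843
```

— the gain-of-function mutation speeds atrial conduction, the drug slows it
back.  The same heterozygous machinery is exact by construction: every
model integrates two independent I_Na allele populations, so under voltage
clamp the heterozygous current equals the mean of the WT and mutant
currents to machine precision.

Single-cell phenotype in three lines:

```python
from cardiokit import build_model, apply, genotype_intervention
m = apply(build_model("purkinje_SANNBZ"),
          genotype_intervention("R222Q", "TNNP_SANNBZ"))
# pace at 1 Hz and count upstrokes not triggered by the stimulus
```

(see `examples/03_purkinje_ectopy.py` — R222Q fires ectopically at 1 Hz;
adding E3G or pacing at 2.5 Hz silences it.)

## Command line

```bash
cardiokit ap        --model purkinje_SANNBZ --genotype R222Q
cardiokit clamp     --model atrial_MGTG --e3g --out availability.csv
cardiokit sd-curve  --model ventricular_TNNP_epi --schedule scaled
cardiokit cv        --model atrial_MGTG --genotype I141V --schedule scaled
cardiokit dispersion --e3g
cardiokit table4    --out cv_table.csv     # the full grid (~15 min)
```

Each subcommand also accepts `--config experiment.yaml`; CLI flags override
the file.

## Repository map

```
src/cardiokit/
  engine.py         fixed-step integrator (Euler + Rush-Larsen), numba kernels
  models/           atrial (Maleckar 2009), ventricular (ten Tusscher 2004,
                    epi/mid/endo), Purkinje (Stewart 2009), toy (FitzHugh-
                    Nagumo); parameters in models/data/*.yaml
  sodium.py         GHK form of I_Na (oracle-tested)
  interventions.py  genotype / drug gate shifts + current scalings
  protocols.py      clamp, AP features & ectopy, thresholds, dispersion
  fiber.py          1D cable, WT-calibrated conduction velocity
  io.py, cli.py     RunConfig validation, tidy CSV results, click CLI
examples/           narrative scripts, one per capability
tests/              unit + property tests; test_acceptance.py holds the
                    end-to-end phenotype checks
scripts/acceptance.py  computes the headline fiber velocities as JSON
docs/methods.md     models, conventions, numerics, limitations
```

## Notes

* Everything is deterministic: fixed-step integration, no randomness.
* The fiber's cell length is calibrated once per family on the wild-type
  control only; all other velocities are predictions.  Known quantitative
  deviations from the reference velocities (notably the Purkinje fiber
  under E3G) are documented in `docs/methods.md` — they are reported, not
  tuned away.
* The `toy` model runs the full pipeline in milliseconds and is used to
  oracle-test thresholds and the CV ∝ √(coupling) law.
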