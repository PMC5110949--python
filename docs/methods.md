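# Methods

## Scope

`cardiokit` is an in-silico study pipeline for two Na_v1.5 gain-of-function
channelopathies — p.R222Q (associated with multifocal ectopic
Purkinje-related premature contractions, MEPPC) and p.I141V (exercise-induced
polymorphic ventricular tachycardia, EPVT) — and for the green-tea catechin
Epigallocatechin-3-Gallate (E3G, 30 µM) as a candidate antiarrhythmic.
It provides three human cardiac cell models, declarative gate-level
interventions, single-cell excitability protocols, and 1D-fiber conduction
velocity measurement.

## Cell models

All models are systems of ODEs with Hodgkin–Huxley-type gating, transcribed
from their original publications:

| registry name            | preparation         | lineage                                  | states | dt (ms) |
|--------------------------|---------------------|------------------------------------------|--------|---------|
| `atrial_MGTG`            | human atrial        | Maleckar et al. 2009 (Nygren 1998 line)  | 32     | 0.01    |
| `ventricular_TNNP_{epi,mid,endo}` | human ventricular | ten Tusscher et al. 2004          | 20     | 0.001   |
| `purkinje_SANNBZ`        | human Purkinje      | Stewart et al. 2009                      | 23     | 0.01    |
| `toy`                    | synthetic           | FitzHugh–Nagumo, rescaled to mV/ms       | 2      | 0.01    |

Conventions: time in ms, voltage in mV, transmembrane current in µA/µF,
positive stimulus depolarizing.  The atrial model natively works in seconds,
pA and per-litre concentrations; it is converted to the shared unit system
at load time (membrane capacitance 50 pF).  The atrial I_Na uses the
Goldman–Hodgkin–Katz permeability form

    I_Na = P_Na m³ (0.9 h1 + 0.1 h2) [Na⁺]_c V F²/(RT) ·
           (e^{(V−E_Na)F/RT} − 1) / (e^{VF/RT} − 1),

implemented as a total function of V (the removable singularity at V = 0 is
evaluated through its analytic limit) and unit-tested against a 50-digit
`mpmath` oracle.  The ventricular/Purkinje I_Na is the conductance form
g_Na·m³·h·j·(V − E_Na).  The ventricular epi/mid/endo subtypes differ only
in their transient-outward and I_Ks conductances; the 2004 formulation is
used throughout (the Purkinje model carries the later calcium machinery of
its own source).  Model parameters and initial states live in YAML files
under `cardiokit/models/data/`; rate equations live in the numba kernels,
one per family, each exposing a labelled gate table and recorded currents.

The toy cell is first-class: it exercises the identical engine, protocol
and fiber code paths in milliseconds and anchors the oracle tests
(bisection-vs-sweep thresholds, CV ∝ √g coupling law).

## Interventions

Every kernel integrates **two independent I_Na allele populations** (A and
B), each with its own gate states, mixed 50/50.  A wild-type cell simply
carries two identical copies — so heterozygous mixing is not a special
case, and under voltage clamp the heterozygous current is *exactly* the
mean of the all-WT and all-mutant currents (a test asserts this to 1e-12).

Shifts follow `x_modified(V) = x_WT(V + shift)`: a positive shift moves the
curve toward more negative potentials (hyperpolarizing).

* **R222Q**: activation midpoint (m∞, and α_m/β_m in the conductance-form
  models) shifted +6.3 mV; inactivation steady state h∞ shifted +6.2 mV.
* **I141V**: activation (m∞ with its rate functions) shifted +7 mV; the
  inactivation *rate* (β_h, or the atrial h-factor) shifted +7 mV; h∞
  unchanged.
* **E3G 30 µM**: h∞ shifted +6 mV on both alleles; I_CaL scaled ×0.8;
  I_Ks scaled ×0.5.

Heterozygous genotypes put the mutation on allele B only; homozygous on
both; drug effects always on both.  Interventions compose additively
(shifts) / multiplicatively (scales), are applied out-of-place, and
applying a second non-trivial zygosity is an error.  An ablation switch
(`include_inactivation_shift=False`) removes only the R222Q h∞ shift for
mechanism dissection.

## Numerics

Fixed-step integration: forward Euler for non-gating states, Rush–Larsen
exponential updates for gates (`y ← y∞ + (y − y∞)e^{−dt/τ}`), which keeps
gates bounded by construction.  One numba-compiled loop per model family
serves both single cells and fibers; non-finite states raise
`SolverDivergence` with the failure time.  Step-halving on the toy model
changes the solution by < 1 % of the AP range (tested).

Voltage-clamp protocols do not time-step the full model: at a clamped
potential every I_Na gate relaxes exponentially in closed form, so
availability curves and peak-current ratios are evaluated analytically up
to the current waveform sampling.

## Protocols

* **AP features**: upstrokes are dV/dt > 10 V/s crossings with a 50 ms
  refractory; an upstroke within 20 ms of a stimulus onset is *stimulated*,
  otherwise *ectopic*.  APD90 runs from the time of maximal dV/dt to 90 %
  repolarization toward the potential at the stimulus onset.
* **Excitation threshold**: bisection over stimulus amplitude (relative
  tolerance 1 %), an AP being an overshoot above 0 mV within 40 ms of the
  test pulse (twice the stimulated-latency convention, so diastolic
  automaticity later in the cycle is not mistaken for capture).  Strength–
  duration curves reuse one stabilized state across durations.
* **Transmural dispersion**: spread (max − min) of the 90 %-repolarization
  times of epi/mid/endo cells under an identical protocol.

Default pacing (from the models' source figure protocols): atrial 1 Hz with
15 µA/µF × 6 ms stimuli; ventricular 1 Hz with 52 µA/µF × 1 ms; Purkinje
2.5 Hz with 52 µA/µF × 1 ms.

## Fiber and conduction velocity

A fiber is n identical cells (default 100) coupled by a discrete Laplacian
on V with sealed ends (intercellular conductance g = 17 mS/µF atrial and
Purkinje, 7 mS/µF ventricular); the first 3 cells are stimulated at twice
the family's pacing amplitude (measured to be ≈ 2× diastolic threshold).
Activation time per cell is the time of maximal dV/dt of the measured
beat; CV is read across the interior 20–80 % span.

Pipeline per condition: pace a single cell to its limit cycle (10 beats),
seed all fiber cells with that state, run conditioning fiber beats (1 for
the quiescent atrial/ventricular families; 10 for the self-oscillatory
Purkinje fiber, which needs to entrain to the 2.5 Hz drive), then measure
the next beat.

The discrete cable has no intrinsic length scale, so the physical cell
length is calibrated **once per family** so that the wild-type, drug-free
fiber conducts at the family's reference velocity (55.07 / 49.91 / 67.68
cm/s for atrial / ventricular / Purkinje), then held fixed across all
genotype and drug conditions.  Every non-WT-control velocity is therefore a
prediction, not a fit.

## Problem-size presets

Two schedules are exposed (`RunConfig.schedule`): `paper` (100-cell fibers,
10 stabilization beats — the full protocol) and `scaled` (60-cell fibers,
4–6 stabilization beats) used by the test suite and quick demos.  The
scaled sizes were chosen for runtime only; all directional results below
hold at both sizes.

## Results summary and limitations

Reproduced (see `tests/test_acceptance.py`): the Purkinje ectopy phenotype
and its suppression by E3G and by fast pacing; the availability/clamp
ratio pattern across holdings; all E3G AP-feature directions including
decreased transmural dispersion; all excitation-threshold orderings; the
R222Q inactivation-shift ablation flipping the Purkinje CV deficit into an
increase; and the qualitative CV grid — E3G slows conduction everywhere,
I141V speeds it everywhere, R222Q slows the Purkinje fiber and its
combination with E3G produces outright conduction block.

Known quantitative deviations (documented, deliberately not tuned):

* The Purkinje fiber under E3G slows less here (≈ −14 %) than the
  reference values (≈ −45 %), so the WT+E3G and I141V+E3G Purkinje
  velocities sit above the ±15 % band.
* The atrial and ventricular R222Q+E3G velocities slow *more* here than
  the reference (compounded h∞ shifts depress availability strongly at
  the resting potentials of our formulations).
* Ventricular R222Q lands ~2 % below WT where the reference puts it
  slightly above.  No single sign convention for the R222Q h∞ shift can
  reproduce the reference pattern in all three fiber types at once; the
  convention used here is the one that also yields the Purkinje deficit,
  the ablation flip and the ectopy phenotype.
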