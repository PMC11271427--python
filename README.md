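# bionicgait

Computational core of a continuously neurally controlled bionic ankle and
of the gait study built around it, exercised end to end on synthetic
cohort data.

People with below-knee amputation who receive an agonist–antagonist
myoneural interface (AMI) — residual tibialis anterior (TA) and lateral
gastrocnemius (GAS) surgically coupled so one muscle's contraction
stretches the other — regain proprioceptive muscle afferents that a
standard amputation removes. This package implements, in Python, the
pipeline such a study needs:

* **EMG conditioning** (`bionicgait.emg`): order-198 linear-phase FIR
  band-pass (stop 0–60 Hz and >360 Hz, pass 90–330 Hz at 2 kHz), optional
  drift-robust cumulative-histogram rank filter, 200 ms RMS envelope,
  min/max normalization and bilinear activation dynamics.
* **Neural decoding** (`bionicgait.decoder`): subject calibration maps
  maximal phantom dorsiflexion/plantar flexion activation patterns onto
  the device range of motion (+10°/−20°), producing the equilibrium angle

  θ_ref = LP₆Hz( clip(w_TA·a_TA − w_GAS·a_GAS) )

  (critically damped second-order low-pass, 6 Hz) and the impedance level
  μ_Z = clip((w_TA·a_TA + w_GAS·a_GAS)/N_dir, 0, 1) with per-direction
  normalizers.
* **Impedance control** (`bionicgait.controller`): commanded torque

  τ = μ_Z · (δ/δ_max) · τ_bio(θ, θ̇) · sign(δ) + τ_passive(θ) − 0.45·(θ−θ_ref) − 0.02·θ̇

  where δ = θ_ref − θ, τ_bio is a Hill-type force–length × force–velocity
  maximal-torque surface per direction, τ_passive an exponential
  ligament/capsule restoring torque, and the total saturates at 162 Nm.
* **Ankle plant** (`bionicgait.plant`): semi-implicit Euler single-inertia
  ankle with hard stops and a percent-cycle ground-load schedule, closing
  the loop for full gait-cycle simulation.
* **Spindle afferents** (`bionicgait.spindle`): type II (secondary
  ending) firing from fascicle strain, strain rate and EMG envelope;
  steady-state mean over the 25–75% cycle window; the agonist–antagonist
  afferent statistic (antagonist lengthening minus agonist shortening
  rate, averaged over the two phantom movements, Imp/s).
* **Gait metrics** (`bionicgait.gait`): cycle normalization to a 1001-point
  grid, gait-event excursions (HS/LR/PO/FC, WA/FCo/PU), peak power, net
  work, torque–angle work loops (counterclockwise ⇔ net positive work),
  range of motion, lower-extremity kinematic (LEK) symmetry = 100 − SI,
  obstacle swing-kinematics delta and recovery-step propulsion.
* **Cohort statistics** (`bionicgait.cohort`): percent increases and
  restoration ratios, Pearson r with Fisher-z CI and OLS slope CI, PC1
  composite functionality (z-scored metrics, stair-descent signs
  flipped), and Shapiro–Wilk-gated t / Mann–Whitney comparisons with
  Holm–Šidák correction.
* **Synthetic data** (`bionicgait.synth`): seeded generators for raw EMG
  (pass-band comb carrier amplitude-modulated by the commanded
  activation, so the envelope chain round-trips it), phantom DF/PF cycles
  whose downstream afferent statistic is calibrated to a target level,
  parametric gait trials spanning level/slope/stair/obstacle conditions
  with a single "biomimeticness" dial, and cohort tables with known
  afferent–function slopes for parameter-recovery testing.

## Worked example

```python
from bionicgait import synth, pipeline

subjects = synth.generate_cohort_trials(n_per_group=7, noise_sd=0.02, seed=1)
aff = pipeline.afferent_table(subjects)
print(aff.groupby("group")["afferent_estimated"].mean().round(2))
```

```
group
AMI    10.18
CTL    -0.22
```

The AMI archetype sits near 10.5 Imp/s of agonist–antagonist afferent
signalling and the decoupled CTL archetype near zero. Continuing,

```python
table = pipeline.cohort_table(subjects, afferents=aff)
rep = pipeline.cohort_report(table)
print(round(rep["correlations"]["pc1"]["r"], 2))
print(rep["derived_statistics"]["max_speed_increase_pct"]["rounded"])
```

prints `1.0` (the PC1 composite functionality score tracks the afferent
level across the synthetic cohort) and `41` (the percent increase in
maximum walking speed recomputed from the published cohort means, 1.78
vs 1.26 m/s). The closed-loop controller demo
(`analysis/05_controller_analysis.py`) prints the zero-activity
restoring stiffness `0.4500 Nm/deg`, the sweep-wide torque bound
`162.0 Nm`, and a coordination sweep in which the simulated work loop
flips from clockwise/dissipative (−0.060 J/kg) to counterclockwise with
+0.339 J/kg of net positive work per stride.

The numbered scripts under `analysis/` run the study pipeline in order:
simulate the cohort, estimate afferents, compute gait metrics, run the
cohort statistics, and analyse the controller; outputs land in
`results/`.

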