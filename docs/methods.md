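# Methods

This note documents the models, parameter choices and numerical
decisions behind `bionicgait`, and what the synthetic study conditions
do and do not establish about real data.

## EMG conditioning

Raw surface EMG from the residual tibialis anterior (TA, dorsiflexor)
and lateral gastrocnemius (GAS, plantar flexor) is band-passed with a
linear-phase FIR filter of order 198 (199 taps) at the 2 kHz recording
rate: stop bands 0–60 Hz and above 360 Hz, pass band 90–330 Hz. The
filter is designed by the equiripple (Parks–McClellan) method with the
stop bands weighted 100:1 over the pass band, which achieves roughly
−80 dB stop-band floors at the cost of ±0.14 dB pass-band ripple; an
85 dB floor is the design target but is marginally out of reach at this
order and rate, so the design routine verifies the response at relaxed
levels (≤ −60 dB at 45 and 400 Hz, ≥ −3 dB across 110–310 Hz) and fails
loudly if they are violated. For offline analysis the filter is applied
with its constant group delay (99 samples) compensated.

The envelope is the 200 ms sliding RMS of the rectified signal
(reflect padding, to avoid startup bias in short calibration records),
min/max-normalized with calibration constants; when none are supplied
they are taken from the RMS trace away from the filter edge transients.
Muscle activation follows bilinear first-order dynamics — the rate
constant is τ_act = 10 ms while excitation exceeds activation and
τ_deact = 40 ms otherwise (physiological defaults, configurable) — with
an exact exponential per-sample update, so the steady state under
constant excitation equals the excitation and the output stays in [0, 1].

A cumulative-histogram rank filter is provided for the socket-interface
robustness role: each sample is replaced by its empirical-CDF rank,
within a 5 s trailing window, of the rectified amplitude quantized into
128 bins (pandas rolling rank, tie groups at their top rank so monotone
inputs map to monotone ranks). Ranks are invariant to slow baseline
drift by construction. Because the transform deliberately discards
absolute amplitude over stationary segments, it is **off by default** in
the envelope chain used for decoding and afferent estimation — amplitude
recovery there is a tested contract — and can be enabled with
`histogram_filter=True` where liner–socket drift robustness matters.

## Decoding and impedance control

Calibration solves the 2×2 linear system mapping the plateau-mean
activation pairs of the maximal phantom dorsiflexion (DF) and plantar
flexion (PF) trials onto the device range of motion, +10° DF / −20° PF;
plateaus are the samples at ≥ 90% of the trial maximum and must span
0.5 s. Indistinct (co-activated) trials make the system singular and
calibration fails with a diagnostic. The μ_Z normalizers are the
plateau-mean weighted sums per direction, so replaying a calibration
trial yields μ_Z = 1 exactly.

The equilibrium-angle command is the weighted activation difference,
clipped to the range of motion **before** low-pass filtering (the
filtered command then respects actuator limits without post-filter
discontinuities), smoothed by a critically damped second-order low-pass
with 6 Hz cut-off. The discretization is bilinear with the cut-off
prewarped, so the half-amplitude point of the critically damped pair
lands exactly at 6 Hz and the step response is monotone.

Torque command: with angle error δ = θ_ref − θ, the active torque is
μ_Z · (|δ|/δ_max) · τ_bio, where δ_max is the remaining range of motion
toward the commanded direction — this normalization makes μ_Z = 1 with
maximal δ land exactly on the biological bound. τ_bio is a Hill-type
surface per direction: a Gaussian force–length factor over angle
(plantar flexors peak 180 Nm near +5°, width 30°; dorsiflexors 45 Nm
near −10°, width 25°), multiplied by a force–velocity factor that is a
Hill hyperbola in the shortening velocity (maximum 500 deg/s, curvature
0.25) and rises smoothly to a 1.4× eccentric plateau during lengthening.
All parameters are configuration with these documented defaults; the
curve family is standard muscle mechanics, the values chosen once for a
physiological ankle. Passive ligament/capsule torque is zero inside a
neutral zone (−15° to +5°) and grows exponentially (scale 2°, 1.5 Nm)
toward the stops, opposing displacement. Virtual stiffness
0.45 Nm/deg acts on (θ − θ_ref) and damping 0.02 Nm·s/deg on velocity,
so the rest closed loop (zero activity, θ_ref = 0) is a stable
mass–spring–damper. The summed command saturates at ±162 Nm; the
passive-structure term is included inside the saturation. Degrees and Nm
are used throughout (the virtual gains are per-degree); radians appear
only in power and work-loop integrals.

## Ankle plant

A single rotational inertia (default 0.05 kg·m², a ~2.4 kg ankle–foot
device with ~14 cm gyration radius) integrates the commanded plus
external torque by semi-implicit Euler at 1 kHz — stable with the stiff
virtual-impedance terms — with hard stops at the range-of-motion ends
(angle clamped, velocity zeroed) and a divergence guard on velocity.
Ground contact is not simulated: an external torque profile in Nm/kg of
body mass is replayed against percent gait cycle, which exercises
stance/swing asymmetry at desk scale. The closed-loop level-walking
demonstration feeds synthetic TA/GAS EMG (plantar-flexor burst through
stance peaking before push-off, dorsiflexor bursts at heel strike and
through swing) through the full conditioning/decoding/control stack
against a half-sine stance load of 1.4 Nm/kg; mistimed activation
(bursts swapped between stance and swing) degrades the work loop from
counterclockwise/propulsive to clockwise/dissipative.

## Spindle afferents

Secondary (type II) muscle spindle endings are predominantly length
sensitive. Firing is modelled additively:

rate = max(0, baseline + k_len·strain + k_vel·sign(v)·|v|^p + k_act·env)

with strain the fascicle strain (positive = lengthening, fraction of
optimal fascicle length), v its rate (central differences after 5-point
smoothing — ultrasound-derived strains are noisy), and env the
normalized EMG envelope. Defaults: baseline 10 Imp/s, k_len
333 Imp/s per unit strain, k_vel 13.5 with exponent 0.5, k_act 5 —
anchored once so a full-range intact-limb excursion (~0.15 plateau
strain) yields ≈ 60 Imp/s of steady antagonist firing, the published
intact-limb scale. The steady-state value is the mean over the 25–75%
window of the 101-point movement-cycle grid. The cohort statistic is
the antagonist-minus-agonist steady rate **averaged** over the DF and PF
movements (averaging rather than summing was an open choice; averaging
keeps the statistic on the per-movement scale the intact-limb anchor
uses). It is near zero for mechanically decoupled residuals and
negative when afferents rise paradoxically during agonist action.

## Gait metrics

Cycles live on a fixed 1001-point 0–100% grid (0.1% resolution); cycles
shorter than 0.2 s are rejected as spurious. Power is torque times
angular velocity (rad/s), mass-normalized; net work is the trapezoidal
time-integral of power over a percent-cycle window. The work-loop area
is the line integral of torque over angle, which equals the
counterclockwise-signed shoelace area in the conventional work-loop
plotting plane (torque plotted plantar-flexion-positive); net work and
loop area are computed by independent routes and agree to < 0.5% on all
synthetic trials — a standing cross-module oracle. Event excursions
follow landmark definitions verbatim: heel strike is the PF excursion
from initial contact to the first local PF maximum in stance, loading
response the DF excursion from there to the stance DF maximum, push-off
the PF excursion from the stance DF maximum to end of stance, foot
clearance the DF excursion from end of stance to end of swing; stair
descent uses weight acceptance (contact to stance DF maximum) and
forward continuance (stance DF maximum to end of swing), stair ascent
weight acceptance, pull-up and foot clearance. Local extrema use strict
inequality with plateau-midpoint tie breaking; a missing landmark flags
the event absent rather than fabricating it. Stance end is supplied by
the generator/load schedule, never inferred silently.

The symmetry index is a dialect choice (the literature admits variants):
per joint, SI = 100 × ∫|x_contra − x_ipsi| over the cycle, normalized by
the mean cycle-integrated absolute excursion of the two limbs, averaged
over ankle, knee and hip, with angles in degrees; LEK symmetry =
100 − SI. This form is symmetric in the limbs, equals 100% exactly at
identity, and decreases monotonically with offset.

## Synthetic study conditions

The generator's defaults are the study conditions and were fixed once.

*Raw EMG* is a deterministic comb carrier — cosines at 5 Hz spacing over
95–325 Hz with seeded phases, unit RMS — amplitude-modulated by the
commanded activation profile, plus white noise and 50 Hz mains hum
scaled by `noise_sd` as out-of-band interference. Because every
difference frequency in the comb is a multiple of 5 Hz, the RMS over any
200 ms window is analytically constant, so the envelope chain recovers
the commanded profile almost exactly (boxcar round-trip error < 0.05
away from filter edges — a tested contract). Real EMG is a stochastic
interference process; this carrier reproduces its band occupancy and
amplitude modulation, not its amplitude statistics.

*Phantom movements* use a smooth ramp–plateau–ramp strain shape with the
25–75% steady state. The coupling amplitude (antagonist +a, agonist
−0.8a) is solved by root finding **through the spindle model itself** so
the downstream agonist–antagonist statistic equals the archetype's
target level; negative targets produce the paradoxical
agonist-lengthening pattern of decoupled residuals. CTL archetypes add
triple cycle-to-cycle amplitude jitter, per-cycle phase wander and
independent additive strain noise (inconsistent residual mechanics).

*Gait trials* come from sum-of-Gaussian bump templates on the ankle
angle per condition, and a torque family with three parts: a
conservative spring (0.02 Nm/kg/deg, zero net work), a propulsive
push-off bump, and viscous damping. Bump amplitude and damping are
linear in the biomimeticness scalar b ∈ [0, 1]; the four coefficients
were solved exactly (once) so that level walking at maximum effort gives
peak power 0.68 W/kg and net work −0.049 J/kg at b = 0 and 1.95 W/kg
and +0.174 J/kg at b = 1 — the two cohorts' published operating points —
which makes net work strictly monotone in b and flips the work loop
from clockwise to counterclockwise near b ≈ 0.5. Stair templates use
stance damping (descent, absorption) and a pull-up bump (ascent)
calibrated the same way; the obstacle condition adds a swing
dorsiflexion bump of (5.6·b − 0.9)°, spanning the published +4.14°
(AMI) to −0.45° (CTL) swing-modification range. Contralateral
kinematics are fixed normative ankle/knee/hip templates; ipsilateral
trajectories are scaled by 0.90 − 0.25(1 − b) and offset by 4(1 − b)°,
so LEK symmetry falls from ≈ 90% toward ≈ 55% as b → 0. Afferent level
maps to b via b = clip((afferent + 1.5)/13.5, 0, 1), placing the
non-biomimetic stratum (≈ −1.3 Imp/s) at b ≈ 0 and the high stratum
(≈ 12 Imp/s) at b ≈ 1. Condition speeds interpolate the published
cohort speeds (e.g. maximum level walking 1.26 → 1.78 m/s).

*Cohorts*: `generate_cohort` draws afferents uniformly from the lower
(CTL) and upper (AMI) 40% of a configured range and builds metrics from
a known linear relation plus Gaussian noise — the parameter-recovery
bench for the correlation layer. `generate_cohort_trials` draws
afferents near the published cohort means (AMI 10.5 ± 2.3, CTL
0.09 ± 1.8 Imp/s) and emits full per-subject trials for the end-to-end
pipeline.

Passing tests on these conditions show that the pipeline's arithmetic,
contracts and qualitative mechanisms are right; they do not validate
the waveform families against human biomechanics (no forward-dynamics
model, no contact mechanics, no soft-tissue or electrode artifacts).

## Statistics

Pearson r carries a Fisher-z 95% CI (valid for bivariate-normal-ish
data at these n), the OLS slope a t-based 95% CI. PCA acts on the
correlation matrix (columns z-scored) with stair-descent peak power and
net work negated first, and PC1 oriented so the peak-power loading is
positive. Group comparisons gate on Shapiro–Wilk at α = 0.05 in both
groups, choosing a two-sided t-test (paired or unpaired) or a
Mann–Whitney U-test, and apply Holm–Šidák step-down correction across a
declared family (identity for one comparison); under a simulated null
(n = 7 per group) the realized type-I rate stays within [0.035, 0.065]
at α = 0.05 across 2000 replicates. Reported percentages round half
away from zero to integers, which reproduces every published derived
percentage from its printed inputs (e.g. 186.8 → 187).

## Problem sizes

The test suite and acceptance script run at desk scale by choice: 14
synthetic subjects × 9 conditions, 10 phantom cycles per movement,
100-cycle oracle sweeps, 200-replicate slope-recovery and
2000-replicate type-I Monte Carlo runs, and controller sweeps of ~8×10⁴
grid points. Everything is seeded; identical spec + seed reproduces
identical bytes.

## Known limitations

* The envelope min/max normalization is per record when no calibration
  constants are given; real sessions calibrate once and hold constants.
* The closed-loop plant is one degree of freedom with replayed ground
  load; no balance, contralateral dynamics or contact.
* The spindle model omits primary (Ia) endings and fusimotor drive; its
  coefficients are anchored, not fitted.
* Holm–Šidák families must be declared by the caller; no automatic
  family inference.
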