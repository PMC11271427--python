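"""Synthetic study-condition generator.

Everything the real study measured — raw EMG, phantom-movement fascicle
strain, gait kinematics/kinetics and cohort tables — is emulated here with
controllable archetype parameters and seeds, so that every downstream
stage (EMG pipeline, decoder, controller, spindle model, gait metrics,
cohort statistics) is testable without any recorded data.

Two archetypes mirror the two cohorts.  The AMI archetype has surgically
coupled residual muscles: during a phantom movement the agonist shortens
while the antagonist lengthens in anti-phase, giving a large positive
agonist-antagonist afferent.  The CTL archetype is mechanically
decoupled: strains are small, inconsistent cycle to cycle and can move
with the agonist, giving near-zero or negative afferent values.  A single
"gait biomimeticness" scalar in [0, 1] scales push-off work, gait-event
amplitudes and inter-limb symmetry between the non-biomimetic and
biomimetic extremes.

The raw-EMG carrier is a deterministic 5 Hz comb of pass-band sinusoids
with seeded phases: its 200 ms windowed RMS is analytically constant, so
amplitude modulation by an activation profile round-trips through the
envelope chain almost exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .emg import EMG_RATE, EmgRecording
from .gait import GRID, GaitCycle
from .spindle import (CYCLE_GRID, FascicleTrace, SpindleParams,
                      agonist_antagonist_afferent, estimate_afferents)

__all__ = [
    "CONDITIONS",
    "ArchetypeSpec",
    "SyntheticTrial",
    "PhantomCycleSet",
    "generate_emg",
    "generate_phantom_cycles",
    "generate_gait_trial",
    "generate_cohort",
    "generate_cohort_trials",
    "biomimeticness_from_afferent",
    "trial_to_gait_cycle",
]

CONDITIONS = (
    "level_slow", "level_moderate", "level_max",
    "slope_up", "slope_down", "stair_up", "stair_down",
    "obstacle", "unperturbed_baseline",
)

KINEMATICS_RATE = 1000.0  # Hz, telemetry rate of the joint sensors


@dataclass
class ArchetypeSpec:
    """Archetype parameters for one synthetic subject."""

    group_label: str                  # "AMI" | "CTL"
    afferent_level: float             # target agonist-antagonist afferent, Imp/s
    gait_biomimeticness: float        # in [0, 1]
    noise_sd: float = 0.0             # relative additive noise amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_label not in ("AMI", "CTL"):
            raise ValueError(f"group_label must be AMI or CTL, got {self.group_label!r}")
        if not np.isfinite(self.afferent_level):
            raise ValueError("afferent_level must be finite")
        if not 0.0 <= self.gait_biomimeticness <= 1.0:
            raise ValueError("gait_biomimeticness must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticTrial:
    """One synthetic gait trial on the fixed cycle grid."""

    condition: str
    speed: float                      # m/s
    angle: np.ndarray                 # deg on GRID (ipsilateral ankle)
    torque: np.ndarray                # Nm/kg on GRID
    kinematics_ipsi: dict             # joint -> deg trace on GRID
    kinematics_contra: dict
    fascicle: dict                    # muscle -> FascicleTrace (101-pt grid)
    emg: EmgRecording
    stance_end_pct: float
    cycle_duration_s: float
    body_mass: float = 75.0
    spec: ArchetypeSpec | None = None


@dataclass
class PhantomCycleSet:
    """Paired TA/GAS strain and EMG for maximum phantom DF and PF cycles.

    ``strain[movement][muscle]`` has shape (n_cycles, 101);
    ``mean_strain[movement][muscle]`` is the cycle-averaged FascicleTrace;
    ``emg[movement]`` covers all cycles back to back;
    ``envelope_profile[movement][muscle]`` is the commanded activation on
    the cycle grid (what the EMG envelope should recover).
    """

    n_cycles: int
    cycle_duration_s: float
    strain: dict = field(default_factory=dict)
    mean_strain: dict = field(default_factory=dict)
    emg: dict = field(default_factory=dict)
    envelope_profile: dict = field(default_factory=dict)
    coupling_amplitude: float = 0.0


def biomimeticness_from_afferent(afferent: float) -> float:
    """Map an agonist-antagonist afferent level (Imp/s) to the gait
    biomimeticness scalar: the non-biomimetic stratum (~-1.3 Imp/s) maps
    near 0, the high stratum (~12 Imp/s) near 1."""
    return float(np.clip((afferent + 1.5) / 13.5, 0.0, 1.0))


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    z = (x - center) / width
    return np.exp(-z * z)


def comb_carrier(n: int, sample_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS pass-band carrier: 5 Hz comb over 95-325 Hz with seeded
    phases.  All difference frequencies are multiples of 5 Hz, so the RMS
    over any 200 ms window is exactly constant."""
    t = np.arange(n) / sample_rate
    freqs = np.arange(95.0, 326.0, 5.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    c = np.zeros(n)
    for f, p in zip(freqs, phases):
        c += np.cos(2.0 * np.pi * f * t + p)
    return c / np.sqrt(np.mean(c * c))


def generate_emg(profile, sample_rate: float = EMG_RATE,
                 noise_sd: float = 0.0, seed: int = 0) -> EmgRecording:
    """Raw EMG whose envelope recovers the commanded activation profile.

    ``profile`` maps channel name to an activation waveform in [0, 1] (a
    bare array becomes channel ``"emg"``).  Each channel is the profile
    amplitude-modulating an independent pass-band comb carrier, plus
    ``noise_sd`` times (white noise + 50 Hz mains hum) as out-of-band
    interference exercising the filter stop bands.
    """
    if not isinstance(profile, dict):
        profile = {"emg": profile}
    if sample_rate < EMG_RATE:
        raise ValueError(f"sample_rate must be >= {EMG_RATE:.0f} Hz")
    rng = np.random.default_rng(seed)
    channels = {}
    for name, p in profile.items():
        p = np.asarray(p, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError(f"profile for channel {name!r} is not finite")
        if p.min() < -1e-12 or p.max() > 1.0 + 1e-12:
            raise ValueError(f"profile for channel {name!r} must lie in [0, 1]")
        n = p.size
        x = p * comb_carrier(n, sample_rate, rng)
        if noise_sd > 0:
            t = np.arange(n) / sample_rate
            hum = np.sin(2.0 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
            x = x + noise_sd * (rng.standard_normal(n) + 0.5 * hum)
        channels[name] = x
    return EmgRecording(sample_rate, channels)


def _phantom_shape(pct: np.ndarray) -> np.ndarray:
    """Smooth ramp-plateau-ramp movement shape: 0 at the cycle ends,
    1 across the 25-75% steady state."""
    up = np.clip((pct - 5.0) / 20.0, 0.0, 1.0)
    down = np.clip((95.0 - pct) / 20.0, 0.0, 1.0)
    s = np.minimum(up, down)
    return s * s * (3.0 - 2.0 * s)


def _phantom_statistic(a: float, params: SpindleParams) -> float:
    """Agonist-antagonist afferent produced by coupling amplitude ``a``
    (antagonist plateau strain +a, agonist strain -0.8a) through the
    spindle model.  Each channel's EMG envelope is min/max-normalized per
    record, so both roles see a unit-peak envelope of the movement shape.
    """
    base = _phantom_shape(CYCLE_GRID)
    ant = estimate_afferents(FascicleTrace(a * base, "ant"), base,
                             "antagonist_lengthening", params=params)
    ag = estimate_afferents(FascicleTrace(-0.8 * a * base, "ag"), base,
                            "agonist_shortening", params=params)
    # DF and PF movements are symmetric by construction
    return agonist_antagonist_afferent(ag, ant, ag, ant)


def generate_phantom_cycles(spec: ArchetypeSpec, n_cycles: int = 10,
                            spindle_params: SpindleParams | None = None,
                            cycle_duration_s: float = 2.0,
                            sample_rate: float = EMG_RATE) -> PhantomCycleSet:
    """Paired TA/GAS fascicle strain and EMG for ``n_cycles`` maximum
    phantom DF and PF movements.

    The coupling amplitude is solved (through the spindle model with its
    configured coefficients) so that the downstream agonist-antagonist
    afferent statistic matches ``spec.afferent_level``; negative targets
    yield the paradoxical agonist-lengthening pattern of the decoupled
    archetype.  CTL archetypes add triple the cycle-to-cycle strain
    variance and a higher unintended co-activation level.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    params = spindle_params or SpindleParams()
    is_ami = spec.group_label == "AMI"
    coact = 0.05 if is_ami else 0.25

    def f(a: float) -> float:
        return _phantom_statistic(a, params) - spec.afferent_level

    a = brentq(f, -0.4, 0.8, xtol=1e-6)
    rng = np.random.default_rng(spec.seed)
    base = _phantom_shape(CYCLE_GRID)
    var_mult = 1.0 if is_ami else 3.0
    out = PhantomCycleSet(n_cycles, cycle_duration_s, coupling_amplitude=a)
    n_cycle_samp = int(round(cycle_duration_s * sample_rate))
    for movement in ("df", "pf"):
        agonist = "ta" if movement == "df" else "gas"
        antagonist = "gas" if movement == "df" else "ta"
        jitter = 1.0 + spec.noise_sd * var_mult * rng.standard_normal(n_cycles)
        strain = {
            antagonist: np.outer(jitter, a * base),
            agonist: np.outer(jitter, -0.8 * a * base),
        }
        if var_mult > 1.0:  # decoupled residuals drift independently
            for m in strain:
                strain[m] = strain[m] + (spec.noise_sd * (var_mult - 1.0)
                                         * 0.015
                                         * rng.standard_normal((n_cycles,
                                                                base.size)))
        if not is_ami:  # inconsistent residual mechanics: per-cycle phase wander
            shifts = (spec.noise_sd * 20.0 * rng.standard_normal(n_cycles))
            for m in strain:
                for c in range(n_cycles):
                    strain[m][c] = np.roll(strain[m][c], int(round(shifts[c])))
        out.strain[movement] = strain
        out.mean_strain[movement] = {
            m: FascicleTrace(strain[m].mean(axis=0), m, n_cycles)
            for m in strain
        }
        prof_cycle = {agonist: 0.9 * base, antagonist: coact * base}
        out.envelope_profile[movement] = prof_cycle
        t_cycle = np.arange(n_cycle_samp) / sample_rate
        pct = t_cycle / cycle_duration_s * 100.0
        prof_stream = {
            m: np.tile(np.interp(pct, CYCLE_GRID, prof_cycle[m]), n_cycles)
            for m in prof_cycle
        }
        out.emg[movement] = generate_emg(prof_stream, sample_rate,
                                         spec.noise_sd,
                                         seed=spec.seed + (0 if movement == "df" else 1))
    return out


# ---------------------------------------------------------------------------
# gait waveform families
# ---------------------------------------------------------------------------

#: condition -> (stance_end_pct, cycle_duration_s, speed intercept, speed slope in b)
_CONDITION_TABLE = {
    "level_slow": (62.0, 1.30, 0.97, 0.02),
    "level_moderate": (62.0, 1.15, 1.24, 0.02),
    "level_max": (62.0, 1.00, 1.26, 0.52),
    "slope_up": (62.0, 1.20, 0.90, 0.40),
    "slope_down": (62.0, 1.20, 0.95, 0.35),
    "stair_up": (65.0, 1.40, 0.50, 0.25),
    "stair_down": (65.0, 1.40, 0.55, 0.25),
    "obstacle": (62.0, 1.15, 0.60, 0.36),
    "unperturbed_baseline": (62.0, 1.15, 0.60, 0.36),
}


def _level_angle(pct: np.ndarray, b: float) -> np.ndarray:
    return (-4.0 * _gauss(pct, 8.0, 3.5)
            + (6.0 + 6.0 * b) * _gauss(pct, 42.0, 10.0)
            - (12.0 + 8.0 * b) * _gauss(pct, 63.0, 4.5)
            + (2.0 + 3.0 * b) * _gauss(pct, 78.0, 7.0))


def _angle_template(condition: str, b: float, pct: np.ndarray) -> np.ndarray:
    if condition in ("level_slow", "level_moderate", "level_max",
                     "unperturbed_baseline"):
        return _level_angle(pct, b)
    if condition == "obstacle":
        return _level_angle(pct, b) + (5.6 * b - 0.9) * _gauss(pct, 78.0, 6.0)
    if condition == "slope_up":
        return _level_angle(pct, b) + 2.5 * _gauss(pct, 35.0, 20.0)
    if condition == "slope_down":
        return _level_angle(pct, b) - 2.0 * _gauss(pct, 35.0, 20.0)
    if condition == "stair_down":
        return (-10.0 + (20.0 + 6.0 * b) * _gauss(pct, 40.0, 13.0)
                - 4.0 * _gauss(pct, 82.0, 8.0))
    if condition == "stair_up":
        return ((8.0 + 4.0 * b) * _gauss(pct, 30.0, 12.0)
                - (14.0 + 6.0 * b) * _gauss(pct, 67.0, 6.0)
                + (4.0 + 3.0 * b) * _gauss(pct, 88.0, 6.0))
    raise ValueError(
        f"unknown condition {condition!r}; valid conditions: {CONDITIONS}")


# torque family coefficients (Nm/kg); calibrated once against the cohort
# magnitudes the study conditions define (see docs/methods.md)
_SPRING_K = 0.02             # Nm/kg per deg, conservative component
_PROP_AMP = (0.5549, -0.0333)  # push-off bump: intercept, slope in b
_PROP_WIDTH = 8.0            # percent-cycle width of the push-off bump
_DAMP = (1.587e-3, 1.92e-5)  # damping: (1-b) slope, intercept [Nm/kg per deg/s]
_STAIR_DAMP = 1.85e-3        # stance damping scale for stair descent
_PU_AMP = (0.2098, 0.9037)   # stair-ascent pull-up bump: intercept, slope in b
_PU_DAMP = 2.0e-4            # stair-ascent damping [Nm/kg per deg/s]


def _torque_template(condition: str, b: float, pct: np.ndarray,
                     angle: np.ndarray, duration_s: float) -> np.ndarray:
    dt = duration_s / (pct.size - 1)
    omega = np.gradient(angle, dt)  # deg/s
    spring = -_SPRING_K * (angle - angle[0])
    if condition == "stair_down":
        gate = (pct <= 65.0).astype(float)
        damp = -_STAIR_DAMP * (0.35 + 0.65 * b) * omega * gate
        return spring + damp
    if condition == "stair_up":
        prop = -(_PU_AMP[0] + _PU_AMP[1] * b) * _gauss(pct, 58.0, 6.0)
        damp = -_PU_DAMP * omega
        return spring + prop + damp
    scale = {"slope_up": 1.15, "slope_down": 0.70,
             "obstacle": 0.55, "unperturbed_baseline": 0.55,
             "level_slow": 0.80, "level_moderate": 0.92}.get(condition, 1.0)
    prop = -scale * (_PROP_AMP[0] + _PROP_AMP[1] * b) * _gauss(pct, 55.0, _PROP_WIDTH)
    damp = -(_DAMP[1] + _DAMP[0] * (1.0 - b)) * omega
    return spring + prop + damp


def _contra_templates(pct: np.ndarray) -> dict:
    """Fixed normative contralateral joint trajectories (deg)."""
    return {
        "ankle": _level_angle(pct, 1.0),
        "knee": 6.0 * _gauss(pct, 15.0, 8.0) + 60.0 * _gauss(pct, 73.0, 9.0),
        "hip": 20.0 * np.cos(2.0 * np.pi * pct / 100.0) + 5.0,
    }


def generate_gait_trial(spec: ArchetypeSpec, condition: str,
                        body_mass: float = 75.0) -> SyntheticTrial:
    """One synthetic gait trial for the archetype and condition.

    At biomimeticness 1 the level-walking torque-angle loop runs
    counterclockwise with positive net work (propulsive push-off); at 0
    the dissipative damping term dominates and the loop runs clockwise
    with non-positive net work.  Contralateral kinematics come from a
    fixed normative template, and the ipsilateral trajectories are scaled
    and offset away from it as biomimeticness falls, so LEK symmetry
    degrades with the archetype.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; valid conditions: {CONDITIONS}")
    b = spec.gait_biomimeticness
    stance_end, duration, v0, v1 = _CONDITION_TABLE[condition]
    rng = np.random.default_rng(spec.seed + zlib.crc32(condition.encode()) % 10000)
    angle = _angle_template(condition, b, GRID)
    torque = _torque_template(condition, b, GRID, angle, duration)
    if spec.noise_sd > 0:
        angle = angle + spec.noise_sd * 0.5 * rng.standard_normal(GRID.size)
        torque = torque + spec.noise_sd * 0.02 * rng.standard_normal(GRID.size)
    speed = v0 + v1 * b + spec.noise_sd * 0.05 * rng.standard_normal()

    contra = _contra_templates(GRID)
    s = 0.90 - 0.25 * (1.0 - b)
    off = 4.0 * (1.0 - b)
    ipsi = {j: s * x + off * _gauss(GRID, 60.0, 15.0) for j, x in contra.items()}
    ipsi["ankle"] = angle  # the bionic side is the generated ankle itself

    strain_gas = b * (0.04 * _gauss(CYCLE_GRID, 40.0, 15.0)
                      - 0.05 * _gauss(CYCLE_GRID, 60.0, 8.0))
    strain_ta = b * (0.05 * _gauss(CYCLE_GRID, 75.0, 10.0)
                     - 0.02 * _gauss(CYCLE_GRID, 30.0, 20.0))
    fascicle = {"ta": FascicleTrace(strain_ta, "ta"),
                "gas": FascicleTrace(strain_gas, "gas")}

    act = (0.3 + 0.7 * b)
    prof_pct = {
        "ta": np.clip(0.55 * _gauss(GRID, 5.0, 4.0)
                      + 0.80 * act * _gauss(GRID, 75.0, 12.0), 0, 1),
        "gas": np.clip(0.90 * act * _gauss(GRID, 50.0, 12.0), 0, 1),
    }
    n_emg = int(round(duration * EMG_RATE))
    pct_emg = np.arange(n_emg) / n_emg * 100.0
    prof = {m: np.interp(pct_emg, GRID, prof_pct[m]) for m in prof_pct}
    emg = generate_emg(prof, EMG_RATE, spec.noise_sd, seed=spec.seed + 17)

    return SyntheticTrial(condition, float(speed), angle, torque,
                          ipsi, contra, fascicle, emg,
                          stance_end, duration, body_mass, spec)


def trial_to_gait_cycle(trial: SyntheticTrial) -> GaitCycle:
    """View a synthetic trial as a GaitCycle for the metrics layer."""
    return GaitCycle(trial.angle, trial.torque, trial.stance_end_pct,
                     trial.cycle_duration_s, trial.body_mass, trial.condition)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: default linear afferent -> metric relations (intercept, slope per Imp/s)
DEFAULT_SLOPE_SPEC = {
    "peak_power": (0.80, 0.095),     # W/kg
    "net_work": (-0.030, 0.019),     # J/kg
    "speed": (1.25, 0.044),          # m/s
    "lek_symmetry": (68.0, 1.40),    # %
}


def generate_cohort(n_per_group: int = 7,
                    afferent_range: tuple[float, float] = (-2.0, 12.0),
                    slope_spec: dict | None = None,
                    noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Cohort table with a configured linear afferent-function relation.

    Subjects' agonist-antagonist afferents are drawn uniformly: the CTL
    group from the lower 40% of ``afferent_range`` and the AMI group from
    the upper 40%, mirroring the study's strata.  Each functional metric
    is intercept + slope * afferent + N(0, noise * metric scale), so the
    configured slopes are recoverable by the correlation layer.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    lo, hi = afferent_range
    if not hi > lo:
        raise ValueError(f"degenerate afferent_range {afferent_range}")
    slope_spec = slope_spec if slope_spec is not None else DEFAULT_SLOPE_SPEC
    rng = np.random.default_rng(seed)
    aff_ctl = rng.uniform(lo, lo + 0.4 * (hi - lo), n_per_group)
    aff_ami = rng.uniform(hi - 0.4 * (hi - lo), hi, n_per_group)
    rows = []
    for g, affs in (("CTL", aff_ctl), ("AMI", aff_ami)):
        for k, a in enumerate(affs):
            row = {"subject": f"{g}{k + 1}", "group": g, "afferent": float(a)}
            for metric, (c0, m) in slope_spec.items():
                scale = abs(c0) + abs(m) * (hi - lo)
                row[metric] = c0 + m * a + noise * 0.05 * scale * rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort_trials(n_per_group: int = 7, noise_sd: float = 0.02,
                           seed: int = 0,
                           conditions: tuple[str, ...] = CONDITIONS) -> list[dict]:
    """Full synthetic subjects: archetype spec, phantom cycles and one
    gait trial per condition, for the end-to-end pipeline.

    AMI afferent levels are drawn near 10.5 Imp/s and CTL near 0.1 Imp/s
    (the cohort means), each subject's gait biomimeticness following its
    afferent level.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for g, mu, sd in (("AMI", 10.5, 2.3), ("CTL", 0.09, 1.8)):
        for k in range(n_per_group):
            aff = float(mu + sd * rng.standard_normal())
            spec = ArchetypeSpec(g, aff, biomimeticness_from_afferent(aff),
                                 noise_sd, int(rng.integers(0, 2**31 - 1)))
            trials = {c: generate_gait_trial(spec, c) for c in conditions}
            subjects.append({
                "subject": f"{g}{k + 1}", "group": g, "afferent": aff,
                "spec": spec, "trials": trials,
            })
    return subjects
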