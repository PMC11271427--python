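"""Ankle impedance controller with biological torque bounds.

The commanded torque combines three components:

* active torque — the decoded intent (mu_z, delta) scales the maximal
  biological ankle torque at the measured joint state, computed from
  Hill-type force-length and force-velocity characteristics per direction;
* passive-structure torque — restoring torque from ligaments/capsule,
  zero in a neutral zone and growing exponentially toward the ROM ends;
* virtual impedance — stiffness 0.45 Nm/deg about theta_ref and damping
  0.02 Nm·s/deg, guaranteeing stability under zero muscle activity.

The total is saturated at the device limit of 162 Nm.  Angles are in
degrees (DF positive), torques in Nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decoder import ROM_DF, ROM_PF

__all__ = [
    "TAU_MAX",
    "VIRTUAL_STIFFNESS",
    "VIRTUAL_DAMPING",
    "JointState",
    "DirectionalTorqueParams",
    "PassiveParams",
    "BioTorqueModel",
    "TorqueCommand",
    "max_bio_torque",
    "passive_structure_torque",
    "command_torque",
    "zero_activity_stiffness_slope",
    "sweep_max_torque",
]

TAU_MAX = 162.0            #: device active-torque saturation (Nm)
VIRTUAL_STIFFNESS = 0.45   #: Nm per deg, about theta_ref
VIRTUAL_DAMPING = 0.02     #: Nm·s per deg


@dataclass
class JointState:
    """Measured prosthetic ankle state: angle (deg, DF positive, within
    the ROM) and angular velocity (deg/s)."""

    angle: float
    velocity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.angle) and math.isfinite(self.velocity)):
            raise ValueError("joint state must be finite")
        if not (ROM_PF - 1e-9 <= self.angle <= ROM_DF + 1e-9):
            raise ValueError(
                f"angle {self.angle} deg outside ROM [{ROM_PF}, {ROM_DF}]")


@dataclass
class DirectionalTorqueParams:
    """Hill-type maximal-torque surface for one actuation direction.

    ``fl`` is a Gaussian of angle (1 at ``opt_angle``); ``fv`` is a Hill
    hyperbola in the shortening velocity (1 at rest, 0 at ``v_max``) with
    an eccentric plateau ``ecc_plateau`` during lengthening.
    """

    tau_iso_peak: float      # Nm at optimal angle, zero velocity
    opt_angle: float         # deg
    fl_width: float          # deg (Gaussian sigma)
    v_max: float = 500.0     # deg/s maximal shortening velocity
    hill_k: float = 0.25     # curvature of the concentric hyperbola
    ecc_plateau: float = 1.4 # eccentric force enhancement asymptote

    def fl(self, angle: float) -> float:
        z = (angle - self.opt_angle) / self.fl_width
        return float(np.exp(-z * z))

    def fv(self, v_short: float) -> float:
        """Velocity factor; ``v_short`` > 0 is shortening (movement in the
        commanded direction)."""
        if v_short >= self.v_max:
            return 0.0
        if v_short >= 0.0:
            return float((1.0 - v_short / self.v_max)
                         / (1.0 + v_short / (self.v_max * self.hill_k)))
        # eccentric: smooth rise from 1 toward the plateau
        rise = self.ecc_plateau - 1.0
        return float(self.ecc_plateau
                     - rise * np.exp(v_short / (self.v_max * 0.15)))


@dataclass
class PassiveParams:
    """Passive-structure restoring torque: zero inside the neutral zone
    [onset_pf, onset_df], exponential beyond it, opposing displacement."""

    onset_df: float = 5.0    # deg; DF side onset
    onset_pf: float = -15.0  # deg; PF side onset
    k: float = 1.5           # Nm scale
    scale_deg: float = 2.0   # e-folding angle (deg)


@dataclass
class BioTorqueModel:
    """Directional maximal-torque curves and passive parameters.

    Defaults: plantar flexors peak 180 Nm near slight dorsiflexion (where
    they are stretched), dorsiflexors peak 45 Nm in plantar flexion, both
    from literature-shaped Hill curves; all values configurable.
    """

    df: DirectionalTorqueParams = field(default_factory=lambda:
        DirectionalTorqueParams(tau_iso_peak=45.0, opt_angle=-10.0, fl_width=25.0))
    pf: DirectionalTorqueParams = field(default_factory=lambda:
        DirectionalTorqueParams(tau_iso_peak=180.0, opt_angle=5.0, fl_width=30.0))
    passive: PassiveParams = field(default_factory=PassiveParams)


@dataclass
class TorqueCommand:
    """Commanded torque and its components (Nm).  ``tau_active`` is signed
    (+DF); components sum to the pre-saturation total."""

    tau_total: float
    tau_active: float
    tau_passive_structure: float
    tau_virtual: float
    saturated: bool


def max_bio_torque(model: BioTorqueModel, state: JointState,
                   direction: str) -> float:
    """Maximal biological ankle torque magnitude at this joint state for
    the commanded direction: tau_iso_peak * fl(angle) * fv(velocity)."""
    d = direction.lower()
    if d not in ("df", "pf"):
        raise ValueError(f"direction must be 'df' or 'pf', got {direction!r}")
    p = model.df if d == "df" else model.pf
    # shortening velocity is the joint velocity along the commanded direction
    v_short = state.velocity if d == "df" else -state.velocity
    return max(0.0, p.tau_iso_peak * p.fl(state.angle) * p.fv(v_short))


def passive_structure_torque(model: BioTorqueModel, state: JointState) -> float:
    """Restoring torque from passive structures (Nm); zero in the neutral
    zone, plantar-flexing near full DF and dorsiflexing near full PF."""
    p = model.passive
    a = state.angle
    if a > p.onset_df:
        return -p.k * (math.expm1((a - p.onset_df) / p.scale_deg))
    if a < p.onset_pf:
        return p.k * (math.expm1((p.onset_pf - a) / p.scale_deg))
    return 0.0


def command_torque(theta_ref: float, mu_z: float, state: JointState,
                   model: BioTorqueModel, *,
                   stiffness: float = VIRTUAL_STIFFNESS,
                   damping: float = VIRTUAL_DAMPING,
                   tau_max: float = TAU_MAX,
                   rom_df: float = ROM_DF, rom_pf: float = ROM_PF) -> TorqueCommand:
    """Total torque command for one control tick.

    The angle error delta = theta_ref - angle selects the direction; its
    normalization delta/delta_max (delta_max = remaining ROM toward that
    direction) makes mu_z = 1 with maximal delta land exactly on the
    biological bound.  Virtual stiffness acts on (angle - theta_ref) and
    damping on velocity; the summed command is saturated at ±tau_max.
    """
    vals = (theta_ref, mu_z, state.angle, state.velocity)
    if not all(math.isfinite(v) for v in vals):
        raise FloatingPointError(f"non-finite controller input: {vals}")
    if not 0.0 <= mu_z <= 1.0:
        raise ValueError(f"mu_z must be in [0, 1], got {mu_z}")

    delta = theta_ref - state.angle
    if delta >= 0.0:
        direction, delta_max = "df", rom_df - state.angle
    else:
        direction, delta_max = "pf", state.angle - rom_pf
    delta_norm = min(abs(delta) / delta_max, 1.0) if delta_max > 1e-12 else 0.0

    tau_active = mu_z * delta_norm * max_bio_torque(model, state, direction)
    if direction == "pf":
        tau_active = -tau_active
    tau_passive = passive_structure_torque(model, state)
    tau_virtual = (-stiffness * (state.angle - theta_ref)
                   - damping * state.velocity)
    total = tau_active + tau_passive + tau_virtual
    saturated = abs(total) > tau_max
    if saturated:
        total = math.copysign(tau_max, total)
    return TorqueCommand(total, tau_active, tau_passive, tau_virtual, saturated)


def zero_activity_stiffness_slope(model: BioTorqueModel | None = None,
                                  sweep_deg: float = 4.0,
                                  n: int = 81) -> float:
    """Measured restoring-torque slope (Nm/deg) under zero muscle activity.

    Sweeps the joint angle about neutral (inside the passive neutral
    zone) with mu_z = 0, theta_ref = 0 and zero velocity, and fits the
    slope of -tau_total against angle; with the default gains this is the
    virtual stiffness.
    """
    model = model or BioTorqueModel()
    angles = np.linspace(-sweep_deg, sweep_deg, n)
    taus = np.array([command_torque(0.0, 0.0, JointState(a, 0.0), model).tau_total
                     for a in angles])
    return float(np.polyfit(angles, -taus, 1)[0])


def sweep_max_torque(model: BioTorqueModel | None = None,
                     n_mu: int = 6, n_angle: int = 25, n_vel: int = 21,
                     vel_span: float = 1000.0) -> float:
    """Maximum |commanded torque| over an exhaustive saturating sweep.

    Grids mu_z in [0, 1], theta_ref and angle over the full ROM and
    velocity over ±``vel_span`` deg/s; the device saturation bounds the
    result.
    """
    model = model or BioTorqueModel()
    worst = 0.0
    for mu in np.linspace(0.0, 1.0, n_mu):
        for ref in np.linspace(ROM_PF, ROM_DF, n_angle):
            for ang in np.linspace(ROM_PF, ROM_DF, n_angle):
                for vel in np.linspace(-vel_span, vel_span, n_vel):
                    cmd = command_torque(ref, mu, JointState(ang, vel), model)
                    worst = max(worst, abs(cmd.tau_total))
    return worst
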