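"""Minimal ankle/foot plant closing the control loop for desk-scale
simulation.

A single rotational inertia about the ankle is driven by the commanded
torque plus a ground-load torque replayed as a function of percent gait
cycle (no contact mechanics).  Semi-implicit Euler at 1 kHz keeps the
stiff virtual-impedance terms stable; ROM ends are hard stops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import emg as emg_mod
from .controller import BioTorqueModel, JointState, command_torque
from .decoder import ROM_DF, ROM_PF, DecoderCalibration, compute_theta_ref

__all__ = ["PlantConfig", "GaitTrial", "step_dynamics", "simulate_gait"]


@dataclass
class PlantConfig:
    """Ankle plant parameters.

    ``inertia`` is the foot+device rotational inertia about the ankle
    (kg·m², default from a 2.4 kg device with ~0.14 m gyration radius);
    ``ground_load_schedule`` maps percent cycle in [0, 100) to an external
    torque in Nm/kg of body mass (dorsiflexing positive).
    """

    inertia: float = 0.05
    body_mass: float = 75.0
    timestep: float = 1e-3
    velocity_bound: float = 5000.0  # deg/s; divergence guard
    ground_load_schedule: object = None  # callable pct -> Nm/kg

    def __post_init__(self) -> None:
        if self.inertia <= 0:
            raise ValueError("inertia must be positive")
        if self.timestep > 1e-3 + 1e-12:
            raise ValueError("timestep must be <= 1 ms")


@dataclass
class GaitTrial:
    """Closed-loop simulation output at the plant rate."""

    sample_rate: float
    angle: np.ndarray          # deg
    velocity: np.ndarray       # deg/s
    torque: np.ndarray         # commanded torque, Nm
    power: np.ndarray          # W (torque × angular velocity in rad/s)
    cycle_pct: np.ndarray      # percent of gait cycle per sample
    condition: str = ""
    stance_end_pct: float = 62.0
    cycle_duration_s: float = 1.0
    n_cycles: int = 1
    body_mass: float = 75.0
    extras: dict = field(default_factory=dict)


def step_dynamics(state: JointState, tau_command: float, tau_external: float,
                  dt: float, config: PlantConfig) -> JointState:
    """One semi-implicit Euler step under the net torque, with hard stops
    at the ROM ends (angle clamped, velocity zeroed)."""
    if dt > config.timestep + 1e-12:
        raise ValueError(f"dt = {dt} exceeds configured timestep")
    net = tau_command + tau_external
    acc = math.degrees(net / config.inertia)  # deg/s^2
    v = state.velocity + dt * acc
    if abs(v) > config.velocity_bound:
        raise RuntimeError(
            f"simulation divergence: |velocity| = {abs(v):.0f} deg/s exceeds "
            f"bound {config.velocity_bound:.0f}")
    a = state.angle + dt * v
    if a >= ROM_DF:
        a, v = ROM_DF, 0.0
    elif a <= ROM_PF:
        a, v = ROM_PF, 0.0
    return JointState(a, v)


def simulate_gait(emg_streams: dict, emg_rate: float,
                  calib: DecoderCalibration, model: BioTorqueModel,
                  plant: PlantConfig, condition: str, n_cycles: int,
                  cycle_duration_s: float = 1.0,
                  stance_end_pct: float = 62.0,
                  seed: int | None = None) -> GaitTrial:
    """Run the full controller stack through ``n_cycles`` gait cycles.

    ``emg_streams`` maps "ta"/"gas" to raw EMG covering the whole trial at
    ``emg_rate``.  EMG is conditioned to activations, resampled to the
    plant rate, decoded to (theta_ref, mu_z) and fed to the impedance
    controller; the ground load from ``plant.ground_load_schedule`` is
    replayed against percent cycle.  Deterministic for a given input
    (``seed`` is accepted for interface symmetry and recorded).
    """
    fs = 1.0 / plant.timestep
    total_t = n_cycles * cycle_duration_s
    n = int(round(total_t * fs))
    taps = emg_mod.design_bandpass(emg_rate)
    act = {}
    for name in ("ta", "gas"):
        raw = np.asarray(emg_streams[name], dtype=float)
        need = int(round(total_t * emg_rate))
        if raw.size < need:
            raise ValueError(
                f"EMG stream {name!r} covers {raw.size / emg_rate:.2f} s but "
                f"{total_t:.2f} s are required for {n_cycles} cycles")
        a = emg_mod.emg_to_activation(raw[:need], emg_rate, taps=taps)
        t_src = np.arange(need) / emg_rate
        t_dst = np.arange(n) / fs
        act[name] = np.interp(t_dst, t_src, a)

    theta_ref = compute_theta_ref(act["ta"], act["gas"], calib, fs)
    pct = (np.arange(n) / fs / cycle_duration_s * 100.0) % 100.0
    load = plant.ground_load_schedule
    state = JointState(0.0, 0.0)
    angle = np.empty(n)
    velocity = np.empty(n)
    torque = np.empty(n)
    mu = np.empty(n)
    for i in range(n):
        # direction-resolved mu_z against the actual angle
        delta = theta_ref[i] - state.angle
        norm = calib.mu_norm_df if delta >= 0 else calib.mu_norm_pf
        s = calib.w_ta * act["ta"][i] + calib.w_gas * act["gas"][i]
        mu_i = min(max(s / norm, 0.0), 1.0)
        cmd = command_torque(theta_ref[i], mu_i, state, model)
        tau_ext = (load(pct[i]) * plant.body_mass) if load is not None else 0.0
        try:
            state = step_dynamics(state, cmd.tau_total, tau_ext,
                                  plant.timestep, plant)
        except RuntimeError as err:
            raise RuntimeError(
                f"{err} (cycle {int(pct[i] // 100) + 1}, {pct[i]:.1f}%)"
            ) from err
        angle[i] = state.angle
        velocity[i] = state.velocity
        torque[i] = cmd.tau_total
        mu[i] = mu_i
    power = torque * np.radians(velocity)
    return GaitTrial(fs, angle, velocity, torque, power, pct,
                     condition=condition, stance_end_pct=stance_end_pct,
                     cycle_duration_s=cycle_duration_s, n_cycles=n_cycles,
                     body_mass=plant.body_mass,
                     extras={"theta_ref": theta_ref, "mu_z": mu, "seed": seed})
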