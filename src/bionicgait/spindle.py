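"""Muscle spindle (secondary ending) afferent estimation.

Secondary (type II) spindle endings are predominantly length sensitive
with a weak velocity and fusimotor/activation contribution.  Firing is
modelled additively from fascicle strain (positive = lengthening, as a
fraction of optimal fascicle length), its rate, and the normalized EMG
envelope:

    rate = max(0, baseline + k_len*strain
                  + k_vel*sign(d strain/dt)*|d strain/dt|^p
                  + k_act*envelope)

The cohort statistic is the agonist-antagonist afferent: the steady-state
(25-75% of cycle) antagonist (lengthening) rate minus the agonist
(shortening) rate, averaged over the maximum phantom dorsiflexion and
plantar flexion movements.  It is near zero when the residual muscles are
mechanically decoupled and negative when afferents rise paradoxically
during agonist action.

Default coefficients are anchored so that a full-range intact-limb strain
excursion (~0.15) yields ~60 Imp/s steady antagonist firing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CYCLE_GRID",
    "FascicleTrace",
    "SpindleParams",
    "AfferentEstimate",
    "spindle_rate",
    "steady_state_afferent",
    "agonist_antagonist_afferent",
    "estimate_afferents",
]

#: fixed cycle grid: 101 points over 0-100% of the movement cycle
CYCLE_GRID = np.linspace(0.0, 100.0, 101)


@dataclass
class FascicleTrace:
    """Cycle-normalized fascicle strain for one muscle (101-point grid)."""

    strain: np.ndarray     # dimensionless; positive = lengthening
    muscle: str = ""
    n_cycles: int = 1

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        if self.strain.shape != CYCLE_GRID.shape:
            raise ValueError(
                f"strain must be on the {CYCLE_GRID.size}-point cycle grid, "
                f"got shape {self.strain.shape}")
        if not np.all(np.isfinite(self.strain)):
            raise ValueError("strain contains non-finite values")


@dataclass
class SpindleParams:
    """Secondary-ending coefficients (all non-negative).

    Units: ``k_len`` Imp/s per unit strain; ``k_vel`` Imp/s per (unit
    strain per cycle-fraction-second)^p; ``k_act`` Imp/s per unit
    envelope; ``baseline`` Imp/s resting discharge.
    """

    baseline: float = 10.0
    k_len: float = 333.0
    k_vel: float = 13.5
    p: float = 0.5
    k_act: float = 5.0

    def __post_init__(self) -> None:
        if min(self.baseline, self.k_len, self.k_vel, self.k_act) < 0:
            raise ValueError("spindle coefficients must be non-negative")


@dataclass
class AfferentEstimate:
    """Firing-rate trace (Imp/s) over the cycle and its steady-state mean."""

    rate_trace: np.ndarray
    steady_mean: float
    role: str = ""  # "agonist_shortening" | "antagonist_lengthening"


def _strain_rate(strain: np.ndarray, cycle_duration_s: float) -> np.ndarray:
    """Central-difference strain rate (1/s) after 5-point smoothing;
    ultrasound-derived strains are noisy."""
    kernel = np.ones(5) / 5.0
    sm = np.convolve(strain, kernel, mode="same")
    # repair the convolution edges with the raw values
    sm[:2], sm[-2:] = strain[:2], strain[-2:]
    dt = cycle_duration_s / (CYCLE_GRID.size - 1)
    return np.gradient(sm, dt)


def spindle_rate(strain: np.ndarray, strain_rate: np.ndarray,
                 emg_envelope: np.ndarray,
                 params: SpindleParams | None = None) -> np.ndarray:
    """Firing-rate trace (Imp/s) on the common cycle grid, rectified at 0."""
    params = params or SpindleParams()
    strain = np.asarray(strain, dtype=float)
    strain_rate = np.asarray(strain_rate, dtype=float)
    emg_envelope = np.asarray(emg_envelope, dtype=float)
    if not (strain.shape == strain_rate.shape == emg_envelope.shape):
        raise ValueError(
            f"mismatched grids: strain {strain.shape}, rate "
            f"{strain_rate.shape}, envelope {emg_envelope.shape}")
    vel_term = params.k_vel * np.sign(strain_rate) * np.abs(strain_rate) ** params.p
    rate = (params.baseline + params.k_len * strain + vel_term
            + params.k_act * emg_envelope)
    return np.maximum(rate, 0.0)


def steady_state_afferent(rate_trace: np.ndarray) -> float:
    """Mean firing over the steady-state 25-75% window of the cycle."""
    rate_trace = np.asarray(rate_trace, dtype=float)
    if rate_trace.shape != CYCLE_GRID.shape:
        raise ValueError(
            f"rate trace must be on the {CYCLE_GRID.size}-point grid")
    mask = (CYCLE_GRID >= 25.0) & (CYCLE_GRID <= 75.0)
    return float(rate_trace[mask].mean())


def agonist_antagonist_afferent(df_agonist: AfferentEstimate,
                                df_antagonist: AfferentEstimate,
                                pf_agonist: AfferentEstimate,
                                pf_antagonist: AfferentEstimate) -> float:
    """Agonist-antagonist afferent statistic (Imp/s).

    Mean over the two phantom movements of (antagonist steady rate -
    agonist steady rate).  In the dorsiflexion cycle the TA is the
    shortening agonist and the GAS the lengthening antagonist; roles swap
    for plantar flexion.  Negative values indicate non-biomimetic
    behavior (afferents rising during agonist action).
    """
    for est, want in ((df_agonist, "agonist"), (df_antagonist, "antagonist"),
                      (pf_agonist, "agonist"), (pf_antagonist, "antagonist")):
        if est is None:
            raise ValueError("all four movement/role estimates are required")
        if est.role and want not in est.role:
            raise ValueError(
                f"estimate labelled {est.role!r} supplied in the {want} slot")
    d_df = df_antagonist.steady_mean - df_agonist.steady_mean
    d_pf = pf_antagonist.steady_mean - pf_agonist.steady_mean
    return 0.5 * (d_df + d_pf)


def estimate_afferents(trace: FascicleTrace, envelope: np.ndarray,
                       role: str, cycle_duration_s: float = 2.0,
                       params: SpindleParams | None = None) -> AfferentEstimate:
    """Convenience: strain trace + envelope -> AfferentEstimate."""
    rate = spindle_rate(trace.strain,
                        _strain_rate(trace.strain, cycle_duration_s),
                        envelope, params)
    return AfferentEstimate(rate, steady_state_afferent(rate), role)
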