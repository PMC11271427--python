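"""Per-trial gait biomechanics: cycle normalization, event kinematics,
power/net-work energetics, torque-angle work loops, range of motion and
lower-extremity kinematic (LEK) symmetry.

Conventions: ankle angle in deg with dorsiflexion (DF) positive; torque
mass-normalized (Nm/kg); power mass-normalized (W/kg) computed as torque
times angular velocity in rad/s; every cycle lives on a fixed 1001-point
0-100% grid.  Net work over a window equals the signed torque-angle loop
area over that window (work-loop identity), which the two independent
routes here cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRID",
    "GaitCycle",
    "EventKinematics",
    "SymmetryResult",
    "normalize_cycle",
    "segment_level_events",
    "segment_stair_events",
    "peak_power",
    "net_work",
    "torque_angle_loop",
    "lek_symmetry",
    "rom",
    "obstacle_swing_delta",
    "recovery_step_metrics",
]

#: fixed gait-cycle grid: 1001 points over 0-100% (0.1% resolution)
GRID = np.linspace(0.0, 100.0, 1001)


@dataclass
class GaitCycle:
    """One time-normalized stride on the fixed grid."""

    angle: np.ndarray        # deg, DF positive
    torque: np.ndarray       # Nm/kg
    stance_end_pct: float
    duration_s: float
    mass: float = 1.0
    condition: str = ""
    power: np.ndarray = None  # W/kg; derived if not supplied

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        if self.angle.shape != GRID.shape or self.torque.shape != GRID.shape:
            raise ValueError(f"traces must be on the {GRID.size}-point grid")
        if not 0.0 < self.stance_end_pct < 100.0:
            raise ValueError("stance_end_pct must lie inside (0, 100)")
        if self.power is None:
            dt = self.duration_s / (GRID.size - 1)
            omega = np.radians(np.gradient(self.angle, dt))  # rad/s
            self.power = self.torque * omega
        else:
            self.power = np.asarray(self.power, dtype=float)


@dataclass
class EventKinematics:
    """Signed gait-event angle excursions (deg).

    ``magnitudes`` reports |excursion| per event; ``directions`` carries
    the phase's DF/PF label.  Events whose defining landmark is missing
    are flagged in ``absent`` instead of being fabricated.
    """

    magnitudes: dict = field(default_factory=dict)
    directions: dict = field(default_factory=dict)
    absent: list = field(default_factory=list)


@dataclass
class SymmetryResult:
    """Symmetry index (SI, %) and LEK symmetry = 100 - SI."""

    si: float
    lek_symmetry: float
    per_joint_si: dict = field(default_factory=dict)


def normalize_cycle(time_s: np.ndarray, angle: np.ndarray, torque: np.ndarray,
                    mass: float, *, bounds: tuple[float, float] | None = None,
                    stance_end_pct: float = 62.0,
                    condition: str = "",
                    torque_is_mass_normalized: bool = False) -> GaitCycle:
    """Resample one stride onto the fixed 0-100% grid.

    ``bounds`` are the cycle start/end times in seconds (defaults to the
    full record); torque is divided by body mass unless already
    normalized.  Cycles shorter than 0.2 s are rejected as spurious.
    """
    time_s = np.asarray(time_s, dtype=float)
    angle = np.asarray(angle, dtype=float)
    torque = np.asarray(torque, dtype=float)
    if mass <= 0:
        raise ValueError("mass must be positive")
    t0, t1 = bounds if bounds is not None else (time_s[0], time_s[-1])
    if t1 - t0 < 0.2:
        raise ValueError(
            f"cycle of {t1 - t0:.3f} s rejected as spurious (< 0.2 s)")
    sel = (time_s >= t0) & (time_s <= t1)
    t = time_s[sel]
    grid_t = t0 + GRID / 100.0 * (t1 - t0)
    ang = np.interp(grid_t, t, angle[sel])
    tq = np.interp(grid_t, t, torque[sel])
    if not torque_is_mass_normalized:
        tq = tq / mass
    return GaitCycle(ang, tq, stance_end_pct, float(t1 - t0), mass, condition)


def _local_extrema(x: np.ndarray, kind: str) -> list[int]:
    """Indices of strict local extrema, plateaus resolved to midpoints."""
    idx = []
    n = x.size
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and x[j + 1] == x[j]:
            j += 1
        left, right = x[i - 1], x[min(j + 1, n - 1)]
        if kind == "min" and x[i] < left and x[i] < right:
            idx.append((i + j) // 2)
        elif kind == "max" and x[i] > left and x[i] > right:
            idx.append((i + j) // 2)
        i = j + 1
    return idx


def _stance_slice(cycle: GaitCycle) -> slice:
    end = int(np.searchsorted(GRID, cycle.stance_end_pct, side="right"))
    return slice(0, end)


def segment_level_events(cycle: GaitCycle) -> EventKinematics:
    """Level-ground / slope gait events from the ankle angle trace.

    Heel strike (HS): PF excursion from initial contact to the first
    local PF maximum (angle minimum) during stance.  Loading response
    (LR): DF from that minimum to the stance DF maximum.  Push-off (PO):
    PF from the stance DF maximum to the angle at end of stance.  Foot
    clearance (FC): DF from end of stance to end of swing.
    """
    ang = cycle.angle
    st = _stance_slice(cycle)
    ev = EventKinematics()
    stance = ang[st]
    i_end_stance = st.stop - 1
    mins = _local_extrema(stance, "min")
    if not mins:
        ev.absent += ["HS", "LR"]
        i_pf = None
    else:
        i_pf = mins[0]
        ev.magnitudes["HS"] = float(ang[0] - stance[i_pf])
        ev.directions["HS"] = "PF"
    i_df = int(np.argmax(stance))
    df_max = float(stance[i_df])
    if i_pf is not None:
        ev.magnitudes["LR"] = float(df_max - stance[i_pf])
        ev.directions["LR"] = "DF"
    ev.magnitudes["PO"] = float(df_max - ang[i_end_stance])
    ev.directions["PO"] = "PF"
    ev.magnitudes["FC"] = float(ang[-1] - ang[i_end_stance])
    ev.directions["FC"] = "DF"
    for k, v in list(ev.magnitudes.items()):
        if abs(v) < 1e-12:
            ev.absent.append(k + "_degenerate")
    return ev


def segment_stair_events(cycle: GaitCycle, direction: str) -> EventKinematics:
    """Stair gait events.

    Weight acceptance (WA): DF from initial contact to the stance DF
    maximum.  Descent adds forward continuance / foot placement (FCo):
    PF from the stance DF maximum to end of swing.  Ascent adds pull-up
    (PU) and foot clearance (FC), defined like PO and FC on level ground.
    """
    d = direction.lower()
    if d not in ("descent", "ascent"):
        raise ValueError(f"direction must be 'descent' or 'ascent', got {direction!r}")
    ang = cycle.angle
    st = _stance_slice(cycle)
    stance = ang[st]
    ev = EventKinematics()
    i_df = int(np.argmax(stance))
    if i_df == 0 or stance[i_df] <= ang[0]:
        ev.absent.append("WA")
        df_max = float(stance[i_df])
    else:
        df_max = float(stance[i_df])
        ev.magnitudes["WA"] = float(df_max - ang[0])
        ev.directions["WA"] = "DF"
    if d == "descent":
        ev.magnitudes["FCo"] = float(df_max - ang[-1])
        ev.directions["FCo"] = "PF"
    else:
        i_end_stance = st.stop - 1
        ev.magnitudes["PU"] = float(df_max - ang[i_end_stance])
        ev.directions["PU"] = "PF"
        ev.magnitudes["FC"] = float(ang[-1] - ang[i_end_stance])
        ev.directions["FC"] = "DF"
    return ev


def peak_power(cycle: GaitCycle, mode: str = "positive") -> float:
    """Extremum of the requested power sign over the cycle (W/kg); 0 if no
    sample of that sign exists.  Negative peaks are reported for stair
    descent (shock absorption), positive peaks elsewhere."""
    p = cycle.power
    if mode == "positive":
        m = float(p.max())
        return m if m > 0 else 0.0
    if mode == "negative":
        m = float(p.min())
        return m if m < 0 else 0.0
    raise ValueError(f"mode must be 'positive' or 'negative', got {mode!r}")


def net_work(cycle: GaitCycle, window: tuple[float, float] = (0.0, 100.0)) -> float:
    """Trapezoidal time-integral of mass-normalized power (J/kg) over the
    percent-cycle window."""
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"inverted window {window}")
    if lo < 0 or hi > 100:
        raise ValueError(f"window {window} outside [0, 100]")
    mask = (GRID >= lo) & (GRID <= hi)
    dt = cycle.duration_s / (GRID.size - 1)
    return float(np.trapezoid(cycle.power[mask], dx=dt))


def torque_angle_loop(cycle: GaitCycle, *,
                      closure_tol_deg: float = 0.5) -> dict:
    """Signed area of the closed (angle, torque) work loop.

    The area is the line integral of torque over angle (angle in rad, so
    units are J/kg) with the work-loop orientation convention: positive
    area = counterclockwise = net positive work injected.  Open loops
    (endpoints further apart than ``closure_tol_deg``) are closed by a
    straight segment and flagged.
    """
    theta = np.radians(cycle.angle)
    tau = cycle.torque
    closed_by_segment = abs(cycle.angle[-1] - cycle.angle[0]) > closure_tol_deg
    th = np.append(theta, theta[0])
    tq = np.append(tau, tau[0])
    area = float(np.sum(0.5 * (tq[1:] + tq[:-1]) * np.diff(th)))
    return {
        "area": area,
        "direction": "ccw" if area > 0 else "cw",
        "closed_by_segment": closed_by_segment,
    }


def lek_symmetry(ipsi: dict[str, np.ndarray],
                 contra: dict[str, np.ndarray],
                 joints: tuple[str, ...] = ("ankle", "knee", "hip")) -> SymmetryResult:
    """LEK symmetry from the mean symmetry index across joints.

    Per joint, SI = 100 * integral |x_contra - x_ipsi| over the cycle,
    normalized by the mean cycle-integrated absolute excursion of the two
    limbs.  SI is symmetric in the two limbs, zero iff the trajectories
    are identical; LEK symmetry = 100 - mean SI.
    """
    missing = [j for j in joints if j not in ipsi or j not in contra]
    if missing:
        raise ValueError(
            f"missing joints {missing}; present ipsi={sorted(ipsi)}, "
            f"contra={sorted(contra)}")
    per = {}
    for j in joints:
        xi = np.asarray(ipsi[j], dtype=float)
        xc = np.asarray(contra[j], dtype=float)
        if xi.shape != xc.shape:
            raise ValueError(f"joint {j!r} traces differ in length")
        num = np.trapezoid(np.abs(xc - xi), GRID)
        den = 0.5 * (np.trapezoid(np.abs(xc), GRID) + np.trapezoid(np.abs(xi), GRID))
        per[j] = 0.0 if den == 0 else float(100.0 * num / den)
    si = float(np.mean(list(per.values())))
    return SymmetryResult(si, 100.0 - si, per)


def rom(trajectory: np.ndarray) -> float:
    """Range of motion: max minus min of the average trajectory (deg)."""
    x = np.asarray(trajectory, dtype=float)
    return float(x.max() - x.min())


def obstacle_swing_delta(perturbed: list[GaitCycle],
                         unperturbed: list[GaitCycle]) -> float:
    """Mean increase (deg) of the swing-phase DF peak in perturbed cycles
    over the mean unperturbed swing DF peak; negative values allowed."""
    def swing_peak(c: GaitCycle) -> float:
        mask = GRID > c.stance_end_pct
        return float(c.angle[mask].max())

    base = float(np.mean([swing_peak(c) for c in unperturbed]))
    return float(np.mean([swing_peak(c) - base for c in perturbed]))


def recovery_step_metrics(cycle: GaitCycle) -> dict:
    """Propulsive mechanics of the recovery step after obstacle crossing:
    positive peak power (W/kg) and full-cycle net work (J/kg)."""
    return {"peak_power": peak_power(cycle, "positive"),
            "net_work": net_work(cycle)}
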