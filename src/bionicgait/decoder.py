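"""Neural decoding of TA/GAS muscle activations into the two continuous
control variables of the prosthesis:

* ``theta_ref`` — target equilibrium ankle angle (deg, dorsiflexion
  positive), from the weighted activation difference, clipped to the
  device range of motion and smoothed by a critically damped second-order
  low-pass (6 Hz cut-off);
* ``mu_z``     — joint impedance modulation level in [0, 1], from the
  weighted activation sum normalized per movement direction.

Calibration maps each subject's maximal phantom dorsiflexion (DF) and
plantar flexion (PF) activation patterns exactly onto the prosthetic range
of motion (+10 deg DF, -20 deg PF).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

__all__ = [
    "ROM_DF",
    "ROM_PF",
    "DecoderCalibration",
    "calibrate",
    "compute_theta_ref",
    "compute_mu_z",
    "critically_damped_lowpass",
]

ROM_DF = 10.0   #: maximum dorsiflexion angle (deg)
ROM_PF = -20.0  #: maximum plantar flexion angle (deg)


@dataclass
class DecoderCalibration:
    """Per-subject decoder weights and normalizers.

    ``w_ta``/``w_gas`` are in deg per unit activation; ``mu_norm_df`` and
    ``mu_norm_pf`` normalize the weighted activation sum separately for
    each actuation direction (DF and PF motor coordination differ).
    """

    w_ta: float
    w_gas: float
    mu_norm_df: float
    mu_norm_pf: float
    rom_df: float = ROM_DF
    rom_pf: float = ROM_PF

    def __post_init__(self) -> None:
        if self.mu_norm_df <= 0 or self.mu_norm_pf <= 0:
            raise ValueError("mu_z normalizers must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DecoderCalibration":
        with open(path) as fh:
            return cls(**json.load(fh))


def _plateau_mean(a: np.ndarray, sample_rate: float,
                  min_duration_s: float = 0.5,
                  threshold: float = 0.9) -> float:
    """Mean activation over the sustained plateau of a calibration trial.

    The plateau is the set of samples at or above ``threshold`` times the
    trial maximum; it must span at least ``min_duration_s``.
    """
    a = np.asarray(a, dtype=float)
    peak = a.max()
    mask = a >= threshold * peak
    if mask.sum() < min_duration_s * sample_rate:
        raise ValueError(
            f"no sustained plateau >= {min_duration_s} s found in trial")
    return float(a[mask].mean())


def calibrate(max_df_trial, max_pf_trial, sample_rate: float | None = None,
              *, singular_threshold: float = 1e-3) -> DecoderCalibration:
    """Solve the decoder weights from maximal phantom DF and PF trials.

    Each trial is an ``(a_ta, a_gas)`` pair — either scalar plateau means
    or activation traces (then ``sample_rate`` is required and the plateau
    is detected on the trial's dominant channel).  The weights solve

        w_ta * a_ta_df - w_gas * a_gas_df = +10 deg   (max DF)
        w_ta * a_ta_pf - w_gas * a_gas_pf = -20 deg   (max PF)

    and the mu_z normalizers are the plateau-mean weighted sums per
    direction, so replaying the calibration trials yields mu_z = 1.
    """
    def _means(trial):
        a_ta, a_gas = trial
        if np.isscalar(a_ta) and np.isscalar(a_gas):
            return float(a_ta), float(a_gas)
        if sample_rate is None:
            raise ValueError("sample_rate required for trace calibration trials")
        a_ta = np.asarray(a_ta, dtype=float)
        a_gas = np.asarray(a_gas, dtype=float)
        dominant = a_ta if a_ta.max() >= a_gas.max() else a_gas
        peak = dominant.max()
        if peak <= 0:
            raise ValueError("calibration trial contains no activation")
        mask = dominant >= 0.9 * peak
        if mask.sum() < 0.5 * sample_rate:
            raise ValueError("no sustained plateau >= 0.5 s found in trial")
        return float(a_ta[mask].mean()), float(a_gas[mask].mean())

    ta_df, gas_df = _means(max_df_trial)
    ta_pf, gas_pf = _means(max_pf_trial)
    A = np.array([[ta_df, -gas_df], [ta_pf, -gas_pf]], dtype=float)
    b = np.array([ROM_DF, ROM_PF], dtype=float)
    det = float(np.linalg.det(A))
    scale = max(abs(A).max(), 1.0) ** 2
    if abs(det) < singular_threshold * scale:
        raise ValueError(
            "calibration failure: DF and PF activation patterns are "
            f"indistinct (|det| = {abs(det):.2e}); co-activation plateaus "
            "cannot be separated")
    w_ta, w_gas = np.linalg.solve(A, b)
    mu_norm_df = w_ta * ta_df + w_gas * gas_df
    mu_norm_pf = w_ta * ta_pf + w_gas * gas_pf
    return DecoderCalibration(float(w_ta), float(w_gas),
                              float(mu_norm_df), float(mu_norm_pf))


def critically_damped_lowpass(x: np.ndarray, sample_rate: float,
                              fc: float = 6.0) -> np.ndarray:
    """Critically damped second-order low-pass H(s) = wc^2/(s + wc)^2.

    Discretized by the bilinear transform with the cut-off prewarped, so
    the -6 dB point (|H| = 1/2 for a critically damped pair) lands exactly
    at ``fc``.  Zero overshoot to steps; initialized at the first sample.
    """
    x = np.asarray(x, dtype=float)
    wc = 2.0 * sample_rate * np.tan(np.pi * fc / sample_rate)
    b, a = signal.bilinear([wc * wc], [1.0, 2.0 * wc, wc * wc], fs=sample_rate)
    zi = signal.lfilter_zi(b, a) * (x[0] if x.size else 0.0)
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def compute_theta_ref(a_ta: np.ndarray, a_gas: np.ndarray,
                      calib: DecoderCalibration, sample_rate: float,
                      fc: float = 6.0) -> np.ndarray:
    """Equilibrium-angle command from the weighted activation difference.

    raw = w_ta*a_ta - w_gas*a_gas, clipped to the ROM before filtering (so
    the filtered command respects the actuator limits without post-filter
    discontinuities), then smoothed by the critically damped 6 Hz
    low-pass.  Output in deg, DF positive, within [rom_pf, rom_df].
    """
    a_ta = np.asarray(a_ta, dtype=float)
    a_gas = np.asarray(a_gas, dtype=float)
    raw = calib.w_ta * a_ta - calib.w_gas * a_gas
    raw = np.clip(raw, calib.rom_pf, calib.rom_df)
    return critically_damped_lowpass(raw, sample_rate, fc)


def compute_mu_z(a_ta: np.ndarray, a_gas: np.ndarray,
                 calib: DecoderCalibration,
                 direction: str | None = None,
                 *, theta_ref: np.ndarray | None = None,
                 angle: np.ndarray | None = None,
                 hysteresis_deg: float = 0.5) -> np.ndarray:
    """Impedance modulation level mu_z in [0, 1].

    mu_z = clip((w_ta*a_ta + w_gas*a_gas) / norm_dir, 0, 1) where the
    direction-specific normalizer is selected either by the fixed
    ``direction`` ("df" or "pf") or per-sample by the sign of the angle
    error delta = theta_ref - angle, with a small hysteresis band to avoid
    normalizer chattering near delta = 0.
    """
    a_ta = np.asarray(a_ta, dtype=float)
    a_gas = np.asarray(a_gas, dtype=float)
    s = calib.w_ta * a_ta + calib.w_gas * a_gas
    if direction is not None:
        d = direction.lower()
        if d not in ("df", "pf"):
            raise ValueError(f"direction must be 'df' or 'pf', got {direction!r}")
        norm = calib.mu_norm_df if d == "df" else calib.mu_norm_pf
        return np.clip(s / norm, 0.0, 1.0)
    if theta_ref is None or angle is None:
        raise ValueError("either direction or (theta_ref, angle) required")
    delta = np.asarray(theta_ref, dtype=float) - np.asarray(angle, dtype=float)
    norm = np.empty_like(s)
    current_df = True  # start in DF convention; switch outside hysteresis band
    for i, d in enumerate(delta):
        if d > hysteresis_deg:
            current_df = True
        elif d < -hysteresis_deg:
            current_df = False
        norm[i] = calib.mu_norm_df if current_df else calib.mu_norm_pf
    return np.clip(s / norm, 0.0, 1.0)
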