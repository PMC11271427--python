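"""End-to-end assembly: synthetic subjects -> afferent estimates ->
per-trial gait metrics -> cohort table -> correlations / PCA / report.

This is the layer the analysis drivers and the command-line interface
share; every computation lives in the stage modules it wires together.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import gait, plant as plant_mod, reference, spindle, synth
from .controller import BioTorqueModel
from .decoder import DecoderCalibration
from .emg import design_bandpass, emg_envelope

__all__ = [
    "phantom_afferent_statistic",
    "afferent_table",
    "trial_metrics",
    "cohort_table",
    "cohort_report",
    "closed_loop_level_walking",
    "PCA_FLIP_COLUMNS",
]


def _fold_envelope(raw: np.ndarray, sample_rate: float, n_cycles: int,
                   taps=None) -> np.ndarray:
    """Envelope of a multi-cycle EMG stream, cycle-averaged and resampled
    onto the 101-point cycle grid."""
    env = emg_envelope(raw, sample_rate, taps=taps)
    per = env.size // n_cycles
    folded = env[: per * n_cycles].reshape(n_cycles, per).mean(axis=0)
    pct = np.arange(per) / per * 100.0
    return np.interp(spindle.CYCLE_GRID, pct, folded)


def phantom_afferent_statistic(pcs: synth.PhantomCycleSet,
                               params: spindle.SpindleParams | None = None,
                               taps=None) -> dict:
    """Run phantom-movement recordings through the full estimation chain.

    EMG streams are conditioned to cycle-averaged envelopes, combined
    with the cycle-averaged fascicle strains in the spindle model, and
    reduced to the agonist-antagonist afferent statistic (Imp/s).
    """
    if taps is None:
        taps = design_bandpass(2000.0)
    est = {}
    for movement, agonist in (("df", "ta"), ("pf", "gas")):
        antagonist = "gas" if agonist == "ta" else "ta"
        rec = pcs.emg[movement]
        envs = {m: _fold_envelope(rec.channels[m], rec.sample_rate,
                                  pcs.n_cycles, taps) for m in (agonist, antagonist)}
        est[movement] = {
            "agonist": spindle.estimate_afferents(
                pcs.mean_strain[movement][agonist], envs[agonist],
                "agonist_shortening", pcs.cycle_duration_s, params),
            "antagonist": spindle.estimate_afferents(
                pcs.mean_strain[movement][antagonist], envs[antagonist],
                "antagonist_lengthening", pcs.cycle_duration_s, params),
        }
    value = spindle.agonist_antagonist_afferent(
        est["df"]["agonist"], est["df"]["antagonist"],
        est["pf"]["agonist"], est["pf"]["antagonist"])
    return {"agonist_antagonist_afferent": value, "estimates": est}


def afferent_table(subjects: list[dict],
                   params: spindle.SpindleParams | None = None,
                   n_cycles: int = 10) -> pd.DataFrame:
    """Estimated agonist-antagonist afferents for every synthetic subject
    (phantom cycles generated from each subject's archetype spec)."""
    taps = design_bandpass(2000.0)
    rows = []
    for s in subjects:
        pcs = synth.generate_phantom_cycles(s["spec"], n_cycles, params)
        stat = phantom_afferent_statistic(pcs, params, taps)
        rows.append({
            "subject": s["subject"], "group": s["group"],
            "afferent_estimated": stat["agonist_antagonist_afferent"],
            "afferent_target": s["spec"].afferent_level,
            "units": "Imp/s",
        })
    return pd.DataFrame(rows)


def closed_loop_level_walking(coordination: float = 1.0, n_cycles: int = 4,
                              cycle_duration_s: float = 1.1, seed: int = 5,
                              noise_sd: float = 0.0) -> tuple:
    """Closed-loop level-walking simulation through the whole stack.

    Synthetic TA/GAS EMG (plantar-flexor burst through stance peaking
    near push-off, dorsiflexor bursts around heel strike and swing) is
    scaled by ``coordination`` in [0, 1], decoded and fed to the
    impedance controller driving the ankle plant against a stance-phase
    dorsiflexing ground-load schedule.  Returns ``(trial, last_cycle)``
    where ``last_cycle`` is the final stride as a GaitCycle.

    Well-coordinated activation yields a counterclockwise work loop with
    positive net work (push-off against the fading ground load); at low
    coordination the loop degenerates toward passive, dissipative motion.
    """
    calib = DecoderCalibration(10.0, 20.0, 10.0, 20.0)
    model = BioTorqueModel()
    stance_end = 62.0

    def load(pct: float) -> float:
        return 1.4 * np.sin(np.pi * pct / stance_end) if pct <= stance_end else 0.0

    fs_emg = 2000.0
    n = int(round(n_cycles * cycle_duration_s * fs_emg))
    pct = (np.arange(n) / fs_emg / cycle_duration_s * 100.0) % 100.0

    def g(c, w):
        return np.exp(-(((pct - c) / w) ** 2))

    # low coordination = mistimed bursts (amplitude alone cancels in the
    # per-record min/max normalization, as it would in device calibration)
    k = float(np.clip(coordination, 0.0, 1.0))
    prof = {
        "gas": np.clip(k * (0.95 * g(45, 14) + 0.3 * g(20, 10))
                       + (1 - k) * 0.8 * g(78, 10), 0, 1),
        "ta": np.clip(k * (0.55 * g(80, 9) + 0.35 * g(3, 4) + 0.35 * g(99, 3))
                      + (1 - k) * 0.6 * g(40, 12), 0, 1),
    }
    emg_rec = synth.generate_emg(prof, fs_emg, noise_sd, seed=seed)
    plant_cfg = plant_mod.PlantConfig(ground_load_schedule=load)
    trial = plant_mod.simulate_gait(emg_rec.channels, fs_emg, calib, model,
                                    plant_cfg, "level_max", n_cycles,
                                    cycle_duration_s, stance_end, seed)
    fs = trial.sample_rate
    i0 = int(round((n_cycles - 1) * cycle_duration_s * fs))
    i1 = int(round(n_cycles * cycle_duration_s * fs))
    t = np.arange(i1 - i0) / fs
    last = gait.normalize_cycle(t, trial.angle[i0:i1], trial.torque[i0:i1],
                                plant_cfg.body_mass,
                                stance_end_pct=stance_end,
                                condition="level_max")
    return trial, last


def _wa_pu_windows(cycle: gait.GaitCycle) -> tuple[tuple, tuple]:
    """Stair analysis windows: weight acceptance = contact to the stance
    DF maximum; pull-up = stance DF maximum to end of stance."""
    st = (gait.GRID <= cycle.stance_end_pct)
    df_max_pct = float(gait.GRID[st][np.argmax(cycle.angle[st])])
    return (0.0, df_max_pct), (df_max_pct, cycle.stance_end_pct)


def trial_metrics(trial: synth.SyntheticTrial) -> dict:
    """Every reported biomechanical metric for one trial."""
    c = synth.trial_to_gait_cycle(trial)
    sym = gait.lek_symmetry(trial.kinematics_ipsi, trial.kinematics_contra)
    out = {"speed": trial.speed, "lek_symmetry": sym.lek_symmetry,
           "rom": gait.rom(trial.angle)}
    if trial.condition == "stair_down":
        wa, _ = _wa_pu_windows(c)
        out["peak_power"] = gait.peak_power(c, "negative")
        out["net_work"] = gait.net_work(c, wa)
        ev = gait.segment_stair_events(c, "descent")
    elif trial.condition == "stair_up":
        _, pu = _wa_pu_windows(c)
        out["peak_power"] = gait.peak_power(c, "positive")
        out["net_work"] = gait.net_work(c, pu)
        ev = gait.segment_stair_events(c, "ascent")
    else:
        out["peak_power"] = gait.peak_power(c, "positive")
        out["net_work"] = gait.net_work(c)
        ev = gait.segment_level_events(c)
    for name, mag in ev.magnitudes.items():
        out[f"event_{name}"] = mag
    loop = gait.torque_angle_loop(c)
    out["loop_area"] = loop["area"]
    out["loop_direction"] = loop["direction"]
    return out


def cohort_table(subjects: list[dict],
                 conditions: tuple[str, ...] = synth.CONDITIONS,
                 afferents: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wide subject x metric cohort table.

    One row per subject: group, agonist-antagonist afferent (estimated
    through the pipeline when ``afferents`` is given, otherwise the
    archetype target), then ``{condition}_{metric}`` columns, plus the
    obstacle swing-kinematics delta and recovery-step metrics when the
    perturbation conditions are present.
    """
    aff_map = {}
    if afferents is not None:
        aff_map = dict(zip(afferents["subject"], afferents["afferent_estimated"]))
    rows = []
    for s in subjects:
        row = {"subject": s["subject"], "group": s["group"],
               "afferent": aff_map.get(s["subject"], s["afferent"])}
        for cond in conditions:
            tr = s["trials"][cond]
            for k, v in trial_metrics(tr).items():
                if k != "loop_direction":
                    row[f"{cond}_{k}"] = v
        if "obstacle" in conditions and "unperturbed_baseline" in conditions:
            pert = synth.trial_to_gait_cycle(s["trials"]["obstacle"])
            base = synth.trial_to_gait_cycle(s["trials"]["unperturbed_baseline"])
            row["obstacle_swing_delta"] = gait.obstacle_swing_delta([pert], [base])
            rec = gait.recovery_step_metrics(pert)
            row["recovery_peak_power"] = rec["peak_power"]
            row["recovery_net_work"] = rec["net_work"]
        rows.append(row)
    return pd.DataFrame(rows)


#: stair-descent absorption metrics carry a biomimetic-negative sign
PCA_FLIP_COLUMNS = ("stair_down_peak_power", "stair_down_net_work")


def cohort_report(table: pd.DataFrame,
                  correlate: tuple[str, ...] = ("level_max_peak_power",
                                                "level_max_net_work",
                                                "level_max_lek_symmetry",
                                                "level_max_speed")) -> dict:
    """Cohort-level analysis: afferent-function correlations, the PC1
    composite functionality score, AMI-vs-CTL group comparisons, and the
    worked-example derived statistics from the published cohort means."""
    out = {"n": len(table), "correlations": {}, "group_comparisons": {}}
    for col in correlate:
        if col not in table.columns:
            raise ValueError(f"metric column {col!r} missing from cohort table")
        res = cohort_mod.pearson_with_ci(table["afferent"], table[col])
        out["correlations"][col] = {
            "r": res.r, "ci_95": list(res.ci_95), "slope": res.slope,
            "p": res.p, "n": res.n,
        }
    metric_cols = [c for c in table.columns
                   if c not in ("subject", "group", "afferent")
                   and table[c].dtype != object]
    flips = tuple(c for c in PCA_FLIP_COLUMNS if c in metric_cols)
    sign_col = ("level_max_peak_power"
                if "level_max_peak_power" in metric_cols else metric_cols[0])
    comp = cohort_mod.pca_composite(table[metric_cols].set_axis(table["subject"]),
                                    flip_columns=flips, sign_column=sign_col)
    out["pc1"] = {
        "variance_explained": comp.variance_explained,
        "scores": comp.pc1_scores.to_dict(),
        "loadings": comp.pc1_loadings.to_dict(),
    }
    pc1_corr = cohort_mod.pearson_with_ci(
        table["afferent"], comp.pc1_scores.to_numpy())
    out["correlations"]["pc1"] = {"r": pc1_corr.r, "ci_95": list(pc1_corr.ci_95),
                                  "slope": pc1_corr.slope, "p": pc1_corr.p,
                                  "n": pc1_corr.n}
    ami = table[table["group"] == "AMI"]
    ctl = table[table["group"] == "CTL"]
    if len(ami) >= 3 and len(ctl) >= 3:
        fam_cols = [c for c in ("level_max_peak_power", "level_max_net_work",
                                "level_max_speed", "level_max_lek_symmetry")
                    if c in table.columns]
        fam = cohort_mod.group_compare_family(
            [(ami[c].to_numpy(), ctl[c].to_numpy()) for c in fam_cols])
        for c, res in zip(fam_cols, fam):
            out["group_comparisons"][c] = {
                "test": res.test, "p": res.p, "p_adjusted": res.p_adjusted,
            }
    out["derived_statistics"] = {
        k: (v if np.isscalar(v) else v)
        for k, v in reference.derived_statistics().items()
    }
    return out
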