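"""Published cohort summary statistics used as worked-example inputs.

These are the reported cohort means (and biologically intact reference
values from the gait literature) for the two amputee cohorts: AMI
(agonist-antagonist myoneural interface amputation, n = 7) and CTL
(standard amputation, n = 7; perturbation subset n = 4 AMI / n = 6 CTL).
They are inputs to the derived-statistics layer — every headline
percentage or difference is recomputed from them at run time, never
stored.
"""

from __future__ import annotations

from .cohort import absolute_increase, percent_increase, restoration_ratio

__all__ = ["COHORT_MEANS", "derived_statistics"]

COHORT_MEANS = {
    # level-ground walking at each cohort's maximum speed
    "max_speed_m_s": {"ami": 1.78, "ctl": 1.26},
    "peak_power_w_kg": {"ami": 1.95, "ctl": 0.68, "intact": 3.0},
    "net_work_j_kg": {"ami": 0.174, "ctl": -0.049, "intact": 0.267},
    "lek_symmetry_pct": {"ami": 84.9, "intact": 91.4},
    # residual-limb agonist-antagonist muscle afferents
    "afferent_imp_s": {"ami": 10.5, "ctl": 0.09, "intact": 60.0},
    # obstacle-crossing recovery step and perturbed walking
    "recovery_peak_power_w_kg": {"ami": 1.01, "ctl": 0.45},
    "recovery_net_work_j_kg": {"ami": 0.125, "ctl": -0.016},
    "perturbed_speed_m_s": {"ami": 0.94, "ctl": 0.61},
}


def derived_statistics(means: dict | None = None) -> dict:
    """Recompute every headline derived statistic from the cohort means.

    Returns percent increases (AMI over CTL), absolute net-work
    differences (J/kg) and restoration ratios against biologically
    intact values, each as produced by the cohort-statistics operations.
    """
    m = means or COHORT_MEANS
    return {
        "max_speed_increase_pct": percent_increase(
            m["max_speed_m_s"]["ami"], m["max_speed_m_s"]["ctl"]),
        "peak_power_increase_pct": percent_increase(
            m["peak_power_w_kg"]["ami"], m["peak_power_w_kg"]["ctl"]),
        "net_work_increase_j_kg": absolute_increase(
            m["net_work_j_kg"]["ami"], m["net_work_j_kg"]["ctl"]),
        "peak_power_restoration_pct": restoration_ratio(
            m["peak_power_w_kg"]["ami"], m["peak_power_w_kg"]["intact"]),
        "lek_restoration_pct": restoration_ratio(
            m["lek_symmetry_pct"]["ami"], m["lek_symmetry_pct"]["intact"]),
        "afferent_restoration_pct": restoration_ratio(
            m["afferent_imp_s"]["ami"], m["afferent_imp_s"]["intact"]),
        "recovery_power_increase_pct": percent_increase(
            m["recovery_peak_power_w_kg"]["ami"],
            m["recovery_peak_power_w_kg"]["ctl"]),
        "recovery_work_increase_j_kg": absolute_increase(
            m["recovery_net_work_j_kg"]["ami"],
            m["recovery_net_work_j_kg"]["ctl"]),
        "perturbed_speed_increase_pct": percent_increase(
            m["perturbed_speed_m_s"]["ami"], m["perturbed_speed_m_s"]["ctl"]),
    }
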