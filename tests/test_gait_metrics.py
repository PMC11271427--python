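"""Gait metrics: normalization, event segmentation, energetics, work
loops, symmetry and perturbation metrics."""

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

from bionicgait import synth
from bionicgait.gait import (GRID, GaitCycle, lek_symmetry, net_work,
                             normalize_cycle, obstacle_swing_delta,
                             peak_power, recovery_step_metrics, rom,
                             segment_level_events, segment_stair_events,
                             torque_angle_loop)


def planted_cycle(knots, stance_end=62.0, duration=1.0, torque=None):
    """Angle trace through (pct, deg) knots with extrema exactly at the
    knots (monotone interpolation between them)."""
    pts = np.array(knots, dtype=float)
    angle = PchipInterpolator(pts[:, 0], pts[:, 1])(GRID)
    tq = torque if torque is not None else np.zeros(GRID.size)
    return GaitCycle(angle, tq, stance_end, duration)


def brute_level_landmarks(angle, stance_end):
    """Independent landmark search: plain loop over samples."""
    n_st = int(np.searchsorted(GRID, stance_end, side="right"))
    first_min = None
    for i in range(1, n_st - 1):
        if angle[i] < angle[i - 1] and angle[i] < angle[i + 1]:
            first_min = i
            break
    i_max = max(range(n_st), key=lambda i: angle[i])
    return first_min, i_max, n_st - 1


class TestNormalizeCycle:
    def test_identity_on_normalized_input(self):
        t = np.linspace(0.0, 1.0, GRID.size)
        angle = np.sin(2 * np.pi * GRID / 100) * 10
        tq = np.cos(2 * np.pi * GRID / 100)
        c = normalize_cycle(t, angle, tq, 1.0, torque_is_mass_normalized=True)
        np.testing.assert_allclose(c.angle, angle, atol=1e-9)
        np.testing.assert_allclose(c.torque, tq, atol=1e-9)

    def test_mass_normalization(self):
        t = np.linspace(0.0, 1.0, 500)
        c = normalize_cycle(t, np.zeros(500), np.full(500, 150.0), mass=75.0)
        np.testing.assert_allclose(c.torque, 2.0)

    def test_resampling_preserves_net_work(self, rng):
        # dense irregular sampling vs the fixed grid: < 0.1% difference
        t = np.sort(rng.uniform(0.0, 1.0, 4000))
        t[0], t[-1] = 0.0, 1.0
        angle = 10 * np.sin(2 * np.pi * t) + 3 * np.sin(4 * np.pi * t)
        tq = 1.2 * np.sin(2 * np.pi * t + 0.8)
        omega = np.gradient(np.radians(angle), t)
        direct = np.trapezoid(tq * omega, t)
        c = normalize_cycle(t, angle, tq, 1.0, torque_is_mass_normalized=True)
        assert net_work(c) == pytest.approx(direct, rel=1e-3)

    def test_spurious_cycle_rejected(self):
        t = np.linspace(0.0, 0.1, 100)
        with pytest.raises(ValueError, match="spurious"):
            normalize_cycle(t, np.zeros(100), np.zeros(100), 70.0)


class TestLevelEvents:
    def test_planted_landmarks_match_hand_values(self):
        c = planted_cycle([(0, 0), (8, -5), (45, 12), (62, -18), (100, 0)])
        ev = segment_level_events(c)
        assert ev.magnitudes["HS"] == pytest.approx(5.0, abs=0.05)
        assert ev.magnitudes["LR"] == pytest.approx(17.0, abs=0.05)
        assert ev.magnitudes["PO"] == pytest.approx(30.0, abs=0.05)
        assert ev.magnitudes["FC"] == pytest.approx(18.0, abs=0.05)
        assert ev.directions == {"HS": "PF", "LR": "DF", "PO": "PF", "FC": "DF"}

    def test_matches_brute_force_landmark_search(self):
        c = planted_cycle([(0, 1), (10, -6), (40, 9), (62, -15), (85, 4), (100, -1)])
        ev = segment_level_events(c)
        i_min, i_max, i_end = brute_level_landmarks(c.angle, c.stance_end_pct)
        assert ev.magnitudes["HS"] == pytest.approx(c.angle[0] - c.angle[i_min])
        assert ev.magnitudes["LR"] == pytest.approx(c.angle[i_max] - c.angle[i_min])
        assert ev.magnitudes["PO"] == pytest.approx(c.angle[i_max] - c.angle[i_end])
        assert ev.magnitudes["FC"] == pytest.approx(c.angle[-1] - c.angle[i_end])

    def test_flat_trace_flags_degenerate(self):
        c = GaitCycle(np.zeros(GRID.size), np.zeros(GRID.size), 62.0, 1.0)
        ev = segment_level_events(c)
        assert "HS" not in ev.magnitudes  # no PF local max in stance
        assert "HS" in ev.absent
        assert any("degenerate" in a for a in ev.absent)

    def test_biomimetic_archetype_enlarges_push_off_and_clearance(self):
        hi = synth.generate_gait_trial(
            synth.ArchetypeSpec("AMI", 10.5, 1.0, 0.0, 3), "level_max")
        lo = synth.generate_gait_trial(
            synth.ArchetypeSpec("CTL", -1.0, 0.0, 0.0, 3), "level_max")
        ev_hi = segment_level_events(synth.trial_to_gait_cycle(hi))
        ev_lo = segment_level_events(synth.trial_to_gait_cycle(lo))
        assert ev_hi.magnitudes["PO"] > ev_lo.magnitudes["PO"]
        assert ev_hi.magnitudes["FC"] > ev_lo.magnitudes["FC"]

    def test_time_reparameterization_leaves_excursions_unchanged(self):
        c1 = planted_cycle([(0, 0), (8, -5), (45, 12), (62, -18), (100, 0)],
                           duration=1.0)
        c2 = planted_cycle([(0, 0), (8, -5), (45, 12), (62, -18), (100, 0)],
                           duration=1.7)
        assert segment_level_events(c1).magnitudes == \
            segment_level_events(c2).magnitudes


class TestStairEvents:
    def test_planted_descent_landmarks(self):
        c = planted_cycle([(0, -12), (40, 10), (100, -14)], stance_end=65.0)
        ev = segment_stair_events(c, "descent")
        assert ev.magnitudes["WA"] == pytest.approx(22.0, abs=0.05)
        assert ev.magnitudes["FCo"] == pytest.approx(24.0, abs=0.05)

    def test_ascent_without_stance_df_max_flags_absent(self):
        angle = np.linspace(5.0, -10.0, GRID.size)  # monotone PF from contact
        ev = segment_stair_events(GaitCycle(angle, np.zeros(GRID.size),
                                            65.0, 1.0), "ascent")
        assert "WA" in ev.absent

    def test_descent_wa_exceeds_level_lr_for_ami_archetype(self):
        spec = synth.ArchetypeSpec("AMI", 10.5, 0.9, 0.0, 11)
        stair = synth.trial_to_gait_cycle(
            synth.generate_gait_trial(spec, "stair_down"))
        level = synth.trial_to_gait_cycle(
            synth.generate_gait_trial(spec, "level_max"))
        wa = segment_stair_events(stair, "descent").magnitudes["WA"]
        lr = segment_level_events(level).magnitudes["LR"]
        assert wa > lr

    def test_bad_direction_rejected(self):
        c = planted_cycle([(0, -12), (40, 10), (100, -14)], stance_end=65.0)
        with pytest.raises(ValueError):
            segment_stair_events(c, "sideways")


class TestEnergetics:
    def test_peak_power_signs_on_sine(self):
        p = 2.0 * np.sin(2 * np.pi * GRID / 100)
        c = GaitCycle(np.zeros(GRID.size), np.zeros(GRID.size), 62.0, 1.0,
                      power=p)
        assert peak_power(c, "positive") == pytest.approx(2.0, rel=1e-3)
        assert peak_power(c, "negative") == pytest.approx(-2.0, rel=1e-3)

    def test_no_sample_of_requested_sign_gives_zero(self):
        c = GaitCycle(np.zeros(GRID.size), np.zeros(GRID.size), 62.0, 1.0,
                      power=-np.ones(GRID.size))
        assert peak_power(c, "positive") == 0.0

    def test_peak_matches_exhaustive_scan(self, rng):
        p = rng.standard_normal(GRID.size)
        c = GaitCycle(np.zeros(GRID.size), np.zeros(GRID.size), 62.0, 1.0,
                      power=p)
        assert peak_power(c, "positive") == max(p.max(), 0.0)

    def test_net_work_of_symmetric_sine_is_zero(self):
        p = np.sin(2 * np.pi * GRID / 100)
        c = GaitCycle(np.zeros(GRID.size), np.zeros(GRID.size), 62.0, 1.0,
                      power=p)
        assert net_work(c) == pytest.approx(0.0, abs=1e-9)

    def test_constant_power_closed_form(self):
        c = GaitCycle(np.zeros(GRID.size), np.zeros(GRID.size), 62.0, 1.0,
                      power=np.ones(GRID.size))
        assert net_work(c) == pytest.approx(1.0)

    def test_inverted_window_rejected(self):
        c = GaitCycle(np.zeros(GRID.size), np.zeros(GRID.size), 62.0, 1.0)
        with pytest.raises(ValueError, match="inverted"):
            net_work(c, (70.0, 30.0))


class TestWorkLoop:
    @staticmethod
    def _circle_cycle(reverse=False):
        # a circle in the work-loop plotting plane (angle, PF-positive
        # torque), traversed counterclockwise: area +pi*r^2
        th = np.linspace(0.0, 2 * np.pi, GRID.size)
        if reverse:
            th = th[::-1]
        r_deg = 5.0
        angle = r_deg * np.cos(th)
        torque_plot = r_deg * np.pi / 180.0 * np.sin(th)
        return GaitCycle(angle, -torque_plot, 62.0, 1.0)

    def test_ccw_circle_area_is_pi_r_squared(self):
        r = np.radians(5.0)
        loop = torque_angle_loop(self._circle_cycle())
        assert loop["direction"] == "ccw"
        assert loop["area"] == pytest.approx(np.pi * r * r, rel=1e-3)

    def test_reversed_circle_flips_sign(self):
        fwd = torque_angle_loop(self._circle_cycle())
        rev = torque_angle_loop(self._circle_cycle(reverse=True))
        assert rev["direction"] == "cw"
        assert rev["area"] == pytest.approx(-fwd["area"], rel=1e-9)

    def test_area_equals_net_work_on_synthetic_cycle(self):
        spec = synth.ArchetypeSpec("AMI", 10.5, 0.85, 0.0, 5)
        c = synth.trial_to_gait_cycle(
            synth.generate_gait_trial(spec, "level_max"))
        assert torque_angle_loop(c)["area"] == pytest.approx(
            net_work(c), rel=0.005)

    def test_open_loop_flagged(self):
        angle = np.linspace(-5.0, 5.0, GRID.size)
        loop = torque_angle_loop(GaitCycle(angle, np.ones(GRID.size), 62.0, 1.0))
        assert loop["closed_by_segment"]


class TestSymmetry:
    def test_identical_limbs_score_100(self):
        kin = {j: np.sin(2 * np.pi * GRID / 100) * a
               for j, a in (("ankle", 10), ("knee", 30), ("hip", 20))}
        res = lek_symmetry(kin, {j: x.copy() for j, x in kin.items()})
        assert res.lek_symmetry == pytest.approx(100.0)

    def test_offset_degrades_monotonically(self):
        base = {j: 20 * np.sin(2 * np.pi * GRID / 100) + 5
                for j in ("ankle", "knee", "hip")}
        scores = []
        for off in (0.0, 2.0, 5.0, 10.0):
            contra = {j: x + off for j, x in base.items()}
            scores.append(lek_symmetry(base, contra).lek_symmetry)
        assert scores[0] == pytest.approx(100.0)
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_two_point_hand_computation(self):
        # trapezoid integrals over the percent grid, done by hand:
        # ipsi = 2, contra = 4 constant => SI = 100*|2|/((4+2)/2) = 66.67
        ipsi = {j: np.full(GRID.size, 2.0) for j in ("ankle", "knee", "hip")}
        contra = {j: np.full(GRID.size, 4.0) for j in ("ankle", "knee", "hip")}
        res = lek_symmetry(ipsi, contra)
        assert res.si == pytest.approx(200.0 / 3.0, rel=1e-9)
        assert res.lek_symmetry == pytest.approx(100.0 - 200.0 / 3.0, rel=1e-6)

    def test_limb_exchange_symmetry(self, rng):
        a = {j: rng.standard_normal(GRID.size) for j in ("ankle", "knee", "hip")}
        b = {j: rng.standard_normal(GRID.size) for j in ("ankle", "knee", "hip")}
        assert lek_symmetry(a, b).si == pytest.approx(lek_symmetry(b, a).si)

    def test_missing_joint_rejected(self):
        kin = {"ankle": np.zeros(GRID.size)}
        with pytest.raises(ValueError, match="missing joints"):
            lek_symmetry(kin, kin)


class TestRomAndPerturbation:
    def test_rom_constant_sine_and_brute(self, rng):
        assert rom(np.full(100, 3.0)) == 0.0
        assert rom(7 * np.sin(np.linspace(0, 4 * np.pi, 500))) == \
            pytest.approx(14.0, rel=1e-3)
        x = rng.standard_normal(300)
        assert rom(x) == x.max() - x.min()

    def test_identical_sets_give_zero_delta(self):
        c = GaitCycle(np.sin(2 * np.pi * GRID / 100) * 8, np.zeros(GRID.size),
                      62.0, 1.0)
        assert obstacle_swing_delta([c], [c]) == 0.0

    def test_planted_offset_recovered(self):
        base = GaitCycle(np.sin(2 * np.pi * GRID / 100) * 8,
                         np.zeros(GRID.size), 62.0, 1.0)
        shifted = GaitCycle(base.angle + 4.0 * (GRID > 62.0),
                            np.zeros(GRID.size), 62.0, 1.0)
        assert obstacle_swing_delta([shifted], [base]) == pytest.approx(4.0)

    def test_ctl_archetype_can_reduce_swing_dorsiflexion(self):
        spec = synth.ArchetypeSpec("CTL", -1.29, 0.0, 0.0, 21)
        pert = [synth.trial_to_gait_cycle(
            synth.generate_gait_trial(spec, "obstacle"))]
        base = [synth.trial_to_gait_cycle(
            synth.generate_gait_trial(spec, "unperturbed_baseline"))]
        assert obstacle_swing_delta(pert, base) < 0.0

    def test_recovery_metrics_delegate(self):
        p = np.sin(2 * np.pi * GRID / 100)
        c = GaitCycle(np.zeros(GRID.size), np.zeros(GRID.size), 62.0, 1.0,
                      power=p)
        rec = recovery_step_metrics(c)
        assert rec["peak_power"] == peak_power(c, "positive")
        assert rec["net_work"] == net_work(c)

    def test_zero_trace_zero_recovery(self):
        c = GaitCycle(np.zeros(GRID.size), np.zeros(GRID.size), 62.0, 1.0)
        rec = recovery_step_metrics(c)
        assert rec == {"peak_power": 0.0, "net_work": 0.0}
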