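"""Synthetic study-condition generator: EMG round trip, phantom cycles,
gait trial families and cohort sampling."""

import numpy as np
import pytest

from bionicgait import gait, pipeline, synth
from bionicgait.emg import emg_envelope


class TestGenerateEmg:
    def test_zero_profile_zero_noise_gives_silence(self):
        rec = synth.generate_emg(np.zeros(4000), 2000.0, 0.0, seed=3)
        assert np.all(rec.channels["emg"] == 0.0)

    def test_seed_contract(self):
        p = {"ta": np.full(4000, 0.5), "gas": np.full(4000, 0.2)}
        a = synth.generate_emg(p, 2000.0, 0.1, seed=7)
        b = synth.generate_emg(p, 2000.0, 0.1, seed=7)
        c = synth.generate_emg(p, 2000.0, 0.1, seed=8)
        np.testing.assert_array_equal(a.channels["ta"], b.channels["ta"])
        assert not np.array_equal(a.channels["ta"], c.channels["ta"])

    def test_boxcar_round_trip_through_envelope_chain(self, taps):
        fs = 2000.0
        t = np.arange(int(8 * fs)) / fs
        profile = ((t >= 2.0) & (t < 6.0)).astype(float)
        rec = synth.generate_emg(profile, fs, 0.0, seed=7)
        env = emg_envelope(rec.channels["emg"], fs, taps=taps)
        away = np.ones(t.size, dtype=bool)
        for edge in (0.0, 2.0, 6.0, 8.0):
            away &= np.abs(t - edge) > 0.3
        assert np.abs(env - profile)[away].max() < 0.05

    def test_interference_is_rejected_by_the_filter(self, taps):
        # 50 Hz hum plus white noise should barely perturb the envelope
        fs = 2000.0
        t = np.arange(int(8 * fs)) / fs
        profile = ((t >= 2.0) & (t < 6.0)).astype(float)
        rec = synth.generate_emg(profile, fs, 0.05, seed=7)
        env = emg_envelope(rec.channels["emg"], fs, taps=taps)
        away = np.ones(t.size, dtype=bool)
        for edge in (0.0, 2.0, 6.0, 8.0):
            away &= np.abs(t - edge) > 0.3
        assert np.abs(env - profile)[away].max() < 0.1

    def test_non_finite_profile_rejected(self):
        bad = np.zeros(100)
        bad[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            synth.generate_emg(bad, 2000.0)


class TestArchetypeSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            synth.ArchetypeSpec("XYZ", 1.0, 0.5)
        with pytest.raises(ValueError):
            synth.ArchetypeSpec("AMI", np.inf, 0.5)
        with pytest.raises(ValueError):
            synth.ArchetypeSpec("AMI", 1.0, 1.5)


class TestPhantomCycles:
    def test_exactly_n_cycles_emitted(self):
        spec = synth.ArchetypeSpec("AMI", 10.5, 0.9, 0.0, 1)
        pcs = synth.generate_phantom_cycles(spec, n_cycles=10)
        for movement in ("df", "pf"):
            assert pcs.strain[movement]["ta"].shape[0] == 10
            n_emg = pcs.emg[movement].n_samples
            assert n_emg == 10 * int(pcs.cycle_duration_s * 2000)

    def test_ami_coupling_is_anti_phase(self):
        spec = synth.ArchetypeSpec("AMI", 10.5, 0.9, 0.0, 1)
        pcs = synth.generate_phantom_cycles(spec)
        ta = pcs.mean_strain["df"]["ta"].strain
        gas = pcs.mean_strain["df"]["gas"].strain
        assert gas[40:61].min() > 0.0   # antagonist lengthens
        assert ta[40:61].max() < 0.0    # agonist shortens
        r = np.corrcoef(ta, gas)[0, 1]
        assert r < -0.95

    def test_ctl_cycles_are_more_variable(self):
        ami = synth.generate_phantom_cycles(
            synth.ArchetypeSpec("AMI", 10.5, 0.9, 0.05, 1))
        ctl = synth.generate_phantom_cycles(
            synth.ArchetypeSpec("CTL", 0.1, 0.1, 0.05, 1))
        var_ami = ami.strain["df"]["gas"].std(axis=0).mean()
        var_ctl = ctl.strain["df"]["gas"].std(axis=0).mean()
        assert var_ctl > var_ami

    @pytest.mark.parametrize("group, target", [("AMI", 10.5), ("CTL", 0.0)])
    def test_downstream_statistic_matches_target(self, group, target):
        spec = synth.ArchetypeSpec(group, target, 0.5, 0.0, 7)
        pcs = synth.generate_phantom_cycles(spec, n_cycles=5)
        stat = pipeline.phantom_afferent_statistic(pcs)
        got = stat["agonist_antagonist_afferent"]
        if target == 0.0:
            assert abs(got) < 0.5
        else:
            assert got == pytest.approx(target, rel=0.10)

    def test_bad_cycle_count_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_phantom_cycles(
                synth.ArchetypeSpec("AMI", 10.5, 0.9), n_cycles=0)


class TestGaitTrials:
    def test_biomimetic_loop_is_ccw_with_positive_work(self):
        spec = synth.ArchetypeSpec("AMI", 11.9, 1.0, 0.0, 2)
        c = synth.trial_to_gait_cycle(
            synth.generate_gait_trial(spec, "level_max"))
        loop = gait.torque_angle_loop(c)
        assert loop["direction"] == "ccw" and gait.net_work(c) > 0.0

    def test_non_biomimetic_loop_is_cw_and_dissipative(self):
        spec = synth.ArchetypeSpec("CTL", -1.3, 0.0, 0.0, 2)
        c = synth.trial_to_gait_cycle(
            synth.generate_gait_trial(spec, "level_max"))
        loop = gait.torque_angle_loop(c)
        assert loop["direction"] == "cw" and gait.net_work(c) <= 0.0

    def test_unknown_condition_lists_valid_labels(self):
        spec = synth.ArchetypeSpec("AMI", 10.5, 0.9)
        with pytest.raises(ValueError, match="level_max"):
            synth.generate_gait_trial(spec, "moonwalk")

    def test_net_work_monotone_in_biomimeticness(self):
        works = []
        for b in np.linspace(0.0, 1.0, 11):
            spec = synth.ArchetypeSpec("AMI", 10.5, float(b), 0.0, 4)
            c = synth.trial_to_gait_cycle(
                synth.generate_gait_trial(spec, "level_max"))
            works.append(gait.net_work(c))
        assert np.all(np.diff(works) >= -1e-9)

    def test_determinism_same_spec_same_bytes(self):
        spec = synth.ArchetypeSpec("AMI", 10.5, 0.8, 0.05, 77)
        t1 = synth.generate_gait_trial(spec, "slope_up")
        t2 = synth.generate_gait_trial(spec, "slope_up")
        np.testing.assert_array_equal(t1.angle, t2.angle)
        np.testing.assert_array_equal(t1.torque, t2.torque)
        np.testing.assert_array_equal(t1.emg.channels["ta"],
                                      t2.emg.channels["ta"])
        assert t1.speed == t2.speed

    def test_symmetry_degrades_with_biomimeticness(self):
        scores = []
        for b in (1.0, 0.5, 0.0):
            spec = synth.ArchetypeSpec("AMI", 10.5, b, 0.0, 4)
            tr = synth.generate_gait_trial(spec, "level_max")
            scores.append(gait.lek_symmetry(tr.kinematics_ipsi,
                                            tr.kinematics_contra).lek_symmetry)
        assert scores[0] > scores[1] > scores[2]


class TestCohortSampling:
    def test_seven_per_group_gives_fourteen(self):
        table = synth.generate_cohort(n_per_group=7, seed=1)
        assert len(table) == 14
        assert set(table["group"]) == {"AMI", "CTL"}
        assert not table["subject"].duplicated().any()

    def test_null_slope_gives_no_correlation(self):
        from bionicgait.cohort import pearson_with_ci
        table = synth.generate_cohort(
            n_per_group=50, slope_spec={"metric": (1.0, 0.0)},
            noise=1.0, seed=5)
        res = pearson_with_ci(table["afferent"], table["metric"])
        assert abs(res.r) < 0.25

    def test_zero_noise_lies_exactly_on_the_line(self):
        table = synth.generate_cohort(
            n_per_group=5, slope_spec={"metric": (0.5, 2.0)}, noise=0.0,
            seed=2)
        np.testing.assert_allclose(table["metric"],
                                   0.5 + 2.0 * table["afferent"])

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            synth.generate_cohort(afferent_range=(3.0, 3.0))

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_cohort(n_per_group=1)
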