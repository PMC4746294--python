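import numpy as np
import pytest

import flightlearn as fl
from flightlearn import eeg_spectral as es
from flightlearn.cluster_perm import build_adjacency, permutation_test
from flightlearn.errors import ConfigurationError
from flightlearn.flight_metrics import control_inputs, landing_gforce
from flightlearn.nback import replay_levels, score_log
from flightlearn.synthetic_data import (autopilot_reference, default_channel_map,
                                        generate_eeg, generate_flight_trace,
                                        generate_nback_log, generate_study)


class TestAutopilotReference:
    def test_profile_matches_briefing(self, autopilot):
        # constant -600 ft/min for the majority of the approach
        frac_at_600 = np.mean(autopilot.vspeed == -600.0)
        assert frac_at_600 > 0.9
        # vertical speed changes only in the final 5 s
        flare = autopilot.vspeed[:-50]
        assert np.all(flare == -600.0)
        assert autopilot.alt[0] == pytest.approx(800.0)
        assert autopilot.alt[-1] == 0.0

    def test_single_flare_control_input(self, autopilot):
        assert control_inputs(autopilot) == 1

    def test_touches_down_at_threshold_origin(self, autopilot):
        i = autopilot.touchdown_index
        assert i == len(autopilot) - 1
        assert autopilot.lat[i] == pytest.approx(47.46)


class TestGenerateFlightTrace:
    def test_infinite_skill_reproduces_reference(self, autopilot):
        tr = generate_flight_trace(float("inf"), autopilot, np.random.default_rng(0))
        assert np.array_equal(tr.vspeed, autopilot.vspeed)
        assert np.array_equal(tr.alt, autopilot.alt)
        assert fl.path_deviation(tr, autopilot) == pytest.approx(0.0, abs=1e-9)
        assert fl.vspeed_deviation(tr, autopilot) == 0.0

    def test_higher_skill_smaller_deviations(self, autopilot):
        devs = {}
        for skill in (0.5, 8.0):
            rng = np.random.default_rng(1)
            d = [fl.vspeed_deviation(generate_flight_trace(skill, autopilot, rng),
                                     autopilot) for _ in range(10)]
            devs[skill] = np.mean(d)
        assert devs[8.0] < devs[0.5]

    def test_missed_landing_never_touches_down(self, autopilot):
        tr = generate_flight_trace(1.0, autopilot, np.random.default_rng(2),
                                   miss_prob=1.0)
        assert tr.missed and tr.touchdown_index is None
        assert tr.alt.min() > 0

    def test_touchdown_has_impact_gforce(self, autopilot):
        rng = np.random.default_rng(3)
        g = landing_gforce(generate_flight_trace(1.0, autopilot, rng))
        assert np.isfinite(g) and g > 0


class TestGenerateStudy:
    def test_default_design_thirty_two_subjects(self):
        study = generate_study(seed=1)
        assert len(study.subjects) == 32
        assert study.design.n_days == 4
        counts = study.subjects.group.value_counts()
        assert counts["M1_stim"] == 10 and counts["DLPFC_stim"] == 7

    def test_same_seed_identical_outputs(self, small_study, small_design):
        other = generate_study(small_design, seed=7)
        for subj in small_study.nback_logs:
            a, b = small_study.nback_logs[subj], other.nback_logs[subj]
            assert a.levels() == b.levels()
            for ba, bb in zip(a.blocks, b.blocks):
                assert np.array_equal(ba.position_correct, bb.position_correct)
        tr_a = small_study.flight_traces[("S01", 1)][0]
        tr_b = other.flight_traces[("S01", 1)][0]
        assert np.array_equal(tr_a.vspeed, tr_b.vspeed)
        assert np.array_equal(small_study.eeg("S01", 2).data,
                              other.eeg("S01", 2).data)
        ra, _ = small_study.fnirs("S01", 1)
        rb, _ = other.fnirs("S01", 1)
        assert np.array_equal(ra.od[760.0], rb.od[760.0])

    def test_different_seeds_differ(self, small_study, small_design):
        other = generate_study(small_design, seed=8)
        tr_a = small_study.flight_traces[("S01", 1)][0]
        tr_b = other.flight_traces[("S01", 1)][0]
        assert not np.array_equal(tr_a.vspeed, tr_b.vspeed)

    def test_ground_truth_complete(self, small_study):
        gt = small_study.ground_truth
        assert set(gt["subjects"]) == set(small_study.subjects["subject"])
        for info in gt["subjects"].values():
            assert np.isfinite(info["online_rate"])
            assert len(info["theta_power_by_day"]) == 4

    def test_invalid_group_rejected(self):
        with pytest.raises(ConfigurationError):
            fl.StudyDesign(groups=(("hippocampus", 3),))

    def test_nback_logs_replay_consistently(self, small_study):
        for log in small_study.nback_logs.values():
            assert replay_levels(log) == log.levels()


class TestVarianceShrinkGroundTruth:
    def test_quarter_shrink_halves_true_rate_sd(self):
        # Monte-Carlo over replicate cohorts: between-subject SD of the TRUE
        # online rates under shrink 0.25 is half the sham SD
        stim_rates, sham_rates = [], []
        for rep in range(120):
            st = generate_study(
                fl.StudyDesign(groups=(("DLPFC_stim", 7), ("DLPFC_sham", 7))),
                seed=40_000 + rep)
            for s, info in st.ground_truth["subjects"].items():
                (stim_rates if info["group"] == "DLPFC_stim" else sham_rates
                 ).append(info["online_rate"])
        ratio = np.std(stim_rates, ddof=1) / np.std(sham_rates, ddof=1)
        assert ratio == pytest.approx(0.5, rel=0.12)


class TestGenerateEeg:
    def test_fixed_seed_identical(self):
        labels = list(fl.load_layout()["label"])
        r1 = generate_eeg(labels, 4.0, 4.0, np.random.default_rng(5), duration_s=2)
        r2 = generate_eeg(labels, 4.0, 4.0, np.random.default_rng(5), duration_s=2)
        assert np.array_equal(r1.data, r2.data)

    def test_quadrupled_theta_power_ratio_recovered(self):
        labels = list(fl.load_layout()["label"])
        i, j = labels.index("Fz"), labels.index("FC1")
        cells = []
        for power, seed in ((4.0, 6), (16.0, 7)):
            rec = generate_eeg(labels, power, 4.0, np.random.default_rng(seed),
                               duration_s=20)
            cell = es.band_power_cell(es.highpass(rec).data, rec.fs)
            cells.append((cell["theta"][i] + cell["theta"][j]) / 2)
        assert cells[1] / cells[0] == pytest.approx(4.0, rel=0.1)

    def test_zero_oscillation_null_rarely_clusters(self):
        labels = list(fl.load_layout()["label"])
        adj = build_adjacency(fl.load_layout())
        rng = np.random.default_rng(8)
        hits = 0
        n_runs = 12
        for run in range(n_runs):
            powers = []
            for subj in range(8):
                rec = generate_eeg(labels, 0.0, 0.0, rng, duration_s=4)
                powers.append(es.band_power_cell(rec.data, rec.fs)["theta"])
            res = permutation_test(np.array(powers[:4]), np.array(powers[4:]),
                                   adj, n_perm=200, rng=rng)
            hits += bool(res.significant_clusters())
        assert hits <= 2  # nominal 5% familywise rate, small-sample slack


class TestGenerateFnirsStudyLevel:
    def test_channel_map_matches_montage(self):
        cmap = default_channel_map()
        assert len(cmap.channels) == 20
        rois = list(cmap.roi.values())
        assert rois.count("M1") == 10 and rois.count("DLPFC") == 10
        assert all(d <= 3.5 for d in cmap.distance_cm.values())

    def test_overlarge_concentration_rejected(self):
        from flightlearn.synthetic_data import generate_fnirs
        with pytest.raises(ConfigurationError):
            generate_fnirs(default_channel_map(), np.random.default_rng(0),
                           {"DLPFC": 0.1})

    def test_zero_change_zero_noise_zero_od(self):
        from flightlearn.synthetic_data import generate_fnirs
        rec, _ = generate_fnirs(default_channel_map(), np.random.default_rng(0),
                                {"DLPFC": 0.0, "M1": 0.0}, od_noise_sd=0.0,
                                drift=False, cardiac=False)
        assert np.allclose(rec.od[760.0], 0) and np.allclose(rec.od[850.0], 0)


class TestNbackGeneratorModes:
    def test_exactly_one_mode_required(self, small_design):
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigurationError):
            generate_nback_log(None, small_design, rng)
        with pytest.raises(ConfigurationError):
            generate_nback_log(2.0, small_design, rng,
                               target_scaled=np.zeros((4, 6)))

    def test_target_mode_mean_scaled_accuracy_unbiased(self, small_design):
        from flightlearn.synthetic_data import nback_target_line
        rng = np.random.default_rng(1)
        targets = nback_target_line(25.0, 1.0, np.ones(3), small_design)
        scaled = []
        for _ in range(150):
            log = generate_nback_log(None, small_design, rng,
                                     target_scaled=targets)
            scaled.append(score_log(log)["scaled_combined"].to_numpy())
        mean_traj = np.mean(scaled, axis=0)
        assert np.allclose(mean_traj, targets.ravel(), atol=1.2)
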