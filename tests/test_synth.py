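import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from evacpanic import (
    CohortConfig,
    EmotionProfile,
    EyeProfile,
    FnirsNoiseSpec,
    assign_sequences,
    binned_gaze_entropy,
    build_timeline,
    eye_metrics,
    fit_session,
    simulate_cohort,
    simulate_emotions,
    simulate_eye,
    simulate_fnirs,
)
from evacpanic.synth import SynthError
from evacpanic.timeline import round_window


class TestDeterminism:
    def test_eye_stream_bit_identical_under_seed(self, timeline):
        a = simulate_eye(timeline, seed=7)
        b = simulate_eye(timeline, seed=7)
        np.testing.assert_array_equal(a.pupil_left, b.pupil_left)
        np.testing.assert_array_equal(a.gaze_x, b.gaze_x)
        np.testing.assert_array_equal(a.fixation_left, b.fixation_left)

    def test_fnirs_bit_identical_under_seed(self, timeline):
        beta = np.full((3, 8), 4.0)
        a = simulate_fnirs(timeline, beta, seed=7)
        b = simulate_fnirs(timeline, beta, seed=7)
        np.testing.assert_array_equal(a.hbo, b.hbo)

    def test_cohort_manifests_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_participants=2, seed=3)
        simulate_cohort(cfg, tmp_path / "a")
        simulate_cohort(cfg, tmp_path / "b")
        for name in ("manifest.json", "emotions.csv", "P001/eye.csv",
                     "P002/fnirs.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestEyeGenerator:
    def test_noiseless_amplitude_recovery(self, timeline):
        profile = EyeProfile().noiseless()
        rec = simulate_eye(timeline, profile, seed=1)
        amps = (
            eye_metrics(rec, timeline)
            .query("metric == 'dilation_amplitude'")
            .set_index("scenario")["value"]
        )
        for scen, truth in profile.amplitude.items():
            assert amps[scen] == pytest.approx(truth, rel=1e-6)

    def test_single_point_regime_zero_entropy(self, timeline):
        profile = dataclasses.replace(
            EyeProfile().noiseless(),
            scanning_weight={s: 0.0 for s in ("Roaming", "Alarm", "Smoke", "Flame")},
            n_clusters=1,
        )
        rec = simulate_eye(timeline, profile, seed=1)
        win = round_window(timeline, 1, timeline.eye_rate)
        xs = rec.gaze_x[win[0]:win[1]]
        assert np.unique(xs).size == 1
        assert binned_gaze_entropy(rec, win) == pytest.approx(0.0, abs=1e-12)

    def test_blink_rate_and_fraction_match_config(self, timeline):
        profile = EyeProfile()
        events, fracs = [], []
        for seed in range(5):
            rec = simulate_eye(timeline, profile, seed=seed)
            blink = np.isnan(rec.pupil_left)
            events.append(int((blink[1:] & ~blink[:-1]).sum() + blink[0]))
            fracs.append(blink.mean())
        # blink onsets are a Poisson process: rate · duration arrivals expected
        expected_events = profile.blink_rate * timeline.session_duration / 60.0
        total = sum(events)
        assert abs(total - 5 * expected_events) < 4 * np.sqrt(5 * expected_events)
        # time fraction = rate · mean duration, up to sample-rounding bias
        expected_frac = (profile.blink_rate / 60.0) * (
            profile.blink_shape * profile.blink_scale
        )
        assert np.mean(fracs) == pytest.approx(expected_frac, rel=0.25)

    def test_blink_convention(self, timeline):
        rec = simulate_eye(timeline, EyeProfile(), seed=2)
        blink = np.isnan(rec.pupil_left)
        assert not rec.fixation_left[blink].any()
        assert not rec.saccade_left[blink].any()
        assert np.isnan(rec.gaze_x[blink]).all()

    def test_flags_mutually_exclusive(self, timeline):
        rec = simulate_eye(timeline, EyeProfile(), seed=2)
        assert not (rec.fixation_left & rec.saccade_left).any()

    def test_missing_scenario_profile_rejected(self, timeline):
        profile = dataclasses.replace(EyeProfile(), amplitude={"Alarm": 1.4})
        with pytest.raises(SynthError, match="missing scenario"):
            simulate_eye(timeline, profile, seed=0)

    def test_entropy_increases_with_scanning_weight(self, timeline):
        weights = [0.05, 0.3, 0.6, 0.95]
        means = []
        for w in weights:
            vals = []
            for seed in range(4):
                profile = dataclasses.replace(
                    EyeProfile(),
                    scanning_weight={s: w for s in
                                     ("Roaming", "Alarm", "Smoke", "Flame")},
                )
                rec = simulate_eye(timeline, profile, seed=seed)
                m = eye_metrics(rec, timeline)
                vals.append(m.query("metric == 'gaze_entropy'")["value"].mean())
            means.append(np.mean(vals))
        rho, _ = spearmanr(weights, means)
        assert rho > 0

    def test_amplitude_increases_with_configured_bump(self, timeline):
        peaks = [1.1, 1.3, 1.5, 1.8]
        recovered = []
        for p in peaks:
            profile = dataclasses.replace(
                EyeProfile().noiseless(),
                amplitude={"Alarm": p, "Smoke": p, "Flame": p},
            )
            rec = simulate_eye(timeline, profile, seed=0)
            m = eye_metrics(rec, timeline)
            recovered.append(
                m.query("metric == 'dilation_amplitude'")["value"].mean()
            )
        rho, _ = spearmanr(peaks, recovered)
        assert rho == 1.0


class TestFnirsGenerator:
    def test_noiseless_identifiability_single_channel(self, timeline):
        beta = np.array([[5.0], [3.0], [4.0]])
        rec = simulate_fnirs(timeline, beta, FnirsNoiseSpec.silent(), seed=0)
        est = fit_session(rec, timeline)
        np.testing.assert_allclose(est.beta, beta, rtol=1e-9)

    def test_null_beta_fits_near_zero(self, timeline):
        rec = simulate_fnirs(timeline, np.zeros((3, 8)), FnirsNoiseSpec(), seed=5)
        est = fit_session(rec, timeline)
        assert np.abs(est.beta).max() < 1.0

    def test_bad_beta_shape_rejected(self, timeline):
        with pytest.raises(SynthError):
            simulate_fnirs(timeline, np.ones((2, 8)), seed=0)

    def test_negative_noise_amplitude_rejected(self):
        with pytest.raises(SynthError):
            FnirsNoiseSpec(white_sd=-1.0)


class TestEmotionGenerator:
    def test_scores_within_scale(self):
        df = simulate_emotions(n=20, seed=0)
        assert df["score"].between(1, 9).all()
        assert set(df["scenario"]) == {"Roaming", "Alarm", "Smoke", "Flame"}

    def test_zero_sd_shifts_are_deterministic_rounded(self):
        profile = EmotionProfile(
            baseline_mean={t: 2.0 for t in EmotionProfile().baseline_mean},
            baseline_sd=0.0,
            shift_mean={t: {"Alarm": 3.67, "Smoke": 2.14, "Flame": 2.49}
                        for t in EmotionProfile().baseline_mean},
            shift_sd={t: {"Alarm": 0.0, "Smoke": 0.0, "Flame": 0.0}
                      for t in EmotionProfile().baseline_mean},
        )
        df = simulate_emotions(profile, n=3, seed=0)
        wide = df.pivot_table(index=["participant", "term"],
                              columns="scenario", values="score")
        assert (wide["Roaming"] == 2).all()
        assert (wide["Alarm"] - wide["Roaming"] == round(2 + 3.67) - 2).all()
        assert (wide["Smoke"] - wide["Roaming"] == round(2 + 2.14) - 2).all()

    def test_zero_shift_everywhere(self):
        base = EmotionProfile()
        profile = EmotionProfile(
            baseline_sd=0.0,
            shift_mean={t: {s: 0.0 for s in ("Alarm", "Smoke", "Flame")}
                        for t in base.baseline_mean},
            shift_sd={t: {s: 0.0 for s in ("Alarm", "Smoke", "Flame")}
                      for t in base.baseline_mean},
        )
        df = simulate_emotions(profile, n=2, seed=0)
        wide = df.pivot_table(index=["participant", "term"],
                              columns="scenario", values="score")
        for scen in ("Alarm", "Smoke", "Flame"):
            assert (wide[scen] == wide["Roaming"]).all()

    def test_clamping_at_scale_top(self):
        base = EmotionProfile()
        profile = EmotionProfile(
            baseline_mean={t: 9.0 for t in base.baseline_mean},
            baseline_sd=0.0,
            shift_mean={t: {s: 5.0 for s in ("Alarm", "Smoke", "Flame")}
                        for t in base.baseline_mean},
            shift_sd={t: {s: 0.0 for s in ("Alarm", "Smoke", "Flame")}
                      for t in base.baseline_mean},
        )
        df = simulate_emotions(profile, n=2, seed=0)
        assert (df["score"] == 9).all()  # realized shift clamps to 0

    def test_n_below_one_rejected(self):
        with pytest.raises(SynthError):
            simulate_emotions(n=0, seed=0)


class TestCohort:
    def test_default_sequence_split_is_26_15_15(self):
        seqs = assign_sequences(56)
        assert seqs.count("Alarm-Smoke-Flame") == 26
        assert seqs.count("Smoke-Flame-Alarm") == 15
        assert seqs.count("Flame-Alarm-Smoke") == 15

    def test_split_rescales_with_n(self):
        seqs = assign_sequences(8)
        assert len(seqs) == 8
        assert seqs.count("Alarm-Smoke-Flame") >= seqs.count("Smoke-Flame-Alarm")

    def test_small_cohort_on_disk(self, tmp_path):
        manifest = simulate_cohort(CohortConfig(n_participants=2, seed=1), tmp_path)
        assert manifest["n_participants"] == 2
        stored = json.loads((tmp_path / "manifest.json").read_text())
        assert [p["id"] for p in stored["participants"]] == ["P001", "P002"]
        eye_df = pd.read_csv(tmp_path / "P001" / "eye.csv")
        assert {"pupil_area_L", "gaze_x_px", "fixation_R"} <= set(eye_df.columns)
        fnirs_df = pd.read_csv(tmp_path / "P001" / "fnirs.csv")
        assert fnirs_df.shape == (3600, 9)  # time + 8 channels

    def test_cohort_size_validated(self):
        with pytest.raises(SynthError):
            CohortConfig(n_participants=1)
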