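import numpy as np
import pytest

from evacpanic import (
    FnirsNoiseSpec,
    FnirsRecording,
    HrfModel,
    bandpass,
    build_regressor,
    build_timeline,
    canonical_hrf,
    estimate_beta,
    fit_session,
    simulate_fnirs,
)
from evacpanic.fnirs import FnirsError
from evacpanic.synth import BETA_MEAN


def fit_sinusoid_amplitude(x, rate, freq):
    """Oracle: amplitude of a sinusoid via least squares on a sin/cos basis."""
    t = np.arange(len(x)) / rate
    basis = np.column_stack([np.sin(2 * np.pi * freq * t),
                             np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return float(np.hypot(*coef))


class TestHrf:
    def test_peak_near_5s_on_dense_grid(self):
        t = np.arange(0, 35, 0.01)
        h = HrfModel().evaluate(t)
        assert t[h.argmax()] == pytest.approx(5.0, abs=0.5)

    def test_undershoot_minimum_near_16s(self):
        t = np.arange(0, 35, 0.01)
        h = HrfModel().evaluate(t)
        assert t[h.argmin()] == pytest.approx(16.0, abs=0.5)

    def test_sampled_peak_is_exactly_one(self):
        for rate in (10.0, 60.0):
            assert canonical_hrf(rate=rate).max() == 1.0

    def test_starts_at_zero(self):
        assert canonical_hrf(rate=10.0)[0] == 0.0

    def test_negligible_beyond_30s(self):
        t = np.arange(30.0, 60.0, 0.01)
        assert np.abs(HrfModel().evaluate(t)).max() <= 0.02

    def test_mistimed_parameters_rejected(self):
        with pytest.raises(FnirsError, match="peak"):
            HrfModel(peak_shape=9.0)  # positive lobe would peak at 8 s
        with pytest.raises(FnirsError, match="undershoot"):
            HrfModel(undershoot_shape=24.0, support=40.0)

    def test_sample_count(self):
        assert len(canonical_hrf(rate=10.0)) == 300


class TestRegressor:
    def test_onset_at_zero_is_padded_hrf(self, timeline):
        tl = build_timeline(roaming_duration=0.0)
        h = canonical_hrf(rate=10.0)
        f = build_regressor(tl, 1, h, 3600, 10.0)
        np.testing.assert_array_equal(f[: len(h)], h)
        assert not f[len(h):].any()

    def test_zero_before_onset(self, timeline):
        h = canonical_hrf(rate=10.0)
        f = build_regressor(timeline, 2, h, 3600, 10.0)
        onset = int(200 * 10)
        assert not f[:onset].any()
        np.testing.assert_array_equal(f[onset:onset + len(h)], h)

    def test_onset_beyond_recording_rejected(self, timeline):
        h = canonical_hrf(rate=10.0)
        with pytest.raises(FnirsError, match="outside"):
            build_regressor(timeline, 3, h, 1000, 10.0)

    def test_supports_disjoint_at_80s_spacing(self, timeline):
        # 80 s apart vs 30 s support: each stimulus stands alone
        h = canonical_hrf(rate=10.0)
        fs = [build_regressor(timeline, i, h, 3600, 10.0) for i in (1, 2, 3)]
        for fa, fb in [(0, 1), (0, 2), (1, 2)]:
            assert float(fs[fa] @ fs[fb]) == 0.0


class TestBandpass:
    RATE = 10.0
    N = 6000  # 600 s

    def _tone(self, freq, amp=1.0):
        t = np.arange(self.N) / self.RATE
        return amp * np.sin(2 * np.pi * freq * t)

    def test_midband_tone_preserved(self):
        x = self._tone(0.05)
        out = fit_sinusoid_amplitude(bandpass(x, self.RATE), self.RATE, 0.05)
        assert out == pytest.approx(1.0, rel=0.05)

    def test_cardiac_tone_attenuated_20db(self):
        x = self._tone(1.0)
        out = fit_sinusoid_amplitude(bandpass(x, self.RATE), self.RATE, 1.0)
        assert out <= 0.1  # ≥ 20 dB down

    def test_dc_removed(self):
        out = bandpass(np.full(self.N, 7.0), self.RATE)
        assert np.abs(out).max() < 0.07  # < 1% of input level

    def test_zero_phase(self):
        # a mid-band tone keeps its phase: correlation with input is positive
        # and the filtered peak is not delayed
        x = self._tone(0.05)
        y = bandpass(x, self.RATE)
        lag = np.argmax(np.correlate(y, x, "full")) - (self.N - 1)
        assert lag == 0

    def test_output_length_preserved(self):
        x = self._tone(0.03)
        assert bandpass(x, self.RATE).shape == x.shape

    def test_invalid_band_rejected(self):
        with pytest.raises(FnirsError):
            bandpass(self._tone(0.05), self.RATE, low=0.2, high=0.1)

    def test_rate_below_nyquist_rejected(self):
        with pytest.raises(FnirsError):
            bandpass(self._tone(0.05), rate=0.15)

    def test_too_short_signal_rejected(self):
        with pytest.raises(FnirsError, match="short"):
            bandpass(np.ones(5), self.RATE)


class TestEstimateBeta:
    def test_exact_scaling(self):
        f = canonical_hrf(rate=10.0)
        assert estimate_beta(2.0 * f, f) == pytest.approx(2.0)

    def test_orthogonal_gives_zero(self):
        h = canonical_hrf(rate=10.0)
        f = np.concatenate([h, np.zeros_like(h)])
        y = np.concatenate([np.zeros_like(h), h])  # same HRF past the support
        assert estimate_beta(y, f) == pytest.approx(0.0, abs=1e-15)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 400))
            f = rng.normal(size=n)
            y = rng.normal(size=n)
            expected, *_ = np.linalg.lstsq(f[:, None], y, rcond=None)
            assert estimate_beta(y, f) == pytest.approx(expected[0], abs=1e-9)

    def test_linearity_in_y(self, rng):
        f = rng.normal(size=200)
        y1, y2 = rng.normal(size=(2, 200))
        a, b = 2.5, -1.25
        assert estimate_beta(a * y1 + b * y2, f) == pytest.approx(
            a * estimate_beta(y1, f) + b * estimate_beta(y2, f)
        )

    def test_scale_covariance(self, rng):
        """Doubling the regressor halves β̂ — why the HRF is unit-peak."""
        f = rng.normal(size=200)
        y = rng.normal(size=200)
        assert estimate_beta(y, 2 * f) == pytest.approx(0.5 * estimate_beta(y, f))

    def test_zero_regressor_rejected(self):
        with pytest.raises(FnirsError):
            estimate_beta(np.ones(10), np.zeros(10))

    def test_length_mismatch_rejected(self):
        with pytest.raises(FnirsError):
            estimate_beta(np.ones(10), np.ones(11))


class TestSeparability:
    def test_joint_equals_separate_for_disjoint_supports(self, timeline, rng):
        """With onsets 80 s apart and 30 s support, the three scalar
        projections coincide with a joint 3-column regression."""
        h = canonical_hrf(rate=10.0)
        n = 3600
        fs = np.stack([build_regressor(timeline, i, h, n, 10.0) for i in (1, 2, 3)])
        y = rng.normal(size=n) + fs.T @ np.array([5.0, 3.0, 4.0])
        joint, *_ = np.linalg.lstsq(fs.T, y, rcond=None)
        separate = [estimate_beta(y, f) for f in fs]
        np.testing.assert_allclose(joint, separate, atol=1e-9)


class TestFitSession:
    def test_noiseless_recovery_of_cohort_truth(self, timeline):
        true = np.array([BETA_MEAN[s] for s in timeline.stimulus_labels])
        rec = simulate_fnirs(timeline, true, FnirsNoiseSpec.silent(), seed=0)
        est = fit_session(rec, timeline)
        np.testing.assert_allclose(est.beta, true, rtol=1e-9)

    def test_all_zero_recording_gives_zero_beta(self, timeline):
        rec = FnirsRecording(hbo=np.zeros((3600, 8)))
        est = fit_session(rec, timeline)
        np.testing.assert_allclose(est.beta, 0.0, atol=1e-12)

    def test_channel_permutation_equivariance(self, timeline, rng):
        true = rng.normal(4.0, 1.5, size=(3, 8))
        rec = simulate_fnirs(timeline, true, FnirsNoiseSpec(), seed=4)
        perm = rng.permutation(8)
        est = fit_session(rec, timeline)
        est_p = fit_session(FnirsRecording(hbo=rec.hbo[:, perm]), timeline)
        np.testing.assert_allclose(est_p.beta, est.beta[:, perm], atol=1e-10)

    def test_scenario_lookup_follows_presentation_order(self):
        tl = build_timeline("Smoke-Flame-Alarm")
        true = np.array([BETA_MEAN[s] for s in tl.stimulus_labels])
        rec = simulate_fnirs(tl, true, FnirsNoiseSpec.silent(), seed=0)
        est = fit_session(rec, tl)
        np.testing.assert_allclose(
            est.by_scenario("Alarm"), BETA_MEAN["Alarm"], rtol=1e-9
        )

    def test_short_recording_rejected(self, timeline):
        rec = FnirsRecording(hbo=np.zeros((1500, 8)))
        with pytest.raises(FnirsError, match="cover"):
            fit_session(rec, timeline)

    def test_separate_mode_close_to_joint_under_noise(self, timeline, rng):
        true = rng.normal(4.0, 1.0, size=(3, 8))
        rec = simulate_fnirs(timeline, true, FnirsNoiseSpec(), seed=9)
        joint = fit_session(rec, timeline, mode="joint").beta
        sep = fit_session(rec, timeline, mode="separate").beta
        # the windowed variant carries filter-leakage bias but stays close
        np.testing.assert_allclose(sep, joint, atol=0.5)
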