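import numpy as np
import pytest
from scipy import signal

from flightlearn.errors import ConfigurationError, DataError
from flightlearn.fnirs import (ChannelMap, ChromophoreSeries, ExtinctionModel,
                               OpticalDensityRecord, bandpass, bandpass_series,
                               baseline_subtract, canonical_hrf, channelwise_sd_test,
                               day_contrast, design_bandpass, event_regressor,
                               exclude_channels, forward_od, glm_betas, mbll_convert)
from flightlearn.synthetic_data import default_channel_map

FS = 8.0


def two_channel_map():
    return ChannelMap(channels=["a", "b"], distance_cm={"a": 3.0, "b": 2.5},
                      roi={"a": "M1", "b": "DLPFC"})


def conc_series(hboxy, hbdeoxy):
    return ChromophoreSeries(np.asarray(hboxy, float), np.asarray(hbdeoxy, float),
                             FS, ["a", "b"])


class TestMbllConvert:
    def test_zero_od_zero_concentration(self):
        cmap = two_channel_map()
        rec = OpticalDensityRecord({760.0: np.zeros((10, 2)), 850.0: np.zeros((10, 2))},
                                   FS, cmap)
        conc = mbll_convert(rec, ExtinctionModel())
        assert np.allclose(conc.hboxy, 0) and np.allclose(conc.hbdeoxy, 0)

    def test_forward_roundtrip_exact_inverse(self):
        rng = np.random.default_rng(0)
        cmap = two_channel_map()
        truth = conc_series(rng.normal(0, 1e-3, (50, 2)), rng.normal(0, 5e-4, (50, 2)))
        rec = forward_od(truth, ExtinctionModel(), cmap)
        back = mbll_convert(rec, ExtinctionModel())
        assert np.allclose(back.hboxy, truth.hboxy, rtol=1e-12, atol=1e-15)
        assert np.allclose(back.hbdeoxy, truth.hbdeoxy, rtol=1e-12, atol=1e-15)

    def test_linearity_doubling_od(self):
        rng = np.random.default_rng(1)
        cmap = two_channel_map()
        od = {760.0: rng.normal(0, 0.01, (20, 2)), 850.0: rng.normal(0, 0.01, (20, 2))}
        c1 = mbll_convert(OpticalDensityRecord(od, FS, cmap), ExtinctionModel())
        od2 = {lam: 2 * v for lam, v in od.items()}
        c2 = mbll_convert(OpticalDensityRecord(od2, FS, cmap), ExtinctionModel())
        assert np.allclose(c2.hboxy, 2 * c1.hboxy)

    def test_hbtot_is_sum_everywhere(self):
        rng = np.random.default_rng(2)
        c = conc_series(rng.normal(size=(30, 2)), rng.normal(size=(30, 2)))
        assert np.array_equal(c.hbtot, c.hboxy + c.hbdeoxy)

    def test_singular_optics_rejected(self):
        bad = ExtinctionModel(epsilon=((1.0, 1.0), (2.0, 2.0)))
        with pytest.raises(ConfigurationError):
            bad.matrix(3.0)

    def test_printed_constants_are_default(self):
        m = ExtinctionModel()
        assert m.epsilon[0] == (1097.0, 781.0)
        assert m.epsilon[1] == (645.5, 1669.0)
        assert m.dpf == (5.98, 7.15)


class TestBandpass:
    taps = design_bandpass(FS)

    def tone_gain(self, freq, n=4000):
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * freq * t)
        y = bandpass(x, FS, taps=self.taps)
        mid = slice(n // 4, 3 * n // 4)
        return np.abs(y[mid]).max() / np.abs(x[mid]).max()

    def test_passband_tone_preserved(self):
        assert self.tone_gain(0.05) == pytest.approx(1.0, abs=0.05)

    def test_cardiac_tone_attenuated_40db(self):
        _, h = signal.freqz(self.taps, worN=[1.2], fs=FS)
        assert 20 * np.log10(np.abs(h[0])) < -40

    def test_dc_removed(self):
        x = np.full(4000, 5.0)
        y = bandpass(x, FS, taps=self.taps)
        # inspect only the full-overlap region (the kernel half-width is 1200)
        assert np.abs(y[1300:2700]).max() < 0.05  # -40 dB residual

    def test_series_shorter_than_filter_rejected(self):
        with pytest.raises(DataError):
            bandpass(np.zeros(100), FS)


class TestExcludeChannels:
    def base(self, swing_b):
        h = np.zeros((40, 2))
        h[:, 1] = np.linspace(0, swing_b, 40)
        return conc_series(h, np.zeros((40, 2)))

    def test_flat_baseline_kept(self):
        assert exclude_channels(self.base(0.0)).all()

    def test_two_microMolar_swing_dropped(self):
        keep = exclude_channels(self.base(0.002))
        assert keep[0] and not keep[1]

    def test_exactly_at_threshold_kept(self):
        # strict inequality: a 0.001 mM swing is retained
        assert exclude_channels(self.base(0.001)).all()


class TestBaselineSubtract:
    def test_constant_series_zeroed(self):
        x = np.full((30, 2), 3.3)
        out = baseline_subtract(x, slice(0, 10))
        assert np.allclose(out, 0)

    def test_additive_shift_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 2))
        out1 = baseline_subtract(x, slice(0, 20))
        out2 = baseline_subtract(x + 7.7, slice(0, 20))
        assert np.allclose(out1, out2)

    def test_hand_computed_toy(self):
        x = np.array([[1.0], [2.0], [3.0], [10.0], [20.0]])
        out = baseline_subtract(x, slice(0, 3))  # baseline mean = 2
        assert np.allclose(out.ravel(), [-1, 0, 1, 8, 18])

    def test_intertrial_samples_excised_from_baseline(self):
        x = np.array([[1.0], [100.0], [3.0], [5.0]])
        mask = np.array([False, True, False, False])
        out = baseline_subtract(x, slice(0, 3), intertrial_mask=mask)
        assert np.allclose(out.ravel(), [-1, 98, 1, 3])  # baseline mean = 2


class TestGlmBetas:
    onsets, durations = [30.0, 90.0, 150.0], [20.0] * 3
    n = int(220 * FS)

    def test_exact_regressor_beta_one(self):
        reg = event_regressor(self.n, FS, self.onsets, self.durations)
        res = glm_betas(reg, FS, self.onsets, self.durations)
        assert res["beta"][0] == pytest.approx(1.0, rel=1e-9)
        assert res["t"][0] > 1e6 or np.isinf(res["t"][0])

    def test_pure_noise_beta_near_zero(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, self.n)
        res = glm_betas(y, FS, self.onsets, self.durations)
        assert abs(res["beta"][0]) < 0.2 and abs(res["t"][0]) < 3.5

    def test_hrf_shaped_response_recovers_amplitude(self):
        rng = np.random.default_rng(5)
        amp = 0.003
        reg = event_regressor(self.n, FS, self.onsets, self.durations)
        y = amp * reg + rng.normal(0, 1e-4, self.n)
        res = glm_betas(y, FS, self.onsets, self.durations)
        assert res["beta"][0] == pytest.approx(amp, rel=0.05)

    def test_rank_deficient_design_rejected(self):
        # a zero-duration event leaves the task regressor identically zero
        with pytest.raises(DataError):
            glm_betas(np.ones(self.n), FS, onsets=[10.0], durations=[0.0])

    def test_onset_outside_series_rejected(self):
        with pytest.raises(DataError):
            event_regressor(100, FS, [1000.0], [10.0])

    def test_hrf_peaks_near_six_seconds(self):
        h = canonical_hrf(FS)
        assert np.argmax(h) / FS == pytest.approx(5.0, abs=1.5)
        assert h.max() == pytest.approx(1.0)
        assert h.min() < 0  # undershoot present


class TestDayContrast:
    def test_identical_days_nothing_significant(self):
        rng = np.random.default_rng(6)
        b = rng.normal(size=(7, 20))
        roi = ["M1"] * 10 + ["DLPFC"] * 10
        out = day_contrast(b, b.copy(), roi)
        assert np.allclose(out["day4_minus_day1"], 0)
        assert (out["n_significant"] == 0).all()

    def test_bonferroni_threshold_for_20_channels(self):
        rng = np.random.default_rng(7)
        b = rng.normal(size=(7, 20))
        roi = ["M1"] * 10 + ["DLPFC"] * 10
        out = day_contrast(b, b + 0.1, roi, family_alpha=0.05)
        assert np.allclose(out["alpha_corrected"], 0.0025)

    def test_injected_roi_decrease_recovered(self):
        rng = np.random.default_rng(8)
        roi = ["M1"] * 10 + ["DLPFC"] * 10
        b1 = rng.normal(0, 0.0002, size=(7, 20))
        b4 = b1 + rng.normal(0, 0.0001, size=(7, 20))
        b4[:, 10:] -= 0.0024  # DLPFC-wide decrease
        out = day_contrast(b1, b4, roi).set_index("roi")
        assert out.loc["DLPFC", "day4_minus_day1"] == pytest.approx(-0.0024, rel=0.2)
        assert out.loc["DLPFC", "n_significant"] >= 9


class TestChannelwiseSdTest:
    def test_zero_mean_not_flagged(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, size=(40, 5))
        out = channelwise_sd_test(x)
        assert out["significant"].sum() <= 1  # chance-level at 3.5 SE

    def test_mean_five_se_flagged(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, size=(100, 1))
        x -= x.mean()
        x += 5 * x.std(ddof=1) / 10  # mean = exactly 5 SE for n=100
        assert channelwise_sd_test(x)["significant"].iloc[0]

    def test_hand_z_on_toy_table(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        out = channelwise_sd_test(x)
        z_hand = 2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2)
        assert out["z"].iloc[0] == pytest.approx(z_hand, rel=1e-12)


def test_pipeline_recovers_true_concentrations_through_drift_and_cardiac():
    from flightlearn.synthetic_data import generate_fnirs
    cmap = default_channel_map()
    rec, truth = generate_fnirs(cmap, np.random.default_rng(11),
                                {"DLPFC": 0.004, "M1": 0.004})
    conc = mbll_convert(rec, ExtinctionModel())
    filt = bandpass_series(conc)
    truth_filt = bandpass_series(truth.conc)
    for j in (0, 7, 13, 19):
        r = np.corrcoef(filt.hboxy[:, j], truth_filt.hboxy[:, j])[0, 1]
        assert r > 0.95
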