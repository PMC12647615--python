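"""Stage-level oracles for the preprocessing pipeline."""

import numpy as np
import pytest
from scipy import signal

import effortnirs as en
from effortnirs.preprocessing import (
    PipelineParams,
    bandpass,
    intensity_to_od,
    od_to_hemoglobin,
    remove_step_noise,
    scalp_coupling_index,
    short_separation_regress,
    wavelet_motion_correct,
)

FS = 10.0


def step_fixture(n=200, step_at=100, magnitude=100.0, base=1000.0):
    x = np.full(n, base)
    x[step_at:] += magnitude
    return x


def manual_step_removal(x, k=2.0):
    """Independent re-computation of the derivative/zero/cumsum rule."""
    d = np.diff(x)
    thr = d.mean() + k * d.std()
    d = np.where(np.abs(d) > thr, 0.0, d)
    return np.concatenate([[x[0]], x[0] + np.cumsum(d)])


class TestStepRemoval:
    def test_linear_ramp_unchanged(self):
        x = np.linspace(0.0, 10.0, 101)
        np.testing.assert_allclose(remove_step_noise(x), x, atol=1e-12)

    def test_matches_hand_computed_oracle(self):
        x = step_fixture()
        got = remove_step_noise(x)
        np.testing.assert_allclose(got, manual_step_removal(x), atol=1e-12)

    def test_step_removed_levels_rejoin(self):
        x = step_fixture()
        got = remove_step_noise(x)
        assert abs(got[-1] - got[0]) < 1e-9
        assert x[-1] - x[0] == pytest.approx(100.0)

    def test_idempotent_on_cleaned_signal(self):
        once = remove_step_noise(step_fixture())
        np.testing.assert_allclose(remove_step_noise(once), once, atol=1e-9)

    def test_short_series_error(self):
        with pytest.raises(ValueError):
            remove_step_noise(np.array([1.0, 2.0]))

    def test_multichannel_shape_preserved(self, rng):
        x = 1 + 0.01 * rng.random((500, 8, 2))
        assert remove_step_noise(x).shape == x.shape


class TestScalpCouplingIndex:
    def test_identical_cardiac_gives_unity(self):
        t = np.arange(0, 60, 1 / FS)
        s = np.sin(2 * np.pi * 1.1 * t)
        assert scalp_coupling_index(s, s, FS) > 0.99

    def test_antiphase_gives_minus_one(self):
        t = np.arange(0, 60, 1 / FS)
        s = np.sin(2 * np.pi * 1.1 * t)
        assert scalp_coupling_index(s, -s, FS) < -0.99

    def test_independent_noise_near_zero(self, rng):
        hits = 0
        n = int(60 * FS)
        reps = 1000
        for _ in range(reps):
            sci = scalp_coupling_index(rng.standard_normal(n), rng.standard_normal(n), FS)
            hits += abs(sci) < 0.3
        assert hits / reps > 0.95

    def test_invariant_to_amplitude_scaling(self, rng):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 1.1 * t) + 0.3 * rng.standard_normal(len(t))
        y = np.sin(2 * np.pi * 1.1 * t) + 0.3 * rng.standard_normal(len(t))
        assert scalp_coupling_index(x, y, FS) == pytest.approx(
            scalp_coupling_index(10 * x, 0.1 * y, FS), abs=1e-12
        )

    def test_zero_variance_warns_and_returns_zero(self):
        flat = np.ones(int(60 * FS))
        with pytest.warns(UserWarning):
            assert scalp_coupling_index(flat, flat, FS) == 0.0


class TestRejection:
    def test_threshold_is_strict_less_than(self, montage):
        # engineer channels just either side of 0.75 from orthogonal sinusoids
        t = np.arange(0, 120, 1 / FS)
        common = np.sin(2 * np.pi * 1.0 * t)
        other = np.sin(2 * np.pi * 1.2 * t)  # orthogonal over the window
        intensity = np.ones((len(t), montage.n_channels, 2))
        rhos = np.linspace(0.55, 0.97, montage.n_channels)
        for c, rho in enumerate(rhos):
            intensity[:, c, 0] += 0.01 * common
            intensity[:, c, 1] += 0.01 * (rho * common + np.sqrt(1 - rho**2) * other)
        rec = en.RawRecording(intensity, FS, en.make_session_design(1, 0).iloc[0:0], montage)
        qc = en.reject_channels(rec, threshold=0.75)
        np.testing.assert_allclose(qc.sci, rhos, atol=0.02)
        np.testing.assert_array_equal(qc.rejected, qc.sci < 0.75)
        assert qc.rejected[0] and not qc.rejected[-1]

    def test_shared_cardiac_rejects_nothing(self, noisy_session):
        rec, _, _ = noisy_session
        qc = en.reject_channels(rec)
        assert qc.fraction_rejected == 0.0

    def test_single_cardiac_free_channel_rejected(self, montage):
        weights = np.ones(8)
        weights[5] = 0.0
        silent = en.HbSeries(np.zeros((900, 8)), np.zeros((900, 8)), FS)
        rec = en.simulate_raw_intensity(
            silent, en.NoiseParams(cardiac_weights=weights), montage, seed=2
        )
        qc = en.reject_channels(rec)
        assert qc.rejected[5]
        assert qc.rejected.sum() == 1


class TestOpticalDensity:
    def test_constant_intensity_gives_zero(self):
        assert np.allclose(intensity_to_od(np.full((100, 1, 1), 7.0)), 0.0)

    def test_halving_jumps_by_ln2(self):
        x = np.ones(100)
        x[50:] = 0.5
        od = intensity_to_od(x)
        assert od[60] - od[40] == pytest.approx(np.log(2), abs=1e-12)

    def test_scale_invariance(self, rng):
        x = 1 + rng.random((200, 2, 2))
        np.testing.assert_allclose(intensity_to_od(3.7 * x), intensity_to_od(x), atol=1e-12)

    def test_nonpositive_sample_names_channel(self):
        x = np.ones((50, 2, 2))
        x[10, 1, 0] = -1.0
        with pytest.raises(ValueError, match="B"):
            intensity_to_od(x, channel_names=["A", "B"])

    def test_mean_referenced(self, rng):
        od = intensity_to_od(1 + rng.random((500, 3, 2)))
        assert np.abs(od.mean(axis=0)).max() < 0.05  # -ln is convex; near zero


class TestWaveletCorrection:
    def test_smooth_polynomial_barely_changed(self):
        t = np.linspace(-1, 1, 512)
        x = 1 + t + 0.5 * t**2
        out = wavelet_motion_correct(x[:, None])
        assert np.abs(out[:, 0] - x).max() / np.abs(x).max() < 0.01

    def test_large_spike_strongly_attenuated(self, rng):
        x = rng.standard_normal(1024)
        x[500] += 50 * x.std()
        out = wavelet_motion_correct(x[:, None])[:, 0]
        assert abs(out[500]) < 0.1 * abs(x[500])

    def test_infinite_iqr_is_identity(self, rng):
        x = rng.standard_normal((600, 2))
        np.testing.assert_allclose(wavelet_motion_correct(x, iqr_k=np.inf), x, atol=1e-8)

    def test_too_short_series_passes_through_with_warning(self):
        x = np.ones((4, 1))
        with pytest.warns(UserWarning):
            out = wavelet_motion_correct(x)
        np.testing.assert_array_equal(out, x)

    def test_length_preserved_odd_sizes(self, rng):
        for n in (257, 500, 1023):
            x = rng.standard_normal((n, 1))
            assert wavelet_motion_correct(x).shape == (n, 1)


class TestBeerLambert:
    def test_zero_od_gives_zero_concentration(self, montage):
        hb = od_to_hemoglobin(np.zeros((100, 8, 2)), montage)
        assert np.all(hb.hbo == 0) and np.all(hb.hbr == 0)

    def test_linearity_in_od(self, montage, rng):
        od = 0.01 * rng.standard_normal((200, 8, 2))
        a = od_to_hemoglobin(od, montage)
        b = od_to_hemoglobin(2.5 * od, montage)
        np.testing.assert_allclose(b.hbo, 2.5 * a.hbo, atol=1e-10)

    def test_doubling_dpf_halves_concentrations(self, montage, rng):
        od = 0.01 * rng.standard_normal((200, 8, 2))
        a = od_to_hemoglobin(od, montage, dpf=6.0)
        b = od_to_hemoglobin(od, montage, dpf=12.0)
        np.testing.assert_allclose(b.hbo, a.hbo / 2, atol=1e-12)


class TestBandpass:
    def _gain(self, f_hz, lo, hi, duration=600.0):
        t = np.arange(0, duration, 1 / FS)
        x = np.sin(2 * np.pi * f_hz * t)
        y = bandpass(x, lo, hi, FS)
        # FFT amplitude at the tone frequency
        k = int(round(f_hz * duration))
        return np.abs(np.fft.rfft(y))[k] / np.abs(np.fft.rfft(x))[k]

    def test_dc_removed(self):
        x = np.full(2000, 5.0)
        assert abs(bandpass(x, 0.01, 0.09, FS).mean()) < 1e-6

    def test_passband_gain_narrow_band(self):
        assert self._gain(0.05, 0.01, 0.09) >= 0.9

    def test_cardiac_rejected_by_narrow_band(self):
        assert self._gain(1.1, 0.01, 0.09) <= 0.05

    def test_wide_band_gain_at_centre_and_cardiac(self):
        # zero-phase application squares the magnitude response, so the
        # passband guarantee holds at the band centre; cardiac near the upper
        # edge is still substantially passed
        assert self._gain(0.12, 0.01, 1.5) >= 0.9
        assert self._gain(1.1, 0.01, 1.5) >= 0.8

    def test_invalid_band_raises(self):
        with pytest.raises(ValueError):
            bandpass(np.ones(100), 0.09, 0.01, FS)
        with pytest.raises(ValueError):
            bandpass(np.ones(100), 0.01, 6.0, FS)


class TestShortSeparationRegression:
    def test_orthogonal_regressor_leaves_signal(self):
        t = np.arange(0, 100, 1 / FS)
        long = np.sin(2 * np.pi * 0.05 * t)
        short = np.sin(2 * np.pi * 0.10 * t)  # orthogonal over integer periods
        resid, beta = short_separation_regress(long, short)
        assert abs(beta) < 1e-6
        np.testing.assert_allclose(resid, long, atol=1e-6)

    def test_contaminated_signal_recovered(self, rng):
        t = np.arange(0, 300, 1 / FS)
        neural = np.sin(2 * np.pi * 0.03 * t)
        short = rng.standard_normal(len(t))
        resid, beta = short_separation_regress(neural + 0.8 * short, short)
        assert beta == pytest.approx(0.8, abs=0.02)
        rmse = np.sqrt(np.mean((resid - (neural - neural.mean())) ** 2))
        assert rmse < 0.05 * neural.std()

    def test_pure_superficial_gives_zero_residual(self, rng):
        short = rng.standard_normal(1000)
        resid, beta = short_separation_regress(2.0 * short, short)
        assert beta == pytest.approx(2.0, abs=1e-10)
        assert np.abs(resid).max() < 1e-10

    def test_residual_orthogonal_to_regressor(self, rng):
        long = rng.standard_normal(2000)
        short = 0.5 * long + rng.standard_normal(2000)
        resid, _ = short_separation_regress(long, short)
        r = np.corrcoef(resid, short)[0, 1]
        assert abs(r) < 1e-8


class TestFullPipeline:
    def test_stage_order_is_enforced(self, noisy_session):
        rec, _, _ = noisy_session
        params = PipelineParams(stages=tuple(reversed(en.CANONICAL_STAGES)))
        with pytest.raises(ValueError, match="order"):
            en.run_pipeline(rec, params)

    def test_all_channels_rejected_aborts(self, noisy_session):
        rec, _, _ = noisy_session
        with pytest.raises(ValueError, match="rejected"):
            en.run_pipeline(rec, PipelineParams(sci_threshold=1.01))

    def test_sample_count_and_rate_preserved(self, pipeline_output):
        rec, hb, _ = pipeline_output
        assert hb.hbo.shape[0] == rec.n_times
        assert hb.fs == rec.fs

    def test_clean_simulation_recovers_amplitude(self, clean_session):
        # artifact thresholds disabled: outlier-based stages assume artifact
        # spread, which noiseless data lacks by construction
        rec, _, truth = clean_session
        params = PipelineParams(k_sd=100.0, iqr_k=np.inf)
        hb, _ = en.run_pipeline(rec, params)
        tbl = en.build_trial_table(hb, rec.events, rec.montage, qc=None)
        ca = en.condition_average(tbl).pivot(index="subregion", columns="condition", values="hbdiff")
        contrast = ca.loc["left_lateral", "standard"] - ca.loc["left_lateral", "dnn"]
        assert contrast == pytest.approx(truth.condition_effect_um(), rel=0.10)

    def test_noisy_simulation_recovers_contrast(self, pipeline_output, noisy_session):
        rec, hb, qc = pipeline_output
        _, _, truth = noisy_session
        tbl = en.build_trial_table(hb, rec.events, rec.montage, qc)
        ca = en.condition_average(tbl).pivot(index="subregion", columns="condition", values="hbdiff")
        contrast = ca.loc["left_lateral", "standard"] - ca.loc["left_lateral", "dnn"]
        assert contrast == pytest.approx(truth.condition_effect_um(), rel=0.25)

    def test_qc_report_records_all_stages(self, pipeline_output):
        _, _, qc = pipeline_output
        log = " ".join(qc.stage_log)
        for stage in en.CANONICAL_STAGES:
            assert stage in log
        d = qc.to_dict()
        assert len(d["channels"]) == 8
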