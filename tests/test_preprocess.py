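"""Preprocessing chain: OD conversion, wavelet artifact correction,
zero-phase band-pass, Beer-Lambert inversion, CBSI."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from nirsentropy import (
    PreprocessParams,
    SyntheticCohortConfig,
    bandpass,
    cbsi_correct,
    forward_mbll,
    generate_cohort,
    intensity_to_od,
    od_to_hemoglobin,
    preprocess_cohort,
    preprocess_recording,
    wavelet_motion_correct,
)
from nirsentropy.preprocess import _wavelet_correct_1d
from nirsentropy.recording import (
    OpticalDensitySeries,
    PhaseWindows,
    RawIntensityRecording,
)

FS = 10.0


def _recording_from_intensities(inten):
    n_ch, _, n_t = inten.shape
    return RawIntensityRecording(
        intensities=inten,
        wavelengths=(690.0, 830.0),
        sampling_rate=FS,
        source_detector_distance_cm=np.full(n_ch, 3.0),
        events=PhaseWindows((("rest1", 0, n_t),)),
        subject_id="T01",
        group_label=0,
    )


class TestIntensityToOD:
    def test_constant_intensity_gives_zero_od(self):
        rec = _recording_from_intensities(np.full((2, 2, 100), 3.7))
        od = intensity_to_od(rec)
        np.testing.assert_allclose(od.od, 0.0, atol=1e-15)

    def test_known_attenuation(self):
        inten = np.full((1, 2, 1000), 1.0)
        inten[0, 0, 500] = 10 ** (-0.02)
        rec = _recording_from_intensities(inten)
        od = intensity_to_od(rec)
        assert od.od[0, 0, 500] == pytest.approx(0.02, abs=1e-4)

    def test_scale_invariance(self):
        inten = np.random.default_rng(0).uniform(0.5, 1.5, (2, 2, 200))
        od1 = intensity_to_od(_recording_from_intensities(inten)).od
        od2 = intensity_to_od(_recording_from_intensities(2.0 * inten)).od
        np.testing.assert_allclose(od1, od2, atol=1e-12)

    def test_nonpositive_intensity_names_location(self):
        inten = np.full((2, 2, 50), 1.0)
        rec = _recording_from_intensities(inten)
        rec.intensities[1, 0, 7] = -1.0
        with pytest.raises(ValueError, match="channel 1.*sample 7"):
            intensity_to_od(rec)


class TestWaveletMotionCorrect:
    def test_smooth_signal_preserved(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        out = _wavelet_correct_1d(x, "db5", 4, 1.5)
        assert np.corrcoef(out, x)[0, 1] > 0.99

    def test_spike_suppressed_sinusoid_kept(self):
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        xa = x.copy()
        xa[1500] += 10 * x.std()
        out = _wavelet_correct_1d(xa, "db5", 4, 1.5)
        spike_residual = abs(out[1500] - x[1500])
        assert spike_residual <= 0.1 * abs(xa[1500] - x[1500])
        # passband amplitude preserved within 5%
        assert out.std() == pytest.approx(x.std(), rel=0.05)

    def test_infinite_iqr_factor_is_identity(self):
        x = np.random.default_rng(1).standard_normal(512)
        out = _wavelet_correct_1d(x, "db5", 4, np.inf)
        np.testing.assert_allclose(out, x, atol=1e-10)

    def test_energy_never_increased(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.standard_normal(777)
            x[rng.integers(0, 777)] += 30.0
            out = _wavelet_correct_1d(x, "db5", 4, 1.5)
            assert np.sum(out**2) <= np.sum(x**2) * (1 + 1e-12)

    def test_short_series_passes_through_with_warning(self):
        od = OpticalDensitySeries(
            od=np.random.default_rng(0).standard_normal((1, 2, 8)),
            wavelengths=(690.0, 830.0), sampling_rate=FS,
            source_detector_distance_cm=np.array([3.0]),
            events=PhaseWindows((("rest1", 0, 8),)),
            subject_id="T", group_label=0,
        )
        with pytest.warns(RuntimeWarning, match="too short"):
            out = wavelet_motion_correct(od)
        np.testing.assert_array_equal(out.od, od.od)


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass(np.full(6000, 5.0), FS)
        assert np.abs(out).max() < 5.0 * 1e-3

    def test_passband_gain_near_unity(self):
        t = np.arange(60000) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        out = bandpass(x, FS)
        mid = slice(5000, 55000)
        gain = out[mid].std() / x[mid].std()
        assert gain == pytest.approx(1.0, rel=0.02)

    def test_cardiac_attenuated_at_least_20db(self):
        # analytic squared-magnitude response of the zero-phase filter
        sos = sps.butter(3, [0.01, 0.4], btype="bandpass", fs=FS, output="sos")
        _, h = sps.sosfreqz(sos, worN=[1.1], fs=FS)
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db >= 20.0
        t = np.arange(20000) / FS
        out = bandpass(np.sin(2 * np.pi * 1.1 * t), FS)
        assert out[2000:-2000].std() <= 10 ** (-20 / 20) / np.sqrt(2)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        t = np.arange(4000) / FS
        a = np.sin(2 * np.pi * 0.05 * t)
        b = np.sin(2 * np.pi * 0.3 * t + 1.0)
        np.testing.assert_allclose(
            bandpass(a + b, FS), bandpass(a, FS) + bandpass(b, FS), atol=1e-10
        )

    def test_invalid_band_edges(self):
        with pytest.raises(ValueError, match="band edges"):
            bandpass(np.zeros(100), FS, low_hz=0.01, high_hz=6.0)


class TestMBLLRoundTrip:
    def test_forward_inverse_roundtrip(self):
        rng = np.random.default_rng(4)
        o2hb = rng.normal(0, 1, 1000)
        hhb = rng.normal(0, 0.5, 1000)
        od_fwd, _ = forward_mbll(o2hb, hhb, distance_cm=4.0)
        od = OpticalDensitySeries(
            od=od_fwd[None], wavelengths=(690.0, 830.0), sampling_rate=FS,
            source_detector_distance_cm=np.array([4.0]),
            events=PhaseWindows((("rest1", 0, 1000),)),
            subject_id="T", group_label=0,
        )
        hb = od_to_hemoglobin(od)
        np.testing.assert_allclose(hb.o2hb[0], o2hb, rtol=1e-9)
        np.testing.assert_allclose(hb.hhb[0], hhb, rtol=1e-9)

    def test_zero_od_zero_concentration(self):
        od = OpticalDensitySeries(
            od=np.zeros((1, 2, 20)), wavelengths=(690.0, 830.0), sampling_rate=FS,
            source_detector_distance_cm=np.array([3.0]),
            events=PhaseWindows((("rest1", 0, 20),)), subject_id="T", group_label=0,
        )
        hb = od_to_hemoglobin(od)
        assert np.all(hb.o2hb == 0) and np.all(hb.hhb == 0)

    def test_hand_solved_2x2(self):
        # eps = [[1, 2], [3, 1]], d*dpf = 1 for both wavelengths:
        # od = (5, 5) -> o2hb = 1, hhb = 2
        ext = np.array([[1.0, 2.0], [3.0, 1.0]])
        od = OpticalDensitySeries(
            od=np.array([[[5.0], [5.0]]]), wavelengths=(690.0, 830.0),
            sampling_rate=FS, source_detector_distance_cm=np.array([1.0]),
            events=PhaseWindows((("rest1", 0, 1),)), subject_id="T", group_label=0,
        )
        hb = od_to_hemoglobin(od, dpf=(1.0, 1.0), extinction=ext)
        assert hb.o2hb[0, 0] == pytest.approx(1.0, rel=1e-12)
        assert hb.hhb[0, 0] == pytest.approx(2.0, rel=1e-12)


class TestCBSI:
    def _hb(self, o2hb, hhb):
        from nirsentropy.recording import HemoglobinRecording

        n = o2hb.shape[1]
        return HemoglobinRecording(
            o2hb=o2hb, hhb=hhb, sampling_rate=FS,
            events=PhaseWindows((("rest1", 0, n),)), subject_id="T", group_label=0,
        )

    def test_formula_matches_direct_evaluation(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((3, 400))
        y = rng.standard_normal((3, 400))
        out = cbsi_correct(self._hb(x, y))
        alpha = x.std(axis=1) / y.std(axis=1)
        np.testing.assert_allclose(out.o2hb, (x - alpha[:, None] * y) / 2, atol=1e-12)
        np.testing.assert_allclose(out.hhb, -out.o2hb / alpha[:, None], atol=1e-12)

    def test_already_anticorrelated_signal_unchanged(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 300))
        alpha = 2.0
        y = -x / alpha
        out = cbsi_correct(self._hb(x, y))
        np.testing.assert_allclose(out.o2hb, x, atol=1e-12)

    def test_corrected_pair_exactly_anticorrelated(self):
        rng = np.random.default_rng(7)
        out = cbsi_correct(
            self._hb(rng.standard_normal((4, 500)), rng.standard_normal((4, 500)))
        )
        for ch in range(4):
            r = np.corrcoef(out.o2hb[ch], out.hhb[ch])[0, 1]
            assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_hhb_names_channel(self):
        x = np.random.default_rng(8).standard_normal((2, 100))
        y = x.copy()
        y[1] = 0.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            cbsi_correct(self._hb(x, y))


class TestFullChain:
    def test_pipeline_order_audit_log(self, small_cohort):
        recordings, _ = small_cohort
        hb = preprocess_recording(recordings[0])
        stages = [h.split("(")[0] for h in hb.history]
        assert stages == [
            "intensity_to_od",
            "wavelet_motion_correct",
            "bandpass",
            "od_to_hemoglobin",
            "cbsi_correct",
        ]
        assert hb.cbsi_applied

    def test_no_cbsi_flag(self, small_cohort):
        recordings, _ = small_cohort
        hb = preprocess_recording(
            recordings[0], PreprocessParams(apply_cbsi=False)
        )
        assert not hb.cbsi_applied

    def test_recovers_latent_inband_component(self):
        """Corrected O2Hb tracks the band-limited latent signal (cohort
        mean correlation > 0.9 despite physiology and drift)."""
        cfg = SyntheticCohortConfig(
            n_per_group=3, n_channels=6, affected_channels=(1, 3),
            artifact_rate=0.0, seed=11,
        )
        recordings, truth = generate_cohort(cfg)
        cohort = preprocess_cohort(recordings)
        cors = []
        for rec, hb in zip(recordings, cohort):
            lat_band = bandpass(truth.latent_o2hb[rec.subject_id], cfg.sampling_rate)
            for ch in range(cfg.n_channels):
                cors.append(np.corrcoef(lat_band[ch], hb.o2hb[ch])[0, 1])
        assert np.mean(cors) > 0.9
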