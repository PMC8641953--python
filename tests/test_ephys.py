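"""MUA envelope, position responses, multitaper band power and cRF mapping."""

import numpy as np
import pytest
from scipy import signal as sps

from prfmap.ephys import (
    LFP_BANDS,
    BandPowerResponse,
    BarSweepRecording,
    CRFEstimate,
    RawSignal,
    band_power_from_psd,
    crf_diameter,
    estimate_crf,
    lfp_band_power,
    mua_envelope,
    multitaper_spectrogram,
    position_response,
)
from prfmap.models import PRFParams
from prfmap.synthetic import synth_moving_bar_mua


FS_RAW = 30000.0


def make_raw(x, fs=FS_RAW, events=None):
    if events is None:
        events = np.array([[0.5]])
    return RawSignal(x, fs, events)


class TestMuaEnvelope:
    def test_zero_input_zero_envelope(self):
        env = mua_envelope(make_raw(np.zeros(int(FS_RAW))))
        assert env.fs == 1000.0
        assert np.allclose(env.samples, 0.0)

    def test_homogeneity(self, rng):
        x = rng.normal(size=int(FS_RAW))
        e1 = mua_envelope(make_raw(x)).samples
        e2 = mua_envelope(make_raw(2.0 * x)).samples
        assert np.allclose(e2, 2.0 * e1, atol=1e-9)

    def test_sinusoid_against_stagewise_oracle(self):
        # independently apply the three stages with scipy reference calls
        t = np.arange(int(FS_RAW)) / FS_RAW
        x = 3.0 * np.sin(2 * np.pi * 3000.0 * t)
        env = mua_envelope(make_raw(x)).samples

        sos_bp = sps.butter(4, (500.0, 9000.0), btype="bandpass", fs=FS_RAW, output="sos")
        sos_lp = sps.butter(4, 200.0, btype="lowpass", fs=FS_RAW, output="sos")
        ref = sps.sosfiltfilt(sos_lp, np.abs(sps.sosfiltfilt(sos_bp, x)))
        ref = sps.resample_poly(ref, 1, 30)
        assert np.allclose(env, ref)
        # steady-state level ~ mean|sin| * amplitude (band-pass gain ~1 at 3 kHz)
        mid = env[300:700]
        assert mid.mean() == pytest.approx(3.0 * 2 / np.pi, rel=0.05)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="kHz"):
            mua_envelope(make_raw(np.zeros(1000), fs=10000.0, events=np.array([[0.01]])))

    def test_envelope_near_nonnegative(self, rng):
        x = rng.normal(size=int(FS_RAW))
        env = mua_envelope(make_raw(x)).samples
        # rectified signal; low-pass ringing may undershoot slightly
        assert env.min() > -0.15 * env.max()


class TestPositionResponse:
    def test_constant_signal_zeroed_by_baseline(self):
        fs = 1000.0
        sig = np.full(int(5 * fs), 7.0)
        events = np.array([[1.5, 2.0, 2.5]])
        raw = RawSignal(sig, fs, events)
        resp = position_response(raw)
        assert np.allclose(resp, 0.0)

    def test_step_at_one_position(self):
        fs = 1000.0
        sig = np.zeros(int(6 * fs))
        events = np.array([[1.5, 2.5, 3.5]])
        # step of height 2 covering position 1's full 50-500 ms window
        sig[int(2.5 * fs) : int(3.1 * fs)] = 2.0
        resp = position_response(RawSignal(sig, fs, events))
        assert resp == pytest.approx([0.0, 2.0, 0.0])

    def test_ramp_matches_integration_oracle(self):
        fs = 1000.0
        t = np.arange(int(6 * fs)) / fs
        sig = 3.0 * t
        events = np.array([[1.5, 2.5]])
        resp = position_response(RawSignal(sig, fs, events))
        base = 3.0 * 1.0  # sweep baseline: mean of ramp over [0.5, 1.5]
        for k, on in enumerate([1.5, 2.5]):
            mean_resp = 3.0 * (on + 0.275)  # mean over [on+.05, on+.5]
            assert resp[k] == pytest.approx(mean_resp - base, rel=1e-2)

    def test_window_outside_record_rejected(self):
        fs = 1000.0
        raw = RawSignal(np.zeros(int(2 * fs)), fs, np.array([[1.9]]))
        with pytest.raises(ValueError, match="window"):
            position_response(raw)

    def test_repeats_averaged(self):
        fs = 1000.0
        sig = np.zeros(int(10 * fs))
        events = np.array([[1.5], [6.5]])
        sig[int(1.55 * fs) : int(2.0 * fs)] = 1.0
        sig[int(6.55 * fs) : int(7.0 * fs)] = 3.0
        resp = position_response(RawSignal(sig, fs, events))
        assert resp[0] == pytest.approx(2.0, rel=0.01)


class TestBandPower:
    def test_band_edges_partition_4_to_120(self):
        edges = sorted(LFP_BANDS.values())
        assert edges[0][0] == 4.0 and edges[-1][1] == 120.0
        for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
            assert hi1 == lo2

    def test_tone_concentrates_in_low_gamma(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 40.0 * t)
        _, freqs, psd = multitaper_spectrogram(x, fs)
        bp = band_power_from_psd(freqs, psd.mean(axis=0))
        total = sum(bp.values())
        assert bp["gamma_low"] / total > 0.9

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        fs = 500.0
        x = rng.normal(size=int(120 * fs))
        _, freqs, psd = multitaper_spectrogram(x, fs)
        bp = band_power_from_psd(freqs, psd.mean(axis=0))
        widths = {k: hi - lo for k, (lo, hi) in LFP_BANDS.items()}
        densities = [bp[k] / widths[k] for k in LFP_BANDS]
        assert max(densities) / min(densities) == pytest.approx(1.0, abs=0.1)
        # flat unit-variance spectrum: density = 2/fs per one-sided Hz... the
        # absolute level check: total 0-Nyquist power equals the variance
        assert psd.mean(axis=0).sum() * (freqs[1] - freqs[0]) == pytest.approx(
            np.var(x), rel=0.05
        )

    def test_record_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            multitaper_spectrogram(np.zeros(100), 500.0)

    def test_silent_epoch_reads_negative_of_baseline(self, rng):
        # active baseline, silent response epochs: band power after baseline
        # subtraction is approximately -baseline power
        fs = 500.0
        n = int(8 * fs)
        x = rng.normal(size=n)
        x[int(2.0 * fs) :] = 0.0  # silence after t=2 s
        events = np.array([[2.5, 3.5]])
        raw = RawSignal(x, fs, events)
        resp = lfp_band_power(raw, baseline=1.0)
        # oracle: same spectrogram, window selection applied by hand
        times, freqs, psd = multitaper_spectrogram(x, fs)
        bp = band_power_from_psd(freqs, psd)
        base_sel = (times >= 1.5) & (times < 2.5)
        for band in LFP_BANDS:
            expected = []
            for on in events[0]:
                sel = (times >= on + 0.05) & (times < on + 0.5)
                expected.append(bp[band][sel].mean() - bp[band][base_sel].mean())
            np.testing.assert_allclose(resp[band], expected, rtol=1e-12)
            # active baseline, silent response: corrected power is negative
            assert (resp[band] < 0).all()

    def test_broadband_input_downsampled(self, rng):
        fs = 2000.0
        x = rng.normal(size=int(6 * fs))
        raw = RawSignal(x, fs, np.array([[2.0, 3.0]]))
        resp = lfp_band_power(raw)
        assert set(resp.bands) == set(LFP_BANDS)

    def test_band_response_validation(self):
        with pytest.raises(ValueError, match="bands"):
            BandPowerResponse({"theta": np.zeros(3)})


class TestCRF:
    @staticmethod
    def _recording(**kw):
        params = PRFParams("P-LIN", kw.pop("x0", 4.0), kw.pop("y0", -3.0),
                          kw.pop("sigma", 0.8), gain=1.0)
        return params, synth_moving_bar_mua(params, **kw)

    def test_size_formula_345_triangle(self):
        est = CRFEstimate(left=0, right=3, bottom=0, top=4, center=(1.5, 2.0),
                          width=3, height=4, size=2.5, aspect_ratio=4 / 3,
                          snr=10, fit_r2=99)
        assert np.hypot(est.width, est.height) / 2 == pytest.approx(2.5)
        assert crf_diameter(est) == pytest.approx(3.3 * 2.5)

    @pytest.mark.parametrize("size,expected", [(1.0, 3.3), (0.5, 1.65), (2.5, 8.25)])
    def test_diameter_is_3p3_sd(self, size, expected):
        est = CRFEstimate(left=0, right=1, bottom=0, top=1, center=(0.5, 0.5),
                          width=1, height=1, size=size, aspect_ratio=1.0,
                          snr=10, fit_r2=99)
        assert crf_diameter(est) == pytest.approx(expected)

    def test_noiseless_center_recovery(self):
        params, rec = self._recording(noise_sd=1e-4, latency=0.0, seed=0)
        crf = estimate_crf(rec)
        assert abs(crf.center[0] - params.x0) < 0.1
        assert abs(crf.center[1] - params.y0) < 0.1
        assert 1 / 1.05 <= crf.aspect_ratio <= 1.05 or crf.aspect_ratio <= 1.05

    def test_latency_cancels_between_opposite_sweeps(self):
        _, rec0 = self._recording(noise_sd=1e-4, latency=0.0, seed=0)
        _, rec60 = self._recording(noise_sd=1e-4, latency=0.060, seed=0)
        c0 = estimate_crf(rec0).center
        c60 = estimate_crf(rec60).center
        assert abs(c60[0] - c0[0]) < 0.05
        assert abs(c60[1] - c0[1]) < 0.05

    def test_low_snr_unit_rejected(self):
        params = PRFParams("P-LIN", 4.0, -3.0, 0.8, gain=0.01)
        rec = synth_moving_bar_mua(params, noise_sd=0.5, seed=1)
        with pytest.raises(ValueError, match="SNR"):
            estimate_crf(rec)

    def test_population_center_recovery_at_snr10(self, rng):
        # 20 units, median center error < 0.2 dva
        errs = []
        for i in range(20):
            x0, y0 = rng.uniform(-8, 8), rng.uniform(-8, 8)
            sigma = rng.uniform(0.5, 1.5)
            p = PRFParams("P-LIN", x0, y0, sigma, gain=1.0)
            rec = synth_moving_bar_mua(p, noise_sd=0.1, n_repeats=10, seed=100 + i)
            crf = estimate_crf(rec)
            errs.append(np.hypot(crf.center[0] - x0, crf.center[1] - y0))
            assert crf.snr > 3
        assert np.median(errs) < 0.2

    def test_missing_direction_pairs_rejected(self):
        with pytest.raises(ValueError, match="directions"):
            BarSweepRecording(
                traces=np.zeros((2, 1, 10)), t=np.linspace(0, 1, 10),
                directions=(0.0, 90.0), offset0=-5, speed=10, spont=np.zeros(10),
            )
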