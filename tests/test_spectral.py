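"""Unit and property tests for multitaper spectral estimation."""

import numpy as np
import pytest
from scipy.fft import fft, fftfreq
from scipy.signal import periodogram

import gammaflick as gf
from gammaflick.errors import (
    BandRangeError,
    InsufficientEpochsError,
    InvalidParameterError,
    ShapeError,
)
from gammaflick.spectral import _next_pow2

from conftest import make_sine


class TestSlepianTapers:
    def test_default_count_is_2nw_minus_1(self):
        assert gf.make_slepian_tapers(64, 2).k == 3
        assert gf.make_slepian_tapers(256, 3).k == 5

    def test_orthonormality(self):
        ts = gf.make_slepian_tapers(64, 2)
        gram = ts.tapers @ ts.tapers.T
        assert np.abs(gram - np.eye(ts.k)).max() < 1e-8

    def test_unit_norm(self):
        ts = gf.make_slepian_tapers(256, 3)
        norms = np.linalg.norm(ts.tapers, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-10

    def test_leading_taper_concentration_vs_dense_dft(self):
        # fractional energy of taper 0 inside |f| <= W, from a dense DFT
        ts = gf.make_slepian_tapers(256, 3)
        nfft = 1 << 16
        spec = np.abs(fft(ts.tapers[0], nfft)) ** 2
        freqs = fftfreq(nfft)
        w = ts.half_bandwidth_cycles
        frac = spec[np.abs(freqs) <= w].sum() / spec.sum()
        assert frac > 0.99

    def test_concentration_ordering(self):
        ts = gf.make_slepian_tapers(256, 3)
        nfft = 1 << 14
        freqs = fftfreq(nfft)
        w = ts.half_bandwidth_cycles
        inband = np.abs(freqs) <= w
        concs = [
            (np.abs(fft(u, nfft)) ** 2)[inband].sum()
            / (np.abs(fft(u, nfft)) ** 2).sum()
            for u in ts.tapers
        ]
        assert all(a >= b for a, b in zip(concs, concs[1:]))

    @pytest.mark.parametrize(
        "n, nw, k",
        [(4, 2, None), (64, 0.5, None), (64, 2, 0), (64, 2, 4)],
    )
    def test_invalid_parameters(self, n, nw, k):
        with pytest.raises(InvalidParameterError):
            gf.make_slepian_tapers(n, nw, k)


class TestMultitaperPSD:
    def test_zero_signal_gives_zero_power(self):
        psd = gf.multitaper_psd(gf.Signal(np.zeros(1024), 1000.0), nw=3)
        assert np.all(psd.power == 0)

    def test_sine_peak_at_nearest_grid_frequency(self):
        sig = make_sine(40.0, fs=1000.0, duration_s=2.0)
        psd = gf.multitaper_psd(sig, nw=3)
        peak = psd.freqs[np.argmax(psd.power)]
        # oracle: single-taper periodogram locates the same line
        f_ref, p_ref = periodogram(sig.samples, 1000.0, nfft=_next_pow2(2000))
        assert abs(peak - f_ref[np.argmax(p_ref)]) < 1e-9
        assert abs(peak - 40.0) <= psd.freqs[1] - psd.freqs[0]

    def test_rectangular_single_taper_reduces_to_periodogram(self, rng):
        n = 4096
        x = rng.standard_normal(n)
        rect = gf.TaperSet(n, 1.0, np.ones((1, n)) / np.sqrt(n))
        psd = gf.multitaper_psd(gf.Signal(x, 1000.0), rect, nfft=n, detrend=None)
        f_ref, p_ref = periodogram(x, 1000.0, window="boxcar", nfft=n, detrend=False)
        assert np.allclose(psd.freqs, f_ref)
        assert np.max(np.abs(psd.power - p_ref)) <= 1e-10 * p_ref.max()

    def test_parseval_on_white_noise(self, white_noise_signal):
        psd = gf.multitaper_psd(white_noise_signal, nw=3)
        total = np.trapezoid(psd.power, psd.freqs)
        assert total == pytest.approx(white_noise_signal.samples.var(), rel=0.05)

    def test_white_noise_spectrum_is_flat(self, white_noise_signal):
        psd = gf.multitaper_psd(white_noise_signal, nw=3)
        band_means = []
        for lo in range(10, 490, 10):
            m = (psd.freqs >= lo) & (psd.freqs < lo + 10)
            band_means.append(psd.power[m].mean())
        assert max(band_means) / min(band_means) < 1.5

    def test_raw_mode_matches_eq_definition(self, rng):
        # direct evaluation of mean_k |(1/N) sum_n e^{2 pi i f n} u x|^2
        n = 256
        x = rng.standard_normal(n)
        ts = gf.make_slepian_tapers(n, 2)
        psd = gf.multitaper_psd(gf.Signal(x, 1000.0), ts, nfft=n, mode="raw",
                                detrend=None)
        idx = 17  # arbitrary grid bin
        f_cyc = idx / n
        ns = np.arange(n)
        vals = [
            np.abs(np.sum(np.exp(2j * np.pi * f_cyc * ns) * u * x) / n) ** 2
            for u in ts.tapers
        ]
        assert psd.power[idx] == pytest.approx(np.mean(vals), rel=1e-12)

    def test_length_mismatch_raises_without_segmentation(self, rng):
        ts = gf.make_slepian_tapers(1000, 3)
        sig = gf.Signal(rng.standard_normal(4000), 1000.0)
        with pytest.raises(ShapeError):
            gf.multitaper_psd(sig, ts)
        psd = gf.multitaper_psd(sig, ts, allow_segmented=True)
        assert psd.power.shape == psd.freqs.shape

    def test_entrained_lfp_peaks_at_flicker_frequency(self):
        from gammaflick.simulate import LFPSimConfig, simulate_lfp

        sess = simulate_lfp(LFPSimConfig(duration_s=20, entrain_hz=40.0, seed=3))
        psd = gf.multitaper_psd(sess.lfp, nw=3)
        m = psd.freqs >= 2.0
        assert abs(psd.freqs[m][np.argmax(psd.power[m])] - 40.0) < 0.5


class TestBandPower:
    def test_flat_density_integrates_to_width_times_level(self):
        freqs = np.linspace(0, 500, 501)
        psd = gf.PSDEstimate(freqs, np.full(501, 3.0), 1, 1000, 1000.0)
        assert gf.band_power(psd, gf.LOW_GAMMA) == pytest.approx(20 * 3.0, abs=1e-9)

    def test_sine_power_concentrates_in_its_band(self):
        sig = make_sine(40.0, duration_s=4.0)
        psd = gf.multitaper_psd(sig, nw=3)
        lg = gf.band_power(psd, gf.LOW_GAMMA)
        assert lg / gf.band_power(psd, gf.THETA) > 10
        assert lg / gf.band_power(psd, gf.HIGH_GAMMA) > 10

    def test_band_outside_grid_raises(self):
        freqs = np.linspace(0, 100, 101)
        psd = gf.PSDEstimate(freqs, np.ones(101), 1, 200, 200.0)
        with pytest.raises(BandRangeError):
            gf.band_power(psd, gf.FrequencyBand("too_high", 90, 120))

    def test_ischemic_preset_lowers_low_gamma_only(self):
        from gammaflick.simulate import LFPSimConfig, simulate_lfp
        from gammaflick.workflows import session_band_powers

        sham = session_band_powers(
            simulate_lfp(LFPSimConfig(duration_s=60, seed=9)).lfp, seed=9
        )
        isch = session_band_powers(
            simulate_lfp(LFPSimConfig(duration_s=60, seed=9, condition="2VO")).lfp,
            seed=9,
        )
        assert isch["low_gamma"] < sham["low_gamma"]
        assert isch["theta"] == pytest.approx(sham["theta"], rel=0.15)


class TestSelectEpochs:
    def test_default_selection_on_clean_recording(self, rng):
        sig = gf.Signal(rng.standard_normal(120_000), 1000.0)
        es = gf.select_epochs(sig, n_epochs=10, epoch_s=2.0, seed=0)
        assert len(es) == 10
        assert all(e.n_samples == 2000 for e in es.epochs)
        # non-overlapping
        idx = np.sort(es.indices)
        assert np.all(np.diff(idx) >= 2000)

    def test_same_seed_reproduces_indices(self, rng):
        sig = gf.Signal(rng.standard_normal(60_000), 1000.0)
        a = gf.select_epochs(sig, seed=7)
        b = gf.select_epochs(sig, seed=7)
        assert np.array_equal(a.indices, b.indices)

    def test_artifacts_are_avoided(self, rng):
        x = rng.standard_normal(120_000)
        artifact_starts = [10_000, 40_000, 75_000, 100_000]
        for s in artifact_starts:
            x[s : s + 500] += 20 * x.std()
        sig = gf.Signal(x, 1000.0)
        es = gf.select_epochs(sig, n_epochs=10, epoch_s=2.0, seed=1)
        for i in es.indices:
            for s in artifact_starts:
                assert i + 2000 <= s or i >= s + 500

    def test_insufficient_windows_reports_available(self, rng):
        sig = gf.Signal(rng.standard_normal(5000), 1000.0)
        with pytest.raises(InsufficientEpochsError) as exc:
            gf.select_epochs(sig, n_epochs=10, epoch_s=2.0, seed=0)
        assert exc.value.available == 2


class TestSpectrogram:
    def test_stationary_sine_has_constant_ridge(self):
        sig = make_sine(40.0, duration_s=10.0)
        sg = gf.spectrogram(sig, window_s=1.0, shift_s=0.1)
        ridge = sg.freqs[np.argmax(sg.power, axis=1)]
        assert np.all(np.abs(ridge - 40.0) < 1.0)

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        from scipy.signal import chirp

        fs, dur = 1000.0, 10.0
        t = np.arange(int(fs * dur)) / fs
        sig = gf.Signal(chirp(t, f0=10, f1=80, t1=dur, method="linear"), fs)
        sg = gf.spectrogram(sig, window_s=0.5, shift_s=0.1)
        ridge = sg.freqs[np.argmax(sg.power, axis=1)]
        f_inst = 10 + (80 - 10) / dur * sg.times
        df = sg.freqs[1] - sg.freqs[0]
        assert np.all(np.abs(ridge - f_inst) <= df + 1e-9)
        assert np.all(np.diff(ridge) >= 0)

    def test_time_bin_count_for_documented_settings(self):
        # 10 s trace, 1 s window, 0.1 s shift -> (10-1)/0.1 + 1 = 91 bins
        sig = make_sine(40.0, duration_s=10.0)
        sg = gf.spectrogram(sig, window_s=1.0, shift_s=0.1)
        assert sg.power.shape[0] == 91
        assert np.allclose(np.diff(sg.times), 0.1)
        assert sg.freqs[-1] <= 120.0

    def test_window_longer_than_signal_raises(self):
        sig = make_sine(40.0, duration_s=0.5)
        with pytest.raises(ShapeError):
            gf.spectrogram(sig, window_s=1.0, shift_s=0.1)


class TestPerieventSpectrogram:
    def test_single_event_equals_sliced_spectrogram(self):
        sig = make_sine(40.0, duration_s=10.0)
        pe = gf.perievent_spectrogram(sig, [5.0], pre_s=1.0, post_s=1.0,
                                      window_s=0.5, shift_s=0.1)
        sliced = gf.spectrogram(
            gf.Signal(sig.samples[4000:6000], 1000.0, t0=-1.0),
            window_s=0.5, shift_s=0.1,
        )
        assert np.allclose(pe.power, sliced.power)
        assert np.allclose(pe.times, sliced.times)

    def test_injected_burst_power_ratio(self, rng):
        fs = 1000.0
        dur = 120.0
        t = np.arange(int(fs * dur)) / fs
        base_amp, boost = 0.5, 2.0
        events = np.arange(5.0, 115.0, 5.5)[:20]
        amp = np.full(t.size, base_amp)
        for ev in events:
            amp[(t >= ev) & (t < ev + 2.0)] = base_amp * boost
        x = amp * np.sin(2 * np.pi * 40 * t) + 0.05 * rng.standard_normal(t.size)
        pe = gf.perievent_spectrogram(gf.Signal(x, fs), events, pre_s=1.5,
                                      post_s=1.5, window_s=0.5, shift_s=0.1)
        band = (pe.freqs >= 30) & (pe.freqs <= 50)
        lg = pe.power[:, band].sum(axis=1)
        post = lg[pe.times >= 0.3].mean()   # windows fully post-onset
        pre = lg[pe.times <= -0.3].mean()
        assert post / pre == pytest.approx(boost**2, rel=0.2)

    def test_edge_events_skipped_with_warning(self):
        sig = make_sine(40.0, duration_s=10.0)
        with pytest.warns(UserWarning, match="skipped"):
            pe = gf.perievent_spectrogram(sig, [0.2, 5.0], pre_s=1.0, post_s=1.0)
        assert pe.n_skipped == 1
        assert pe.n_events == 1


class TestPSDBandRatio:
    def test_identical_psds_give_unity(self, white_noise_signal):
        psd = gf.multitaper_psd(white_noise_signal, nw=3)
        assert gf.psd_band_ratio(psd, psd, gf.LOW_GAMMA) == 1.0

    def test_double_amplitude_gives_four_fold_power_ratio(self):
        a = gf.multitaper_psd(make_sine(40.0, duration_s=2.0, amp=2.0), nw=3)
        b = gf.multitaper_psd(make_sine(40.0, duration_s=2.0, amp=1.0), nw=3)
        assert gf.psd_band_ratio(a, b, gf.LOW_GAMMA) == pytest.approx(4.0, rel=0.02)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(4000)
        y = rng.standard_normal(4000)
        r1 = gf.psd_band_ratio(
            gf.multitaper_psd(gf.Signal(x, 1000.0), nw=3),
            gf.multitaper_psd(gf.Signal(y, 1000.0), nw=3),
            gf.LOW_GAMMA,
        )
        c = 7.3
        r2 = gf.psd_band_ratio(
            gf.multitaper_psd(gf.Signal(c * x, 1000.0), nw=3),
            gf.multitaper_psd(gf.Signal(c * y, 1000.0), nw=3),
            gf.LOW_GAMMA,
        )
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_zero_denominator_raises_with_context(self):
        freqs = np.linspace(0, 500, 501)
        num = gf.PSDEstimate(freqs, np.ones(501), 1, 1000, 1000.0)
        den = gf.PSDEstimate(freqs, np.zeros(501), 1, 1000, 1000.0)
        with pytest.raises(ZeroDivisionError, match="low_gamma"):
            gf.psd_band_ratio(num, den, gf.LOW_GAMMA)
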