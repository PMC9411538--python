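import numpy as np
import pandas as pd
import pytest
from scipy import signal

from evlock import lfp
from evlock.lfp import NormalizedSpectrogram
from evlock.params import BandTable, PreprocessParams, SpectrogramParams


def _digital_mag(f, fs=32000.0, params=PreprocessParams()):
    b, a = lfp.design_antialias_filter(fs, params)
    _, h = signal.freqz(b, a, worN=[f], fs=fs)
    return abs(h[0])


class TestFilterContract:
    def test_edge_is_minus_half_db(self):
        mag = _digital_mag(200.0)
        assert abs(20 * np.log10(mag) - (-0.5)) < 1e-6

    @pytest.mark.parametrize("f", [100.0, 450.0])
    def test_matches_analytic_chebyshev(self, f):
        analytic = lfp.chebyshev1_magnitude(f, 3, 0.5, 200.0)
        assert _digital_mag(f) == pytest.approx(analytic, rel=0.01)

    def test_passband_floor_value(self):
        # order-3 Chebyshev-I: |H(fc/2)| sits exactly on the ripple floor
        assert lfp.chebyshev1_magnitude(100.0, 3, 0.5, 200.0) == pytest.approx(
            1 / np.sqrt(10 ** 0.05), rel=1e-12
        )


class TestPreprocess:
    def test_zero_trace(self):
        y = lfp.preprocess_lfp(np.zeros(int(32000 * 3.2)), 32000.0)
        assert y.size == 3200
        assert np.all(y == 0)

    def test_100hz_amplitude_within_ripple(self):
        fs = 32000.0
        t = np.arange(int(fs * 3.2)) / fs
        y = lfp.preprocess_lfp(np.sin(2 * np.pi * 100 * t), fs)
        amp = np.sqrt(2) * y[500:2700].std()  # RMS estimate away from edges
        assert amp >= 0.944 - 0.002
        assert amp == pytest.approx(_digital_mag(100.0), rel=0.01)

    def test_450hz_amplitude_matches_response(self):
        fs = 32000.0
        t = np.arange(int(fs * 3.2)) / fs
        y = lfp.preprocess_lfp(np.sin(2 * np.pi * 450 * t), fs)
        amp = np.sqrt(2) * y[500:2700].std()
        assert amp == pytest.approx(_digital_mag(450.0), rel=0.01)

    def test_nonfinite_named_index(self):
        x = np.zeros(1000)
        x[123] = np.nan
        with pytest.raises(ValueError, match="index 123"):
            lfp.preprocess_lfp(x, 32000.0)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            lfp.preprocess_lfp(np.zeros(1000), 300.0)

    def test_non_integer_ratio(self):
        fs = 2500.0
        t = np.arange(int(fs * 4)) / fs
        y = lfp.preprocess_lfp(np.sin(2 * np.pi * 20 * t), fs)
        assert y.size == int(np.floor(t.size * 1000.0 / fs))
        assert np.sqrt(2) * y[500:3500].std() == pytest.approx(1.0, rel=0.02)


class TestMorlet:
    def test_zero_trace_zero_power(self):
        spec = lfp.morlet_spectrogram(np.zeros(6000), 1000.0)
        assert np.allclose(spec.power, 0.0)

    def test_pure_tone_peaks_at_carrier(self):
        t = np.arange(8000) / 1000.0
        spec = lfp.morlet_spectrogram(np.sin(2 * np.pi * 20 * t), 1000.0)
        mask = spec.valid_mask().all(axis=0)
        cols = np.flatnonzero(mask)
        peaks = spec.freqs[np.argmax(spec.power[:, cols], axis=0)]
        assert np.all(peaks == 20.0)
        # unit-amplitude sinusoid -> power 0.5 at the carrier row
        row = spec.power[spec.freqs == 20.0, cols]
        assert np.allclose(row, 0.5, rtol=1e-3)

    def test_two_tones_two_local_maxima(self):
        t = np.arange(8000) / 1000.0
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 60 * t)
        spec = lfp.morlet_spectrogram(x, 1000.0)
        col = spec.power[:, 4000]
        is_max = np.r_[False, (col[1:-1] > col[:-2]) & (col[1:-1] > col[2:]), False]
        local = set(spec.freqs[is_max])
        assert 10.0 in local and 60.0 in local

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="fs/2"):
            lfp.morlet_spectrogram(np.zeros(6000), 150.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="support"):
            lfp.morlet_spectrogram(np.zeros(500), 1000.0)

    def test_white_noise_flat_vs_multitaper_oracle(self):
        # Morlet band power of white noise scales as f (fixed-cycles wavelet);
        # after dividing by f * multitaper PSD the profile is flat within
        # estimator noise (the wavelet's known bias is the factor f).
        from scipy.fft import rfft, rfftfreq
        from scipy.signal import windows

        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        fs = 1000.0
        spec = lfp.morlet_spectrogram(x, fs)
        mask = spec.valid_mask()
        mp = np.array(
            [spec.power[i][mask[i]].mean() for i in range(len(spec.freqs))]
        )
        tapers = windows.dpss(x.size, 4, 7)
        psd = np.zeros(x.size // 2 + 1)
        for tap in tapers:
            psd += np.abs(rfft(x * tap)) ** 2 / fs
        psd = 2 * psd / len(tapers)
        f = rfftfreq(x.size, 1 / fs)
        psd_at = np.array(
            [psd[(f >= ff - 2) & (f <= ff + 2)].mean() for ff in spec.freqs]
        )
        ratio = mp / (spec.freqs * psd_at)
        r = ratio / ratio.mean()
        assert r.min() > 0.8 and r.max() < 1.2


def _noise_spec(rng, n_trials=20, fs=1000.0, spacing=7.0):
    dur = 8 + n_trials * spacing
    x = rng.standard_normal(int(dur * fs))
    spec = lfp.morlet_spectrogram(x, fs)
    onsets = 4.0 + np.arange(n_trials) * spacing
    return spec, onsets


class TestNormalize:
    def test_baseline_mean_is_zero_by_construction(self, rng):
        spec, onsets = _noise_spec(rng, n_trials=1)
        nspec = lfp.extract_and_normalize(spec, onsets[:1])
        base_cols = (nspec.times >= -1.0) & (nspec.times < 0.0)
        row_means = nspec.matrix[:, base_cols].mean(axis=1)
        assert np.allclose(row_means, 0.0, atol=1e-9)

    def test_constant_power_gives_zero_everywhere(self):
        freqs = np.arange(4.0, 100.5, 0.5)
        spec = lfp.Spectrogram(
            power=np.outer(1 + freqs, np.ones(10_000)),
            freqs=freqs,
            times=np.arange(10_000) / 1000.0,
            fs=1000.0,
            edge_margins=np.zeros(freqs.size, int),
        )
        nspec = lfp.extract_and_normalize(spec, [5.0])
        assert np.abs(nspec.matrix).max() == 0.0

    def test_carrier_row_power_constant_in_time(self):
        # a pure tone's own row normalizes to ~0% (constant power in time)
        t = np.arange(40_000) / 1000.0
        spec = lfp.morlet_spectrogram(np.sin(2 * np.pi * 20 * t), 1000.0)
        row = np.flatnonzero(spec.freqs == 20.0)[0]
        sub = lfp.Spectrogram(
            power=spec.power[[row]],
            freqs=spec.freqs[[row]],
            times=spec.times,
            fs=spec.fs,
            edge_margins=spec.edge_margins[[row]],
        )
        nspec = lfp.extract_and_normalize(sub, [20.0])
        assert np.abs(nspec.matrix).max() < 1e-6

    def test_stationary_noise_near_zero(self, rng):
        # per-trial ratio normalization carries a positive O(sigma_t/T) bias;
        # at gamma frequencies it is a few percent, so assert within +/-10
        spec, onsets = _noise_spec(rng, n_trials=30)
        nspec = lfp.extract_and_normalize(spec, onsets)
        assert abs(lfp.band_power_change(nspec, "gamma")) < 10.0

    def test_normalization_idempotence(self, rng):
        spec, onsets = _noise_spec(rng, n_trials=2)
        nspec = lfp.extract_and_normalize(spec, onsets)
        # reconstruct a power-equivalent spectrogram from the % matrix
        power = 1.0 + nspec.matrix / 100.0
        spec2 = lfp.Spectrogram(
            power=power,
            freqs=nspec.freqs,
            times=nspec.times - nspec.times[0],
            fs=spec.fs,
            edge_margins=np.zeros(len(nspec.freqs), int),
        )
        onset2 = -nspec.times[0] + spec2.times[0]
        nspec2 = lfp.extract_and_normalize(spec2, [onset2])
        assert np.allclose(nspec2.matrix, nspec.matrix, atol=1e-9)

    def test_onset_without_full_window_rejected(self, rng):
        spec, _ = _noise_spec(rng, n_trials=1)
        with pytest.raises(ValueError, match="full"):
            lfp.extract_and_normalize(spec, [1.0])

    def test_zero_baseline_rejected(self):
        spec = lfp.Spectrogram(
            power=np.zeros((3, 8000)),
            freqs=np.array([10.0, 20.0, 30.0]),
            times=np.arange(8000) / 1000.0,
            fs=1000.0,
            edge_margins=np.zeros(3, int),
        )
        with pytest.raises(ValueError, match="zero baseline"):
            lfp.extract_and_normalize(spec, [4.0])


def _flat_nspec(value_by_band=None, pre=3.0, post=3.0, fs=1000.0):
    freqs = np.arange(4.0, 100.5, 0.5)
    times = (np.arange(int((pre + post) * fs)) - int(pre * fs)) / fs
    m = np.zeros((freqs.size, times.size))
    bands = BandTable().as_dict()
    for band, val in (value_by_band or {}).items():
        lo, hi = bands[band]
        m[(freqs >= lo) & (freqs < hi), :] = val
    return NormalizedSpectrogram(matrix=m, freqs=freqs, times=times, n_trials=1)


class TestBandSummaries:
    def test_zero_matrix(self):
        assert lfp.band_power_change(_flat_nspec(), "gamma") == 0.0

    def test_band_selectivity(self):
        nspec = _flat_nspec({"gamma": 50.0})
        assert lfp.band_power_change(nspec, "gamma") == pytest.approx(50.0)
        assert lfp.band_power_change(nspec, "beta") == 0.0

    def test_band_edges_half_open(self):
        nspec = _flat_nspec({"alpha": 10.0})
        # 8 Hz row belongs to alpha, 14 Hz row to beta
        i8 = np.flatnonzero(nspec.freqs == 8.0)[0]
        i14 = np.flatnonzero(nspec.freqs == 14.0)[0]
        assert nspec.matrix[i8, 0] == 10.0
        assert nspec.matrix[i14, 0] == 0.0

    def test_unknown_band(self):
        with pytest.raises(KeyError):
            lfp.band_power_change(_flat_nspec(), "delta")

    def test_timecourse_constant(self):
        nspec = _flat_nspec({"beta": 20.0})
        tc = lfp.band_timecourse(nspec, "beta")
        assert len(tc) == 60
        assert np.allclose(tc["pct_change"], 20.0)

    def test_timecourse_step(self):
        nspec = _flat_nspec()
        rows = (nspec.freqs >= 30) & (nspec.freqs < 100)
        nspec.matrix[np.ix_(rows, nspec.times >= 0)] = 100.0
        tc = lfp.band_timecourse(nspec, "gamma")
        pre_bins = tc[tc["bin_center"] < -0.05]["pct_change"]
        post_bins = tc[tc["bin_center"] > 0.05]["pct_change"]
        assert np.allclose(pre_bins, 0.0)
        assert np.allclose(post_bins, 100.0)

    def test_timecourse_median_withdrawal_attr(self):
        nspec = _flat_nspec()
        tc = lfp.band_timecourse(nspec, "theta", withdrawal_latencies=[0.2, 0.4, 0.9])
        assert tc.attrs["median_withdrawal_s"] == pytest.approx(0.4)

    def test_timecourse_matches_band_change(self, rng):
        spec, onsets = _noise_spec(rng, n_trials=5)
        nspec = lfp.extract_and_normalize(spec, onsets)
        tc = lfp.band_timecourse(nspec, "beta")
        sel = (tc["bin_center"] > 0) & (tc["bin_center"] < 2.0)
        assert tc[sel]["pct_change"].mean() == pytest.approx(
            lfp.band_power_change(nspec, "beta"), abs=1e-9
        )


class TestBandPowerByForce:
    def test_flat_curve(self):
        tabs = [
            pd.DataFrame({"force_g": [0.07, 0.16, 0.6], "pct_change": [5.0, 5.0, 5.0]})
            for _ in range(3)
        ]
        out = lfp.band_power_by_force(tabs)
        assert np.allclose(out["mean_pct"], 5.0)
        assert np.allclose(out["sem_pct"], 0.0)

    def test_monotone_curve_preserved(self):
        tabs = [
            pd.DataFrame(
                {"force_g": [0.07, 0.16, 0.6, 1.0], "pct_change": [1.0, 2.0, 5.0, 9.0]}
            )
            for _ in range(2)
        ]
        out = lfp.band_power_by_force(tabs).sort_values("force_g")
        assert out["mean_pct"].is_monotonic_increasing

    def test_single_animal_sem_is_nan(self):
        tabs = [pd.DataFrame({"force_g": [0.4], "pct_change": [3.0]})]
        out = lfp.band_power_by_force(tabs)
        assert np.isnan(out["sem_pct"].iloc[0])

    def test_weak_strong_grouping(self):
        tab = lfp.band_power_by_force(
            [
                pd.DataFrame(
                    {
                        "force_g": [0.07, 0.16, 0.6, 1.0],
                        "pct_change": [1.0, 3.0, 10.0, 14.0],
                    }
                )
            ]
        )
        assert lfp.group_forces(tab, (0.07, 0.16)) == pytest.approx(2.0)
        assert lfp.group_forces(tab, (0.6, 1.0)) == pytest.approx(12.0)


class TestPiezoDetector:
    def test_detects_pulse(self):
        fs = 1000.0
        x = np.zeros(10_000)
        x[:2000] = 0.01 * np.sin(np.arange(2000))
        x[5000:5050] = 1.0
        onsets = lfp.detect_onsets_piezo(x, fs)
        assert len(onsets) == 1
        assert onsets[0] == pytest.approx(5.0, abs=0.01)
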