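"""Wavelet-coherence checks: grid construction, CWT against a brute-force
convolution oracle, estimator identities, null behaviour and the volume
statistic."""

import numpy as np
import pytest

from imcoh import (
    CoherenceResult,
    FrequencyGrid,
    TFMap,
    WaveletParams,
    analytic_threshold,
    build_frequency_grid,
    coherence_significance_mask,
    generate_common_drive_emg,
    imc_volume,
    magnitude_squared_coherence,
    morlet_cwt,
    trial_averaged_spectra,
)
from imcoh.coherence import morlet_scale


def conv_cwt(x, fs, freqs, w0):
    """Independent oracle: direct linear correlation with the time-sampled
    Morlet wavelet, truncated at six e-folding times."""
    n = x.size
    dt = 1.0 / fs
    out = np.empty((len(freqs), n), complex)
    for j, f in enumerate(freqs):
        s = morlet_scale(f, w0)
        L = int(np.ceil(6 * s * fs))
        t = np.arange(-L, L + 1) * dt
        psi = (np.pi**-0.25) * np.sqrt(dt / s) * np.exp(1j * w0 * t / s - 0.5 * (t / s) ** 2)
        out[j] = np.correlate(x, psi, mode="full")[L : L + n]
    return out


def small_grid(lo=5.0, hi=50.0, n=10):
    f = np.linspace(lo, hi, n)
    return FrequencyGrid(freqs=f, df=float(f[1] - f[0]))


def noise_trials(rng, k, n=800, fs=1000.0):
    return [rng.standard_normal(n) for _ in range(k)]


class TestFrequencyGrid:
    def test_default_grid_dimensions_and_span(self):
        grid = build_frequency_grid(WaveletParams(), fs=1000.0)
        assert grid.n == 350
        assert round(grid.freqs.min(), 2) == 0.23
        assert round(grid.freqs.max(), 2) == 79.97
        assert round(grid.df, 2) == 0.23
        assert np.allclose(np.diff(grid.freqs), grid.df)

    def test_grid_reaching_nyquist_rejected(self):
        with pytest.raises(ValueError):
            build_frequency_grid(WaveletParams(), fs=150.0)

    def test_wavelet_parameter_validation(self):
        with pytest.raises(ValueError):
            WaveletParams(wavenumber=4)
        with pytest.raises(ValueError):
            WaveletParams(alpha=1.5)


class TestMorletCwt:
    def test_zero_input_gives_zero_map(self):
        w = morlet_cwt(np.zeros(500), small_grid(), 10.0, fs=250.0)
        assert np.all(w == 0)

    def test_linearity_power_quadruples(self, rng):
        x = rng.standard_normal(600)
        g = small_grid()
        w1 = morlet_cwt(x, g, 10.0, fs=250.0)
        w2 = morlet_cwt(2 * x, g, 10.0, fs=250.0)
        assert np.allclose(np.abs(w2) ** 2, 4 * np.abs(w1) ** 2, rtol=1e-10)

    def test_pure_tone_peaks_at_nearest_bin(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 20 * t)
        grid = build_frequency_grid(WaveletParams(), fs=fs)
        w = morlet_cwt(x, grid, 10.0, fs=fs)
        power = (np.abs(w) ** 2)[:, 1000:3000]
        nearest = np.argmin(np.abs(grid.freqs - 20.0))
        assert np.all(np.argmax(power, axis=0) == nearest)

    def test_matches_convolution_oracle(self, rng):
        fs = 250.0
        x = rng.standard_normal(500)
        g = small_grid()
        ours = morlet_cwt(x, g, 10.0, fs=fs)
        oracle = conv_cwt(x, fs, g.freqs, 10.0)
        assert np.abs(ours - oracle).max() < 1e-6

    def test_series_shorter_than_lowest_wavelet_rejected(self):
        grid = FrequencyGrid(freqs=np.array([0.5, 1.0]), df=0.5)
        with pytest.raises(ValueError):
            morlet_cwt(np.zeros(200), grid, 10.0, fs=250.0)


class TestTrialAveragedCoherence:
    def test_self_coherence_is_one(self, rng):
        trials = noise_trials(rng, 5)
        a1, a2, cr = trial_averaged_spectra(trials, trials, 1000.0, small_grid())
        msc = magnitude_squared_coherence(cr, a1, a2)
        assert np.nanmax(np.abs(msc.values - 1.0)) < 1e-9

    def test_scale_invariance(self, rng):
        t1 = noise_trials(rng, 5)
        t2 = noise_trials(rng, 5)
        g = small_grid()
        a1, a2, cr = trial_averaged_spectra(t1, t2, 1000.0, g)
        m = magnitude_squared_coherence(cr, a1, a2)
        b1, b2, cs = trial_averaged_spectra(t1, [7.3 * x for x in t2], 1000.0, g)
        ms = magnitude_squared_coherence(cs, b1, b2)
        assert np.nanmax(np.abs(m.values - ms.values)) < 1e-9

    def test_single_trial_rejected(self, rng):
        with pytest.raises(ValueError):
            trial_averaged_spectra(noise_trials(rng, 1), noise_trials(rng, 1), 1000.0, small_grid())

    @pytest.mark.parametrize("k", [5, 10, 20])
    def test_independent_noise_mean_msc_near_one_over_k(self, rng, k):
        # E[MSC] ~ 1/K for independent trials
        g = small_grid(8, 60, 15)
        means = []
        for _ in range(3):
            a1, a2, cr = trial_averaged_spectra(
                noise_trials(rng, k), noise_trials(rng, k), 1000.0, g
            )
            means.append(np.nanmean(magnitude_squared_coherence(cr, a1, a2).values))
        assert np.mean(means) == pytest.approx(1.0 / k, rel=0.2)

    def test_zero_auto_spectrum_cells_masked(self, rng):
        g = small_grid()
        zeros = [np.zeros(400) for _ in range(3)]
        with pytest.warns(UserWarning):
            a1, a2, cr = trial_averaged_spectra(zeros, zeros, 1000.0, g)
            msc = magnitude_squared_coherence(cr, a1, a2)
        assert np.all(np.isnan(msc.values))


class TestSignificance:
    def test_analytic_threshold_values(self):
        assert analytic_threshold(20, 0.05) == pytest.approx(0.1459, abs=5e-5)
        assert analytic_threshold(2, 0.05) == pytest.approx(0.95)
        with pytest.raises(ValueError):
            analytic_threshold(1, 0.05)
        with pytest.raises(ValueError):
            analytic_threshold(20, 1.5)

    def test_analytic_mask_thresholds_cells(self, rng):
        g = small_grid()
        a1, a2, cr = trial_averaged_spectra(
            noise_trials(rng, 8), noise_trials(rng, 8), 1000.0, g
        )
        msc = magnitude_squared_coherence(cr, a1, a2)
        mask, thr = coherence_significance_mask(msc, 8, 0.05)
        assert np.array_equal(mask.values, msc.values > thr)

    def test_surrogate_mask_close_to_analytic_under_null(self, rng):
        g = small_grid(10, 40, 6)
        t1 = noise_trials(rng, 10, n=500)
        t2 = noise_trials(rng, 10, n=500)
        a1, a2, cr = trial_averaged_spectra(t1, t2, 1000.0, g)
        msc = magnitude_squared_coherence(cr, a1, a2)
        _, thr_s = coherence_significance_mask(
            msc, 10, 0.05, method="surrogate",
            trials1=t1, trials2=t2, fs=1000.0, grid=g, n_surrogates=40, seed=0,
        )
        # cellwise surrogate quantiles scatter around the analytic threshold
        assert np.median(thr_s) == pytest.approx(analytic_threshold(10, 0.05), rel=0.35)


def synthetic_result(msc_value=0.5, nf=6, nt=10, df=3.0, dt=0.02, mask=None):
    freqs = 13.0 + df * np.arange(nf)
    times = -dt * np.arange(nt)[::-1]
    msc = TFMap(np.full((nf, nt), msc_value), freqs, times, n_trials=20)
    m = np.ones((nf, nt), bool) if mask is None else mask
    return CoherenceResult(
        msc=msc,
        mask=TFMap(m, freqs, times, 20),
        params=WaveletParams(),
        pair="BB-BR",
        threshold=0.1459,
    )


class TestVolume:
    def test_all_masked_out_gives_zero(self):
        res = synthetic_result(mask=np.zeros((6, 10), bool))
        assert imc_volume(res, band=(13, 31), window=(-0.2, 0)).volume == 0.0

    def test_rectangle_closed_form(self):
        # MSC=0.5 over 6 bins x 3 Hz and 10 cells x 0.02 s: 0.5*18*0.2 = 1.8
        res = synthetic_result(0.5)
        vol = imc_volume(res, band=(12, 32), window=(-0.25, 0.01)).volume
        assert vol == pytest.approx(0.5 * 18 * 0.2)

    def test_additive_over_disjoint_bands_and_homogeneous(self):
        res = synthetic_result(0.4)
        full = imc_volume(res, band=(12, 32), window=(-0.25, 0.01)).volume
        lo = imc_volume(res, band=(12, 20.5), window=(-0.25, 0.01)).volume
        hi = imc_volume(res, band=(20.6, 32), window=(-0.25, 0.01)).volume
        assert lo + hi == pytest.approx(full)
        res2 = synthetic_result(0.8)
        assert imc_volume(res2, band=(12, 32), window=(-0.25, 0.01)).volume == pytest.approx(2 * full)

    def test_empty_band_rejected(self):
        res = synthetic_result()
        with pytest.raises(ValueError):
            imc_volume(res, band=(60, 70), window=(-0.2, 0))
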