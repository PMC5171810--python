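import numpy as np
import pytest

from spikeinfo.correlations import (
    bin_ensemble,
    compute_psth,
    estimate_correlation_functions,
    estimate_spectra,
    isi_statistics,
)
from spikeinfo.neurons import SpikeTrain, SpikeTrainEnsemble

from conftest import make_inhomogeneous_poisson, make_poisson_ensemble


def _ensemble_from_times(times_per_trial, duration, kind="repeated"):
    trains = tuple(
        SpikeTrain(times=np.asarray(t, dtype=float), duration=duration)
        for t in times_per_trial
    )
    return SpikeTrainEnsemble(trains=trains, ensemble_kind=kind, duration=duration)


class TestBinning:
    def test_two_spikes_two_bins(self):
        ens = _ensemble_from_times([[1.0, 2.0]], 3.0)
        b = bin_ensemble(ens, 0.5)
        assert (b.counts > 0).sum() == 2
        assert set(b.counts[b.counts > 0]) == {1}

    def test_empty_ensemble_all_zero(self):
        ens = _ensemble_from_times([[], []], 1.0)
        b = bin_ensemble(ens, 1.0)
        assert b.counts.sum() == 0

    def test_count_conservation(self, poisson_factory):
        ens = poisson_factory(20.0, 5.0, 4, seed=1)
        b = bin_ensemble(ens, 0.5)
        assert b.counts.sum() == ens.n_spikes

    def test_bin_wider_than_recording_rejected(self):
        ens = _ensemble_from_times([[0.5]], 1.0)
        with pytest.raises(ValueError):
            bin_ensemble(ens, 2000.0)


class TestPSTH:
    def test_identical_trains_reproduce_single_trial(self):
        times = [0.1, 0.55, 0.9]
        ens = _ensemble_from_times([times] * 5, 1.0)
        b = bin_ensemble(ens, 1.0)
        psth = compute_psth(b)
        single = bin_ensemble(_ensemble_from_times([times], 1.0), 1.0)
        assert np.allclose(psth, single.counts[0] / 0.001)

    def test_sinusoidal_rate_recovered(self, inhomogeneous_poisson_factory):
        nu0, m, f0, dt = 50.0, 0.6, 7.0, 0.0005
        t = np.arange(0, 4.0, dt)
        rate_t = nu0 * (1 + m * np.cos(2 * np.pi * f0 * t))
        ens = inhomogeneous_poisson_factory(rate_t, dt, 400, seed=2)
        psth = compute_psth(bin_ensemble(ens, 10.0))
        tt = (np.arange(len(psth)) + 0.5) * 0.01
        # least-squares amplitude of the known sinusoid
        c = np.cos(2 * np.pi * f0 * tt)
        amp = 2 * np.mean((psth - psth.mean()) * c)
        assert amp == pytest.approx(nu0 * m, rel=0.1)


class TestCorrelationFunctions:
    def test_poisson_flat_with_zero_lag_peak(self, poisson_factory):
        nu, delta = 50.0, 1.0
        ens = poisson_factory(nu, 20.0, 8, seed=3, kind="repeated")
        b = bin_ensemble(ens, delta)
        auto, cross = estimate_correlation_functions(b, max_lag=50.0)
        mid = len(auto.lags) // 2
        off = np.abs(auto.lags) > 1e-9
        assert np.mean(auto.values[off]) == pytest.approx(nu**2, rel=0.05)
        # zero-lag bin carries the nu/Delta delta contribution
        assert auto.values[mid] == pytest.approx(nu / (delta / 1000.0) + nu**2, rel=0.1)
        assert np.mean(cross.values) == pytest.approx(nu**2, rel=0.05)

    def test_identical_trains_cross_equals_auto(self):
        rng = np.random.default_rng(4)
        times = np.unique(np.sort(rng.random(60) * 10.0))
        ens = _ensemble_from_times([times] * 4, 10.0)
        b = bin_ensemble(ens, 2.0)
        auto, cross = estimate_correlation_functions(b, max_lag=40.0)
        assert np.allclose(auto.values, cross.values, rtol=1e-9)

    def test_against_brute_force_lagged_products(self):
        rng = np.random.default_rng(5)
        ens = _ensemble_from_times(
            [np.unique(np.sort(rng.random(15))) for _ in range(3)], 1.0
        )
        b = bin_ensemble(ens, 10.0)
        auto, cross = estimate_correlation_functions(b, max_lag=100.0)
        x = b.counts.astype(float)
        m, n = x.shape
        d2 = (b.bin_width / 1000.0) ** 2
        for lag_idx, lag in enumerate(auto.lags):
            l = int(round(lag / b.bin_width))
            if l < 0:
                continue
            a_bf = np.mean([
                np.dot(x[i, : n - l], x[i, l:]) / (n - l) for i in range(m)
            ]) / d2
            c_bf = np.mean([
                np.dot(x[i, : n - l], x[j, l:]) / (n - l)
                for i in range(m) for j in range(m) if i != j
            ]) / d2
            assert auto.values[lag_idx] == pytest.approx(a_bf, rel=1e-9, abs=1e-9)
            assert cross.values[lag_idx] == pytest.approx(c_bf, rel=1e-9, abs=1e-9)

    def test_psth_autocorrelation_identity(self):
        """autocorr(PSTH) = (M-1)/M * cross + auto / M, lag by lag."""
        rng = np.random.default_rng(6)
        ens = _ensemble_from_times(
            [np.unique(np.sort(rng.random(40) * 4)) for _ in range(5)], 4.0
        )
        b = bin_ensemble(ens, 5.0)
        auto, cross = estimate_correlation_functions(b, max_lag=50.0)
        m = b.n_trials
        psth = b.counts.mean(axis=0).astype(float)
        n = len(psth)
        d2 = (b.bin_width / 1000.0) ** 2
        for lag_idx, lag in enumerate(auto.lags):
            l = abs(int(round(lag / b.bin_width)))
            c_psth = np.dot(psth[: n - l], psth[l:]) / (n - l) / d2
            combo = (m - 1) / m * cross.values[lag_idx] + auto.values[lag_idx] / m
            assert c_psth == pytest.approx(combo, rel=1e-9, abs=1e-6)

    def test_single_trial_cross_rejected(self):
        ens = _ensemble_from_times([[0.1, 0.2]], 1.0)
        b = bin_ensemble(ens, 10.0)
        with pytest.raises(ValueError):
            estimate_correlation_functions(b, max_lag=100.0)


class TestSpectra:
    def test_poisson_flat_spectrum_equals_rate(self, poisson_factory):
        nu = 10.0
        ens = poisson_factory(nu, 40.0, 10, seed=7)
        sp = estimate_spectra(bin_ensemble(ens, 0.5), t_seg=4.0)
        assert np.mean(sp.s_auto) == pytest.approx(nu, rel=0.03)
        band = sp.freqs < 100
        assert np.mean(sp.s_auto[band]) == pytest.approx(nu, rel=0.05)

    def test_independent_trials_cross_spectrum_zero(self, poisson_factory):
        # "repeated" label but statistically independent trials = SNR 0
        ens = poisson_factory(20.0, 20.0, 16, seed=8, kind="repeated")
        sp = estimate_spectra(bin_ensemble(ens, 0.5), t_seg=4.0)
        assert abs(np.mean(sp.s_cross)) < 0.05 * np.mean(sp.s_auto)

    def test_matches_naive_periodogram_single_trial(self):
        rng = np.random.default_rng(9)
        times = np.unique(np.sort(rng.random(200) * 8.0))
        ens = _ensemble_from_times([times, times], 8.0)
        sp = estimate_spectra(bin_ensemble(ens, 1.0), t_seg=8.0)
        x = bin_ensemble(ens, 1.0).counts[0].astype(float)
        f = np.fft.rfft(x)[1:]
        naive = np.abs(f) ** 2 / 8.0
        assert np.allclose(sp.s_auto, naive, rtol=1e-9)

    def test_trial_permutation_invariance(self, poisson_factory):
        ens = poisson_factory(30.0, 10.0, 6, seed=10, kind="repeated")
        perm = SpikeTrainEnsemble(
            trains=ens.trains[::-1], ensemble_kind="repeated", duration=ens.duration
        )
        a = estimate_spectra(bin_ensemble(ens, 0.5), 2.0)
        b = estimate_spectra(bin_ensemble(perm, 0.5), 2.0)
        assert np.allclose(a.s_auto, b.s_auto)
        assert np.allclose(a.s_cross, b.s_cross)

    def test_bin_halving_stability_below_500hz(self, inhomogeneous_poisson_factory):
        dt = 0.0005
        t = np.arange(0, 8.0, dt)
        rate_t = 40.0 * (1 + 0.5 * np.cos(2 * np.pi * 11.0 * t))
        ens = inhomogeneous_poisson_factory(rate_t, dt, 32, seed=11)
        sp1 = estimate_spectra(bin_ensemble(ens, 1.0), 4.0)
        sp2 = estimate_spectra(bin_ensemble(ens, 0.5), 4.0)
        band1 = sp1.freqs <= 450
        band2 = sp2.freqs <= 450
        assert np.mean(sp1.s_auto[band1]) == pytest.approx(
            np.mean(sp2.s_auto[band2]), rel=0.05
        )

    def test_t_seg_larger_than_recording_rejected(self, poisson_factory):
        ens = poisson_factory(10.0, 2.0, 2, seed=12)
        with pytest.raises(ValueError):
            estimate_spectra(bin_ensemble(ens, 0.5), t_seg=10.0)


class TestISIStatistics:
    def test_poisson_renewal_statistics(self, poisson_factory):
        ens = poisson_factory(20.0, 100.0, 4, seed=13)
        st = isi_statistics(ens)
        assert st.cv == pytest.approx(1.0, abs=0.05)
        assert abs(st.serial_correlation) < 0.05
        # exponential ISI density: mean matches 1/rate
        assert st.mean_isi == pytest.approx(1 / 20.0, rel=0.05)

    def test_periodic_train_flagged(self):
        times = np.arange(0.1, 9.9, 0.1)
        ens = _ensemble_from_times([times], 10.0, kind="varying")
        st = isi_statistics(ens)
        assert st.cv == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(st.serial_correlation)

    def test_too_few_isis_rejected(self):
        ens = _ensemble_from_times([[0.5]], 1.0)
        with pytest.raises(ValueError):
            isi_statistics(ens)
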