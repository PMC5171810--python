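import numpy as np
import pytest

from spikeinfo.correlations import (
    SpectralPair,
    bin_ensemble,
    estimate_spectra,
    spectral_pair_from_coefficients,
)
from spikeinfo.diagnostics import rayleigh_entropy_bits
from spikeinfo.information import (
    info_correlation_theory,
    info_isi,
    info_lower_bound,
    info_psth_poisson,
)
from spikeinfo.inputs import InputParams, generate_ou
from spikeinfo.neurons import SpikeTrain, SpikeTrainEnsemble

from conftest import make_inhomogeneous_poisson, make_poisson_ensemble


def _surrogate_channel(seed, s_sig_scale=12.0, s_noise=8.0, m_trials=256,
                       f_max=500.0, df=0.25):
    """Frozen complex-Gaussian signal plus independent complex noise."""
    rng = np.random.default_rng(seed)
    freqs = np.arange(df, f_max + df / 2, df)
    s_n = s_noise * np.ones_like(freqs)
    s_s = s_sig_scale / (1 + (freqs / 60.0) ** 2)
    sig = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    sig = sig * np.sqrt(s_s / 2)
    noise = (rng.standard_normal((m_trials, len(freqs)))
             + 1j * rng.standard_normal((m_trials, len(freqs)))) * np.sqrt(s_n / 2)
    coeffs = sig[None, :] + noise
    sp = spectral_pair_from_coefficients(coeffs, freqs, t_seg=4.0, rate=10.0)
    exact = float(np.trapezoid(np.log2((np.abs(sig) ** 2 + s_n) / s_n), freqs))
    return sp, exact


def _flat_pair(s_auto, s_cross, n=500, rate=10.0):
    freqs = np.arange(1.0, n + 1.0)
    return SpectralPair(
        freqs=freqs,
        s_auto=np.full(n, s_auto),
        s_cross=np.full(n, s_cross),
        n_trials=100,
        n_segments=4,
        t_seg=1.0,
        rate=rate,
    )


class TestCorrelationTheory:
    def test_gaussian_channel_closed_form(self):
        """The spectral estimator reproduces the Gaussian-channel integral."""
        sp, exact = _surrogate_channel(seed=3)
        _, res = info_correlation_theory(sp)
        assert res.rate == pytest.approx(exact, rel=0.02)

    def test_zero_cross_spectrum_zero_information(self):
        sp = _flat_pair(10.0, 0.0)
        spectrum, res = info_correlation_theory(sp, debias=False)
        assert res.rate == pytest.approx(0.0, abs=1e-9)
        assert spectrum.clipped_fraction == 0.0
        # the finite-sample debias term is a small negative offset here
        _, res_db = info_correlation_theory(sp)
        assert abs(res_db.rate) < 0.05

    def test_cutoff_beyond_nyquist_rejected(self):
        sp = _flat_pair(10.0, 1.0)
        with pytest.raises(ValueError):
            info_correlation_theory(sp, cutoff_hz=2 * sp.nyquist)

    def test_per_spike_times_rate_equals_total(self):
        sp = _flat_pair(10.0, 2.0)
        _, res = info_correlation_theory(sp)
        assert res.per_spike * sp.rate == pytest.approx(res.rate)

    def test_unit_rescaling_leaves_rate_invariant(self, poisson_factory):
        """Stretching all times by k scales the bits/s rate by exactly 1/k."""
        ens = make_inhomogeneous_poisson(
            40.0 * (1 + 0.5 * np.cos(2 * np.pi * 9.0 * np.arange(0, 8, 5e-4))),
            5e-4, 64, seed=5,
        )
        k = 2.0
        scaled = SpikeTrainEnsemble(
            trains=tuple(
                SpikeTrain(times=tr.times * k, duration=tr.duration * k)
                for tr in ens.trains
            ),
            ensemble_kind="repeated",
            duration=ens.duration * k,
        )
        r1 = info_correlation_theory(estimate_spectra(bin_ensemble(ens, 0.5), 4.0))[1].rate
        r2 = info_correlation_theory(
            estimate_spectra(bin_ensemble(scaled, 0.5 * k), 4.0 * k)
        )[1].rate
        assert r2 * k == pytest.approx(r1, rel=1e-6)


class TestLowerBound:
    def test_zero_cross_gives_zero(self):
        assert info_lower_bound(_flat_pair(10.0, 0.0)).rate == pytest.approx(0.0)

    def test_bounded_by_full_estimate_on_surrogates(self):
        for seed in range(5):
            sp, _ = _surrogate_channel(seed=seed, s_sig_scale=6.0 + 3 * seed)
            full = info_correlation_theory(sp)[1].rate
            lb = info_lower_bound(sp).rate
            assert lb <= full * 1.01 + 0.1

    def test_equality_in_weak_signal_regime(self):
        sp, exact = _surrogate_channel(seed=9, s_sig_scale=0.15, m_trials=512)
        full = info_correlation_theory(sp)[1].rate
        lb = info_lower_bound(sp).rate
        assert lb == pytest.approx(full, rel=0.05)


class TestPSTHPoisson:
    def test_exact_on_inhomogeneous_poisson(self):
        dt = 5e-4
        t = np.arange(0, 12.0, dt)
        base = generate_ou(
            InputParams(kind="ou", tau_stim=20.0, sigma_eta=1.0, snr=0.0,
                        duration=12.0, sigma_convention="stationary"),
            seed=77,
        ).values
        rate_t = np.clip(30.0 * (1 + 0.5 * base), 0, None)
        ens = make_inhomogeneous_poisson(rate_t, dt, 128, seed=9)
        sp = estimate_spectra(bin_ensemble(ens, 0.5), 4.0)
        full = info_correlation_theory(sp)[1].rate
        pp = info_psth_poisson(sp).rate
        assert pp == pytest.approx(full, rel=0.1)

    def test_zero_cross_gives_zero(self):
        assert info_psth_poisson(_flat_pair(10.0, 0.0)).rate == pytest.approx(0.0)


class TestEntropyDecomposition:
    def test_rayleigh_uniform_decomposition_matches_log_variance_ratio(self):
        """Information per coefficient = difference of complex-Gaussian
        entropies = difference of (Rayleigh amplitude entropy + Jacobian
        term); the Euler-Mascheroni constants cancel in the difference."""
        rng = np.random.default_rng(21)
        sig1, sig2 = 3.0, 1.2
        n = 200_000

        def parts(sigma):
            c = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) * sigma / np.sqrt(2)
            amp = np.abs(c)
            scale = np.sqrt(np.mean(amp**2) / 2)
            return rayleigh_entropy_bits(scale) + np.mean(np.log2(amp))

        direct = np.log2(sig1**2 / sig2**2)
        decomposed = parts(sig1) - parts(sig2)
        assert decomposed == pytest.approx(direct, abs=0.02)


class TestISIInformation:
    def test_stimulus_independent_poisson_carries_no_isi_information(self):
        rep = make_poisson_ensemble(20.0, 8.0, 150, seed=31, kind="repeated")
        var = make_poisson_ensemble(20.0, 60.0, 10, seed=32, kind="varying")
        res = info_isi(rep, var)
        # a 20 Hz train could carry tens of bits/s; this must be near zero
        assert abs(res.rate) < 2.0

    def test_poisson_encoder_isi_close_to_full(self):
        """With a renewal-like Poisson encoder the ISI construction recovers
        the bulk of the spectral estimate."""
        dt = 5e-4
        base = generate_ou(
            InputParams(kind="ou", tau_stim=20.0, sigma_eta=1.0, snr=0.0,
                        duration=6.0, sigma_convention="stationary"),
            seed=41,
        ).values
        rate_t = np.clip(25.0 * (1 + 0.7 * base), 0, None)
        # conditional ISI histograms need many repeats to converge
        rep = make_inhomogeneous_poisson(rate_t, dt, 1400, seed=42)
        # varying: independent rate realizations
        var_trains = []
        for i in range(12):
            b = generate_ou(
                InputParams(kind="ou", tau_stim=20.0, sigma_eta=1.0, snr=0.0,
                            duration=50.0, sigma_convention="stationary"),
                seed=100 + i,
            ).values
            r = np.clip(25.0 * (1 + 0.7 * b), 0, None)
            var_trains.append(make_inhomogeneous_poisson(r, dt, 1, seed=200 + i).trains[0])
        var = SpikeTrainEnsemble(trains=tuple(var_trains), ensemble_kind="varying",
                                 duration=var_trains[0].duration)
        sp = estimate_spectra(bin_ensemble(rep, 0.5), 3.0)
        full = info_correlation_theory(sp)[1].rate
        res = info_isi(rep, var)
        assert res.rate == pytest.approx(full, rel=0.35)

    def test_insufficient_isis_rejected(self):
        rep = make_poisson_ensemble(5.0, 2.0, 3, seed=51, kind="repeated")
        var = make_poisson_ensemble(5.0, 2.0, 3, seed=52, kind="varying")
        with pytest.raises(ValueError):
            info_isi(rep, var)
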