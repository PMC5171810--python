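"""Second-order statistics of spike-train ensembles.

The two quantities that carry a stationary neuron's information are the
spike autocorrelation function (within a trial) and the trial
cross-correlation function (between distinct trials that received the same
frozen stimulus; identical to the PSTH autocorrelation up to the finite-trial
self-term).  Their Fourier transforms, the total spectrum ``S_auto(f)`` and
the stimulus-locked cross spectrum ``S_cross(f)``, feed the information
estimators.

Normalization convention: a homogeneous Poisson train of rate ``nu`` has a
flat spectrum ``S_auto(f) = nu`` (Hz) at all f > 0.  Correlation functions
are in rate-squared units (Hz^2); the zero-lag autocorrelation bin carries
the ``nu/Delta`` delta contribution, which is the spectral floor ``nu``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.fft import next_fast_len

from .neurons import SpikeTrainEnsemble

__all__ = [
    "BinnedEnsemble",
    "CorrelationFunction",
    "SpectralPair",
    "ISIStatistics",
    "bin_ensemble",
    "compute_psth",
    "estimate_correlation_functions",
    "estimate_spectra",
    "spectral_pair_from_coefficients",
    "isi_statistics",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinnedEnsemble:
    """Spike counts on half-open bins [k*Delta, (k+1)*Delta)."""

    counts: np.ndarray          # (trials, bins) integer counts
    bin_width: float            # ms
    duration: float             # s, after truncation to whole bins
    ensemble_kind: str

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def mean_rate(self) -> float:
        return float(self.counts.sum()) / (self.n_trials * self.duration)


@dataclass(frozen=True)
class CorrelationFunction:
    """Correlation function on a symmetric lag grid (ms), Hz^2 units."""

    lags: np.ndarray            # ms, symmetric about 0
    values: np.ndarray          # Hz^2 (or dimensionless if normalized)
    kind: Literal["auto", "cross"]
    rate: float                 # Hz
    normalized: bool = False

    def normalized_by_rate(self) -> "CorrelationFunction":
        """Return the same function normalized by nu^2 (dimensionless)."""
        if self.normalized:
            return self
        return CorrelationFunction(
            lags=self.lags,
            values=self.values / self.rate**2,
            kind=self.kind,
            rate=self.rate,
            normalized=True,
        )


@dataclass(frozen=True)
class SpectralPair:
    """One-sided spectral estimates (DC excluded) from a trial ensemble."""

    freqs: np.ndarray           # Hz
    s_auto: np.ndarray          # Hz (Poisson floor = nu)
    s_cross: np.ndarray         # Hz, real; NaN when < 2 trials
    n_trials: int
    n_segments: int
    t_seg: float                # s
    rate: float                 # Hz

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])


@dataclass(frozen=True)
class ISIStatistics:
    """Pooled interspike-interval statistics of an ensemble."""

    isi_values: np.ndarray      # s
    hist_density: np.ndarray    # probability density (1/s)
    hist_edges: np.ndarray      # s
    serial_correlation: float   # lag-1 correlation rho_1 (NaN if undefined)
    cv: float                   # coefficient of variation

    @property
    def mean_isi(self) -> float:
        return float(np.mean(self.isi_values))


def bin_ensemble(ens: SpikeTrainEnsemble, bin_width: float) -> BinnedEnsemble:
    """Bin each trial into exact spike counts; trailing partial bin dropped."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if bin_width / 1000.0 >= ens.duration:
        raise ValueError("bin_width must be smaller than the recording")
    width_s = bin_width / 1000.0
    n_bins = int(np.floor(ens.duration / width_s + 1e-9))
    counts = np.zeros((ens.n_trials, n_bins), dtype=np.int32)
    for i, train in enumerate(ens.trains):
        idx = np.floor(train.times / width_s).astype(np.int64)
        idx = idx[idx < n_bins]
        counts[i] = np.bincount(idx, minlength=n_bins)
    return BinnedEnsemble(
        counts=counts,
        bin_width=bin_width,
        duration=n_bins * width_s,
        ensemble_kind=ens.ensemble_kind,
    )


def compute_psth(binned: BinnedEnsemble) -> np.ndarray:
    """Trial-averaged rate trace in Hz (one value per bin)."""
    if binned.ensemble_kind != "repeated":
        log.warning(
            "PSTH of a %s ensemble is flat up to sampling noise", binned.ensemble_kind
        )
    return binned.counts.mean(axis=0) / (binned.bin_width / 1000.0)


def _fft_lagged_products(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Sum_k x_k y_{k+l} for l = 0..n_lags via FFT, per row, summed over rows."""
    n = x.shape[-1]
    nfft = next_fast_len(n + n_lags)
    f = np.fft.rfft(x, nfft, axis=-1)
    prod = np.fft.irfft((f * f.conj()).sum(axis=0), nfft)
    return prod[: n_lags + 1]


def estimate_correlation_functions(
    binned: BinnedEnsemble, max_lag: float
) -> tuple[CorrelationFunction, CorrelationFunction]:
    """Spike auto- and trial cross-correlation functions up to ``max_lag`` ms.

    The autocorrelation pools time-averaged lagged products over all trials
    (unbiased edge normalization).  The cross estimate averages lagged
    products over *distinct* trial pairs only, which is an unbiased estimate
    of the PSTH autocorrelation free of the 1/M self-term.
    """
    m, n = binned.counts.shape
    delta_s = binned.bin_width / 1000.0
    n_lags = int(round(max_lag / binned.bin_width))
    if n_lags >= n:
        raise ValueError("max_lag must be shorter than the recording")
    if m < 2:
        raise ValueError("cross-correlation requires at least 2 trials")
    x = binned.counts.astype(np.float64)
    auto_sum = _fft_lagged_products(x, n_lags)
    pooled = x.sum(axis=0, keepdims=True)
    cross_sum = _fft_lagged_products(pooled, n_lags) - auto_sum
    n_terms = (n - np.arange(n_lags + 1)).astype(float)

    auto_half = auto_sum / (m * n_terms) / delta_s**2
    cross_half = cross_sum / (m * (m - 1) * n_terms) / delta_s**2

    def _symmetric(half: np.ndarray) -> np.ndarray:
        return np.concatenate([half[:0:-1], half])

    lags = np.arange(-n_lags, n_lags + 1) * binned.bin_width
    rate = binned.mean_rate
    auto = CorrelationFunction(lags=lags, values=_symmetric(auto_half), kind="auto", rate=rate)
    cross = CorrelationFunction(lags=lags, values=_symmetric(cross_half), kind="cross", rate=rate)
    return auto, cross


def _segment_fft(binned: BinnedEnsemble, t_seg: float, taper: str):
    delta_s = binned.bin_width / 1000.0
    bins_per_seg = int(round(t_seg / delta_s))
    if bins_per_seg < 2 or t_seg > binned.duration + 1e-12:
        raise ValueError("t_seg must fit inside the recording")
    n_seg = binned.n_bins // bins_per_seg
    x = binned.counts[:, : n_seg * bins_per_seg].astype(np.float64)
    x = x.reshape(binned.n_trials, n_seg, bins_per_seg)
    if taper == "hann":
        w = np.hanning(bins_per_seg)
        x = (x - x.mean(axis=-1, keepdims=True)) * w
        norm = t_seg * np.mean(w**2)
    elif taper == "none":
        norm = t_seg
    else:
        raise ValueError(f"unknown taper {taper!r}")
    f = np.fft.rfft(x, axis=-1)[..., 1:]     # DC excluded
    freqs = np.fft.rfftfreq(bins_per_seg, delta_s)[1:]
    return f, freqs, norm, n_seg


def estimate_spectra(
    binned: BinnedEnsemble, t_seg: float, taper: str = "none"
) -> SpectralPair:
    """Bartlett-averaged spectra on segments of length ``t_seg`` seconds.

    ``S_auto`` averages per-trial, per-segment periodograms.  ``S_cross``
    averages cross-periodograms over distinct trial pairs within
    time-aligned segments, which requires a repeated (frozen-stimulus)
    ensemble to be meaningful; with fewer than two trials it is NaN.
    Frequency resolution is ``1/t_seg``; DC is excluded.
    """
    f, freqs, norm, n_seg = _segment_fft(binned, t_seg, taper)
    m = binned.n_trials
    s_auto = (np.abs(f) ** 2).mean(axis=(0, 1)) / norm
    if m >= 2:
        f_sum = f.sum(axis=0)
        abs2_sum = (np.abs(f) ** 2).sum(axis=0)
        pair_mean = (np.abs(f_sum) ** 2 - abs2_sum) / (m * (m - 1))
        s_cross = pair_mean.mean(axis=0) / norm
    else:
        s_cross = np.full_like(s_auto, np.nan)
    return SpectralPair(
        freqs=freqs,
        s_auto=s_auto,
        s_cross=s_cross,
        n_trials=m,
        n_segments=n_seg,
        t_seg=t_seg,
        rate=binned.mean_rate,
    )


def spectral_pair_from_coefficients(
    coeffs: np.ndarray, freqs: np.ndarray, t_seg: float, rate: float = np.nan
) -> SpectralPair:
    """Build a SpectralPair from per-trial Fourier coefficients.

    ``coeffs`` has shape (trials, freqs) and is normalized such that
    ``E|c|^2 = S_auto`` (i.e. coefficients divided by sqrt(T)).  Used for
    surrogate-channel constructions and for tying the Fourier-statistics
    diagnostics to the spectral estimators; uses the same distinct-pair
    cross estimator as :func:`estimate_spectra`.
    """
    coeffs = np.asarray(coeffs)
    m = coeffs.shape[0]
    s_auto = (np.abs(coeffs) ** 2).mean(axis=0)
    if m >= 2:
        c_sum = coeffs.sum(axis=0)
        abs2 = (np.abs(coeffs) ** 2).sum(axis=0)
        s_cross = (np.abs(c_sum) ** 2 - abs2) / (m * (m - 1))
    else:
        s_cross = np.full_like(s_auto, np.nan)
    return SpectralPair(
        freqs=np.asarray(freqs, dtype=float),
        s_auto=s_auto,
        s_cross=np.real(s_cross),
        n_trials=m,
        n_segments=1,
        t_seg=t_seg,
        rate=rate,
    )


def isi_statistics(ens: SpikeTrainEnsemble, min_bins: int = 50) -> ISIStatistics:
    """Pooled ISI histogram (Freedman-Diaconis, density), lag-1 serial
    correlation between successive ISIs and coefficient of variation.

    ISIs never straddle trial boundaries.  With zero ISI variance (perfectly
    periodic train) the serial correlation is undefined and returned as NaN.
    """
    isis = ens.pooled_isis()
    if len(isis) < 2:
        raise ValueError("need at least 2 ISIs for statistics")
    iqr = np.subtract(*np.percentile(isis, [75, 25]))
    if iqr > 0:
        width = 2.0 * iqr / len(isis) ** (1.0 / 3.0)
        n_bins = max(min_bins, int(np.ceil(np.ptp(isis) / width)))
    else:
        n_bins = min_bins
    density, edges = np.histogram(isis, bins=n_bins, density=True)

    pairs_a, pairs_b = [], []
    for tr in ens.trains:
        d = np.diff(tr.times)
        if len(d) >= 2:
            pairs_a.append(d[:-1])
            pairs_b.append(d[1:])
    # a relative guard: perfectly periodic trains carry epsilon-level ISI
    # jitter from floating point, for which rho_1 is meaningless
    degenerate = np.std(isis) <= 1e-9 * abs(np.mean(isis))
    if degenerate or not pairs_a:
        rho1 = np.nan
    else:
        a = np.concatenate(pairs_a)
        b = np.concatenate(pairs_b)
        if np.std(a) <= 1e-9 * abs(np.mean(a)) or np.std(b) <= 1e-9 * abs(np.mean(b)):
            rho1 = np.nan
        else:
            rho1 = float(np.corrcoef(a, b)[0, 1])
    cv = float(np.std(isis) / np.mean(isis))
    return ISIStatistics(
        isi_values=isis,
        hist_density=density,
        hist_edges=edges,
        serial_correlation=rho1,
        cv=cv,
    )
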