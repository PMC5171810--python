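"""Mutual-information rate estimators for stationary spike trains.

The central quantity is the spectral information density

    I(f) = log2( S_auto(f) / (S_auto(f) - S_cross(f)) )   [bits / (s Hz)]

where ``S_auto`` is the across-trial variance of the spike-train Fourier
coefficients (the spike spectrum) and ``S_auto - S_cross`` is the variance
of the mean-corrected coefficients under a frozen stimulus (the noise
spectrum).  Because the coefficients are asymptotically complex Gaussian and
independent across frequencies, the total rate is the one-sided frequency
integral of the density,

    I = integral_0^fc I(f) df    [bits / s],

which coincides with the mutual-information rate of a Gaussian channel with
total spectrum ``S_auto`` and noise spectrum ``S_auto - S_cross``.  The DC
bin carries the mean firing rate, not stimulus modulation, and is excluded.

Three comparison estimators are provided:

* a coherence-style **lower bound** (first-order linearization of the
  density in ``S_cross/S_auto``),
* the **PSTH-Poisson approximation** that keeps the measured stimulus-locked
  spectrum but replaces the noise spectrum by the flat Poisson floor ``nu``
  (the spectrum of the Poisson surrogate with the same PSTH is
  ``nu + S_cross`` by Campbell's theorem, so its density is
  ``log2(1 + S_cross/nu)``), and
* the **ISI information**, which treats interspike intervals as independent
  symbols and differences the entropy of the marginal ISI distribution
  against the entropy conditioned on the frozen stimulus and the interval's
  start time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import digamma

from .correlations import SpectralPair
from .neurons import SpikeTrainEnsemble

__all__ = [
    "InfoSpectrum",
    "InfoResult",
    "info_correlation_theory",
    "info_lower_bound",
    "info_psth_poisson",
    "info_isi",
]

#: relative floor applied to the noise spectrum before taking the log
NOISE_FLOOR = 1e-6


@dataclass(frozen=True)
class InfoSpectrum:
    """Per-frequency information density in bits/(s Hz)."""

    freqs: np.ndarray
    density: np.ndarray         # floored density used for the total
    raw_density: np.ndarray     # unclipped (may be negative/NaN from sampling)
    clipped_fraction: float


@dataclass(frozen=True)
class InfoResult:
    """Integrated information rate with estimator provenance."""

    rate: float                 # bits / s
    per_spike: float            # bits / spike (= rate / nu)
    method: str
    cutoff_hz: float
    diagnostics: dict = field(default_factory=dict)


def _select_band(sp: SpectralPair, cutoff_hz: float | None):
    cutoff = sp.nyquist if cutoff_hz is None else float(cutoff_hz)
    if cutoff > sp.nyquist + 1e-9:
        raise ValueError(f"cutoff {cutoff} Hz exceeds Nyquist {sp.nyquist} Hz")
    mask = sp.freqs <= cutoff + 1e-12
    return sp.freqs[mask], sp.s_auto[mask], sp.s_cross[mask], cutoff


def _result(rate: float, nu: float, method: str, cutoff: float, diag: dict) -> InfoResult:
    per_spike = rate / nu if nu > 0 else np.nan
    return InfoResult(
        rate=float(rate), per_spike=float(per_spike), method=method,
        cutoff_hz=float(cutoff), diagnostics=diag,
    )


def info_correlation_theory(
    sp: SpectralPair,
    cutoff_hz: float | None = None,
    noise_floor: float = NOISE_FLOOR,
    debias: bool = True,
) -> tuple[InfoSpectrum, InfoResult]:
    """Full correlation-theory information rate from a spectral pair.

    Where the estimated noise spectrum ``S_auto - S_cross`` is not positive
    it is floored at ``noise_floor * S_auto`` and the affected fraction of
    frequencies is reported.  ``debias`` subtracts the expected log-bias of
    the chi-square distributed spectral estimates (exact for central
    estimates); it scales as one over the trial-segment count and is
    negligible except at very small trial numbers.
    """
    freqs, s_auto, s_cross, cutoff = _select_band(sp, cutoff_hz)
    # S_auto - S_cross is algebraically the mean-corrected coefficient
    # variance, hence nonnegative up to floating point; negative sampling
    # excursions of S_cross are kept (their log contributions average out,
    # clipping them would bias the integral upward at small trial counts)
    noise = s_auto - s_cross
    floor = noise_floor * s_auto
    clipped = noise < floor
    density = np.log2(s_auto / np.maximum(noise, floor))
    if debias and sp.n_trials >= 2 and np.isfinite(sp.n_segments):
        # E[ln x_hat] = ln x + psi(k) - ln k for a chi^2_2k spectral estimate
        j = sp.n_trials * sp.n_segments
        k = (sp.n_trials - 1) * sp.n_segments
        density = density + ((digamma(k) - np.log(k)) - (digamma(j) - np.log(j))) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(noise > 0, np.log2(s_auto / np.where(noise > 0, noise, 1.0)), np.nan)
    rate = float(np.trapezoid(density, freqs))
    spectrum = InfoSpectrum(
        freqs=freqs,
        density=density,
        raw_density=raw,
        clipped_fraction=float(np.mean(clipped)),
    )
    diag = {
        "n_trials": sp.n_trials,
        "n_segments": sp.n_segments,
        "clipped_fraction": spectrum.clipped_fraction,
    }
    return spectrum, _result(rate, sp.rate, "correlation", cutoff, diag)


def info_lower_bound(
    sp: SpectralPair, cutoff_hz: float | None = None
) -> InfoResult:
    """Linearized (first-order kernel) information rate; a strict lower bound.

    Keeping only the first-order term of the density in the ratio
    ``x = S_cross/S_auto`` gives ``x/ln 2 <= -log2(1 - x)``, with equality in
    the weak-signal (linear) regime where the cross spectrum is first order
    in the stimulus-to-noise ratio.
    """
    freqs, s_auto, s_cross, cutoff = _select_band(sp, cutoff_hz)
    # negative sampling excursions of S_cross are kept: they cancel positive
    # ones on integration, and x/ln2 <= -log2(1-x) holds pointwise for any x
    x = s_cross / s_auto
    density = x / np.log(2.0)
    rate = float(np.trapezoid(density, freqs))
    diag = {"n_trials": sp.n_trials, "n_segments": sp.n_segments}
    return _result(rate, sp.rate, "lower_bound", cutoff, diag)


def info_psth_poisson(
    sp: SpectralPair,
    nu: float | None = None,
    cutoff_hz: float | None = None,
) -> InfoResult:
    """Information of the Poisson surrogate sharing the measured PSTH.

    The surrogate keeps the stimulus-locked spectrum ``S_cross`` but its
    noise spectrum is the flat Poisson floor ``nu``, so the density is
    ``log2(1 + S_cross/nu)``.  Exact for truly (inhomogeneous) Poisson spike
    trains; an under- or overestimate when real temporal structure makes the
    noise spectrum deviate from ``nu``.
    """
    freqs, _, s_cross, cutoff = _select_band(sp, cutoff_hz)
    nu = sp.rate if nu is None else float(nu)
    if not nu > 0:
        raise ValueError("need a positive firing rate")
    # keep negative sampling excursions (they cancel on integration); the
    # floor only guards the log against pathological fluctuations
    density = np.log2(np.maximum(1.0 + s_cross / nu, NOISE_FLOOR))
    rate = float(np.trapezoid(density, freqs))
    diag = {"n_trials": sp.n_trials, "n_segments": sp.n_segments, "nu": nu}
    return _result(rate, nu, "psth_poisson", cutoff, diag)


# --------------------------------------------------------------------------
# ISI information
# --------------------------------------------------------------------------

def _entropy_mm(counts: np.ndarray) -> float:
    """Plug-in entropy (bits) with Miller-Madow bias correction."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    h = -np.sum(p * np.log2(p))
    k = len(p)
    return float(h + (k - 1) / (2.0 * n * np.log(2.0)))


def _isi_events(ens: SpikeTrainEnsemble):
    """(trial, start time, isi) arrays for all within-trial intervals."""
    trials, starts, isis = [], [], []
    for i, tr in enumerate(ens.trains):
        if tr.n_spikes >= 2:
            d = np.diff(tr.times)
            trials.append(np.full(len(d), i))
            starts.append(tr.times[:-1])
            isis.append(d)
    if not trials:
        raise ValueError("no ISIs in ensemble")
    return (
        np.concatenate(trials),
        np.concatenate(starts),
        np.concatenate(isis),
    )


def info_isi(
    ens_repeated: SpikeTrainEnsemble,
    ens_varying: SpikeTrainEnsemble,
    n_quantiles: int = 32,
    context_bin_ms: float = 5.0,
    min_context_count: int = 16,
    fractions: Sequence[float] = (1.0, 0.5, 0.25),
    min_isis: int = 200,
) -> InfoResult:
    """Information rate carried by ISIs treated as independent symbols.

    ISIs are discretized into ``n_quantiles`` equiprobable bins of the
    *marginal* ISI distribution (estimated from the varying-stimulus
    ensemble), so the symbol vocabulary is bounded and small-sample entropy
    corrections are effective; by the data-processing inequality the
    quantized estimate can only lose information, never invent it.  The
    marginal symbol entropy (about ``log2 n_quantiles``) is differenced
    against the entropy conditioned on the frozen stimulus and the
    interval's start time (discretized at ``context_bin_ms``).  Conditioning
    contexts are fixed once from the full repeated ensemble (those holding
    at least ``min_context_count`` intervals, occupancy-weighted); both
    entropies get Miller-Madow corrections and the information per interval
    is extrapolated linearly in inverse data fraction over the *same*
    context set, which keeps the residual bias a smooth function of the
    sample size.  The rate is the information per interval times the firing
    rate.
    """
    trials_r, starts_r, isis_r = _isi_events(ens_repeated)
    isis_v = ens_varying.pooled_isis()
    if len(isis_v) < min_isis or len(isis_r) < min_isis:
        raise ValueError(
            f"need at least {min_isis} ISIs in each ensemble "
            f"(have {len(isis_v)} varying, {len(isis_r)} repeated); "
            "increase recording duration"
        )
    # marginal-quantile partition of the ISI axis
    edges = np.quantile(isis_v, np.linspace(0.0, 1.0, n_quantiles + 1)[1:-1])
    edges = np.unique(edges)
    n_bins = len(edges) + 1
    bins_v = np.searchsorted(edges, isis_v, side="right")
    bins_r = np.searchsorted(edges, isis_r, side="right")
    ctx_r = (starts_r / (context_bin_ms / 1000.0)).astype(np.int64)

    # fix the context set from the full repeated data
    ctx_ids, ctx_counts = np.unique(ctx_r, return_counts=True)
    kept = ctx_ids[ctx_counts >= min_context_count]
    if len(kept) == 0:
        raise ValueError(
            "no stimulus context accumulated enough ISIs; increase the number "
            f"of repeated trials (need >= {min_context_count} intervals per context)"
        )
    in_kept = np.isin(ctx_r, kept)
    coverage = float(in_kept.mean())
    ctx_index = {c: i for i, c in enumerate(kept)}
    ctx_arr = np.array([ctx_index[c] for c in ctx_r[in_kept]])
    bins_kept = bins_r[in_kept]
    trials_kept = trials_r[in_kept]
    weights_full = np.bincount(ctx_arr, minlength=len(kept)).astype(float)
    weights_full /= weights_full.sum()

    m = ens_repeated.n_trials
    fractions = sorted(fractions, reverse=True)
    key = ctx_arr * n_bins + bins_kept
    info_by_fraction = []
    for frac in fractions:
        n_trials_f = max(2, int(round(frac * m)))
        sel = trials_kept < n_trials_f
        n_var_f = max(min_isis // 2, int(round(frac * len(isis_v))))
        h_marginal = _entropy_mm(np.bincount(bins_v[:n_var_f], minlength=n_bins))
        table = np.bincount(key[sel], minlength=len(kept) * n_bins)
        table = table.reshape(len(kept), n_bins)
        n_per = table.sum(axis=1)
        ok = n_per >= 2
        with np.errstate(divide="ignore", invalid="ignore"):
            p = table / np.where(n_per > 0, n_per, 1)[:, None]
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        h_rows = -plogp.sum(axis=1)
        k_occ = (table > 0).sum(axis=1)
        h_rows = h_rows + (k_occ - 1) / (2.0 * np.where(n_per > 0, n_per, 1) * np.log(2.0))
        # contexts depleted at this fraction fall back to the marginal
        # entropy (contributing zero information, a conservative choice)
        h_cond = float(
            np.sum(weights_full[ok] * h_rows[ok])
            + np.sum(weights_full[~ok]) * h_marginal
        )
        info_by_fraction.append(h_marginal - h_cond)

    if len(info_by_fraction) >= 2:
        # extrapolate from the two best-sampled fractions: deeper
        # subsamples leave the linear-bias regime and would under-correct
        inv = 1.0 / np.asarray(fractions[:2])
        slope, intercept = np.polyfit(inv, info_by_fraction[:2], 1)
        info_per_isi = float(intercept)
    else:
        slope = np.nan
        info_per_isi = float(info_by_fraction[0])

    nu = ens_varying.mean_rate
    rate = info_per_isi * nu
    diag = {
        "info_per_isi_bits": info_per_isi,
        "info_by_fraction": dict(zip(fractions, info_by_fraction)),
        "extrapolation_slope": float(slope),
        "context_coverage": coverage,
        "n_contexts": int(len(kept)),
        "n_isis_repeated": int(len(isis_r)),
        "n_isis_varying": int(len(isis_v)),
        "n_quantiles": n_quantiles,
        "context_bin_ms": context_bin_ms,
    }
    return _result(rate, nu, "isi", np.nan, diag)
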