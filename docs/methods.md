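# Methods

## Model and estimator

The package measures the Shannon mutual information rate between a
stationary spike train `r(t)` and the stimulus component `s(t)` of its
input current. The working assumptions are those of the underlying theory:
`r`, `s` and the noise `n` are stationary with finite memory and finite,
non-zero coefficient of variation, and `s` and `n` are independent. Under
these assumptions the trial-wise Fourier coefficients

    c_R(ω) = (1/√T) Σ_j exp(−i ω t_j)

converge, across trials, to complex normal distributions that are
independent across frequencies: zero-mean under varying stimuli, with a
stimulus-locked mean under a frozen stimulus. Mean-corrected amplitudes are
Rayleigh, phases uniform and uninformative; the Euler–Mascheroni constant
in the Rayleigh differential entropy cancels when signal and noise
entropies are differenced (`diagnostics.rayleigh_entropy_bits` exposes the
identity, and the test suite verifies the decomposition numerically).

The variance of `c_R` across varying stimuli is the spike spectrum
`S_auto(f)`; the variance of the mean-corrected coefficients under a frozen
stimulus is the noise spectrum `S_auto(f) − S_cross(f)`, where `S_cross` is
the spectrum of the trial cross-correlation function (equivalently, of the
PSTH autocorrelation, without the finite-trial self-term). Each frequency
is then an independent complex-Gaussian channel contributing
`log2[S_auto/(S_auto − S_cross)]` bits per coefficient, and the total rate
is the one-sided frequency integral of that density (trapezoid, DC
excluded, default cutoff at Nyquist). The one-sided integral of the full
log-ratio equals the two-sided integral of the half-density; it also
reproduces the closed-form Gaussian-channel rate exactly, which the test
suite checks against a surrogate channel with known spectra.

### Spectral estimation

Spike trains are binned at Δ = 0.5 ms (Nyquist 1 kHz; the informative band
of the reference models ends well below 500 Hz). Per trial, segments of
`T_seg = 4 s` (0.25 Hz resolution) are Fourier transformed; no taper by
default (a Hann option exists). Normalization is fixed by the Poisson
floor: a homogeneous Poisson train of rate ν has `S_auto(f) = ν`.
`S_cross` uses products over *distinct* trial pairs within time-aligned
segments — an unbiased estimator free of the `S_auto/M` self-term that
squaring the PSTH would introduce (algebraically it equals
`(M|c̄|² − Σ|c|²/M)·…`; the identity with the mean-corrected sample
variance, `S_auto − S_cross = Var(c)`, is what makes the log density always
well defined).

Numerical choices in the density:

* Negative sampling excursions of `S_cross` are **not** clipped inside the
  log. The noise term `S_auto − S_cross` is a variance and stays positive;
  clipping `S_cross` at zero would add a half-normal rectification bias
  that grows as trials decrease (at 8 trials on a 29 Hz cell it inflated
  the rate several-fold). Negative excursions cancel on integration.
* A floor of `1e-6 · S_auto` guards the log where the estimated noise
  spectrum collapses; the affected fraction of frequencies is reported as
  `clipped_fraction` and is ~0 in all reference runs.
* A chi-square log-bias correction `ψ(k) − ln k` (with `k` the
  trial-segment count of each spectral estimate) is subtracted by default.
  It is exact for central estimates, negligible beyond ~30 trial-segments,
  and brings few-trial estimates within a few percent of the closed form
  (verified by Monte Carlo on the surrogate channel).

Even so, the estimator retains a positive `O(1/(M·n_seg))` bias at
frequencies where the coherence approaches one (the noise spectrum is then
small relative to its own estimation noise). Slowly modulated, strongly
driven cells therefore need on the order of 100+ trial-segments for
percent-level accuracy; the reference runs in the tests and the acceptance
script are sized accordingly.

### Comparison estimators

* **Lower bound** — the first-order term of the density in
  `x = S_cross/S_auto`: `I_lb(f) = x/ln 2 ≤ −log2(1−x)`. This is the
  package's reading of the linearized (first-order kernel) variant: from a
  spectral pair alone the kernel orders of the cross-correlation are not
  separable, and the first-order expansion is the unique linearization that
  is computable from `(S_auto, S_cross)`, is a strict lower bound, and
  coincides with the full rate in the weak-signal linear regime (tested).
* **PSTH-Poisson approximation** — the information of the inhomogeneous
  Poisson surrogate sharing the measured PSTH. By Campbell's theorem its
  total spectrum is `ν + S_cross` and its noise spectrum the flat `ν`, so
  `I_P(f) = log2(1 + S_cross/ν)`. For genuinely Poisson spike trains this
  equals the full estimator (a self-consistency test enforces it); for real
  temporal structure it under- or overestimates depending on whether the
  true noise spectrum lies below or above ν in the informative band.
* **ISI information** — interspike intervals treated as independent
  symbols. ISIs are quantized into 32 equiprobable bins of the marginal ISI
  distribution (varying-stimulus ensemble); the marginal symbol entropy is
  differenced against the entropy conditioned on the frozen stimulus and
  the interval's start time (5 ms context bins, contexts with ≥16 intervals,
  occupancy-weighted, the context set frozen across data fractions).
  Histograms get Miller–Madow corrections, and the information per interval
  is extrapolated linearly in inverse data fraction from the two
  best-sampled fractions; the rate is bits-per-interval × ν. The
  marginal-quantile design bounds the vocabulary so the small-sample
  corrections are valid, at the cost of a data-processing loss — the
  estimate is conservative by construction. This construction stands in for
  a procedure whose published details are not available to this package and
  is documented as an approximation; its calibration tests are a
  stimulus-independent Poisson ensemble (≈0 bits/s) and a Poisson encoder
  with slowly modulated rate (matches the spectral estimate once ~10³
  repeats are available).

### Direct (word-entropy) method

Binary words of `L` bins at Δt = 2 ms (sliding positions, counts clipped to
binary), `L = 2…10`, data fractions `{1, 1/2, 1/4, 1/8}`. Plug-in entropies
are extrapolated linearly in inverse data fraction; entropy *rates*
`H(L)/(LΔt)` are then extrapolated to `1/(LΔt) → 0` over the largest
**stably sampled** word lengths, where stability requires the smallest data
fraction to leave at least 4 trials per occupied word in the across-trial
histograms. Outside that regime the inverse-fraction extrapolation stops
removing the downward entropy bias and the information inflates — the
method's classical failure mode; such runs set `undersampled` in the
diagnostics instead of failing silently. On the reduced LIF comparison
point (512 repeats of 8 s) the direct estimate agrees with the spectral
estimator within a few percent, while at 1% of the trials it is off by
several hundred percent and the spectral estimator stays within 20% — the
data-efficiency contrast the estimator exists to demonstrate.

## Input currents

`X(t) = SNR·s(t) + √(1−SNR²)·n(t)`, `SNR ∈ [0,1)`, with `s` and `n`
independent and identically distributed. The weights are variance
preserving — the input's marginal law is independent of SNR, so firing
rates stay fixed across SNR sweeps — and the stimulus share of the input
variance is SNR². The amplitude-weight form was fixed by requiring the
reference threshold-based simulation to reproduce its documented
information rate (~59 bits/s); the variance-share alternative (share = SNR)
overshoots it by ~80% and every ratio-based reading undershoots by ≥50%.

OU processes use the exact discretization `x_{k+1} = a x_k + ξ_k`,
`a = exp(−dt/τ)`, so the step affects resolution only. The amplitude
convention is `dx = −(x/τ)dt + σ_η dW` with time in **milliseconds**:
σ_η is the white-noise (diffusion) amplitude and the stationary variance is
`σ_η²·τ_stim/2`. This convention is pinned down analytically: the Rice
crossing-rate formula for the threshold-based model then predicts 8.46,
4.98 and 4.91 Hz at the three documented TB operating points (reference
values: 8.3, 5, 5 Hz), whereas reading σ_η as the stationary standard
deviation predicts
3.8, 0.05 and 4.9 Hz. A `sigma_convention="stationary"` switch retains the
alternative reading.

Bimodal inputs draw i.i.d. values per 0.05 ms step from a zero-mean
two-Gaussian mixture. The reference distribution is specified only
graphically in the source material; the default (±33 mV, width 13 mV, equal
weights) was chosen so the reference LIF (τ_mem = 10 ms,
V_th = −V_reset = 3 mV, SNR 0.5) sits at its documented ~12 Hz / ~81 ms
operating point. Bimodal-input quantities are treated as qualitative
diagnostics, not numeric targets.

Seeding is counter-based from a single master seed (stimulus and noise
streams never share a seed; frozen-stimulus ensembles share one stimulus
seed), making every ensemble a pure function of (parameters, seed).

## Neuron models

All four models are driven by zero-mean input (subthreshold regime: no
spikes without fluctuations) and integrate their linear subthreshold
dynamics with exact exponential updates (matrix exponential for the coupled
adaptive system), so dt only limits spike-time resolution; threshold
crossings are linearly interpolated. Trials start at V = 0 and discard a
settling window of 10× the slowest time constant; the inputs themselves are
stationary from the first sample.

* **TB** (threshold-based): V is the low-pass filtered input; a spike marks
  each upward crossing of V_th; no reset. Validated against the Rice
  crossing-rate formula computed from the simulated voltage's sample
  autocovariance (test, 10% tolerance).
* **LIF**: threshold-and-reset on the same filter. Validated against the
  closed-form constant-drive ISI and the documented rate span
  1.1–107 Hz across τ_mem = 100 → 3.2 ms.
* **aLIF**: `τ_mem V̇ = −V + α w + X`, `τ_w ẇ = −w + β V`, spike/reset on V
  only, w continuous through the spike, α = −2, β = 4. The coupled form was
  selected over spike-triggered-adaptation variants because it has the
  stated subthreshold resonance, reduces exactly to LIF at α = β = 0
  (tested), and reproduces the documented 50 Hz operating point within 2%.
* **EIF**: exponential spike-initiation term `Δ_T exp((V−V_th)/Δ_T)` with
  Δ_T = 0.5 mV; spike registered at V_th, then reset; the exponent is
  capped so no step can overflow. Approaches the matched LIF as Δ_T → 0
  (tested) and reproduces the documented 0.9–91 Hz span.

Default dt = 0.05 ms everywhere (validation guards require
dt ≤ min(τ_stim, τ_mem)/10).

## What the synthetic ensembles do and do not emulate

The generators produce exactly the stationary, finite-memory regime the
theory assumes: OU or i.i.d.-bimodal currents, frozen-versus-varying trial
designs, stationarity from the first retained sample. They do **not**
emulate non-stationary or clocked stimuli, adaptation on behavioral
time scales, recording artifacts, or spike-sorting noise. Passing tests
therefore show that the estimators are correct and well calibrated *within
the stationary finite-memory class*; on real recordings the diagnostics
module (complex Gaussianity, Rayleigh amplitudes, uniform phases,
cross-frequency decorrelation) is the intended gatekeeper for whether the
theory applies.

## Problem sizes

Reference quantities in tests and `scripts/acceptance.py` use desk-scale
runs chosen so that sampling error is comfortably inside each stated
tolerance: firing rates from ≥10 trials × 60–300 s; the TB information
rate from 160 frozen-stimulus repeats × 20 s; the ISI-deviation sweep from
400 repeats × 5 s plus 20 × 100 s varying recordings per condition; the
direct-method comparison from 512 repeats × 8 s. The `full` experiment
scale (1000 × 40 s) matches the reference simulations.

## Known limitations

* The spectral estimator's high-coherence bias (~1/(M·n_seg)) means
  few-trial estimates of strongly locked, slowly modulated cells are upper
  estimates; the chi-square debias removes only the central part.
* The ISI estimator's quantile discretization bounds its range at
  log2(32) bits per interval and loses some information by construction.
* The lower bound is the first-order expansion of the density, not a
  stimulus-coherence estimate; with access to the stimulus waveform a
  coherence-based bound would be sharper in the nonlinear regime.
* No multitaper spectra, no cross-neuron correlations, no non-stationary
  extensions; analytic closed-form correlation functions of the
  threshold-based model are not included — only the numerical estimation
  path.
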