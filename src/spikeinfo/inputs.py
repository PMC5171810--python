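"""Stationary stochastic input currents for spiking-neuron simulations.

Every neuron model in this package is driven by an input current that is a
mixture of a stimulus process ``s(t)`` and an independent noise process
``n(t)``::

    X(t) = SNR * s(t) + sqrt(1 - SNR**2) * n(t),   SNR in [0, 1)

Both component processes share the same marginal statistics, so the weights
are variance preserving (the input variance is independent of SNR) and the
stimulus share of the input variance is SNR**2.  Two process families are
provided:

* an Ornstein-Uhlenbeck (OU) process with correlation time ``tau_stim``
  (exponential autocovariance, Lorentzian spectrum), and
* an i.i.d.-per-sample draw from a zero-mean bimodal Gaussian mixture.

OU amplitude convention
-----------------------
With time measured in milliseconds the OU stochastic differential equation is

    dx = -(x / tau_stim) dt + sigma_eta dW_t,

so ``sigma_eta`` is the white-noise (diffusion) amplitude in mV/sqrt(ms) and
the stationary standard deviation is ``sigma_eta * sqrt(tau_stim / 2)``.
This convention is pinned down by the printed firing rates of the
threshold-based model via the Rice crossing-rate formula (see
docs/methods.md).  Set ``sigma_convention="stationary"`` to interpret
``sigma_eta`` directly as the stationary standard deviation instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "InputParams",
    "CurrentTrace",
    "InputEnsemble",
    "InvalidResolutionError",
    "generate_ou",
    "generate_bimodal",
    "generate_trace",
    "mix_stimulus_noise",
    "build_input_ensemble",
    "iter_input_traces",
    "derive_trial_seeds",
]

EnsembleKind = Literal["repeated", "varying"]

#: all derived seeds stay below 2**31 so they round-trip through C integers
_SEED_MOD = 2**31 - 1


class InvalidResolutionError(ValueError):
    """Sampling step too coarse for the requested time constants."""


@dataclass(frozen=True)
class InputParams:
    """Parameters of the stimulus/noise processes and their mixture.

    Times follow the convention used throughout the package: time constants
    and the sampling step ``dt`` are in milliseconds, the trace ``duration``
    is in seconds.
    """

    kind: Literal["ou", "bimodal"] = "ou"
    sigma_eta: float = 1.0          # mV / sqrt(ms)  (see module docstring)
    tau_stim: float = 10.0          # ms
    snr: float = 0.0
    dt: float = 0.05                # ms
    duration: float = 10.0          # s
    bimodal_spec: tuple[tuple[float, float, float], ...] = ()
    sigma_convention: Literal["diffusion", "stationary"] = "diffusion"

    def __post_init__(self) -> None:
        if self.kind not in ("ou", "bimodal"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if not 0.0 <= self.snr < 1.0:
            raise ValueError(f"snr must lie in [0, 1), got {self.snr}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "ou":
            if self.tau_stim <= 0:
                raise ValueError("tau_stim must be positive for OU inputs")
            if self.dt > self.tau_stim / 10.0:
                raise InvalidResolutionError(
                    f"dt={self.dt} ms too coarse for tau_stim={self.tau_stim} ms "
                    "(require dt <= tau_stim/10)"
                )
        else:
            if not self.bimodal_spec:
                raise ValueError("bimodal inputs need a nonempty bimodal_spec")
            w = sum(c[2] for c in self.bimodal_spec)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"bimodal_spec weights must sum to 1, got {w}")
            if any(c[1] < 0 for c in self.bimodal_spec):
                raise ValueError("bimodal component widths must be >= 0")
        if self.sigma_convention not in ("diffusion", "stationary"):
            raise ValueError(f"unknown sigma_convention {self.sigma_convention!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))

    @property
    def sigma_stationary(self) -> float:
        """Stationary standard deviation of one component process (mV)."""
        if self.kind == "bimodal":
            locs = np.array([c[0] for c in self.bimodal_spec])
            widths = np.array([c[1] for c in self.bimodal_spec])
            weights = np.array([c[2] for c in self.bimodal_spec])
            mean = float(np.dot(weights, locs))
            var = float(np.dot(weights, widths**2 + (locs - mean) ** 2))
            return np.sqrt(var)
        if self.sigma_convention == "stationary":
            return self.sigma_eta
        return self.sigma_eta * np.sqrt(self.tau_stim / 2.0)


@dataclass(frozen=True)
class CurrentTrace:
    """A uniformly sampled current trace (mV)."""

    values: np.ndarray              # mV
    dt: float                       # ms
    duration: float                 # s
    seed: int

    def __post_init__(self) -> None:
        n_expected = int(round(self.duration * 1000.0 / self.dt))
        if len(self.values) != n_expected:
            raise ValueError(
                f"trace length {len(self.values)} != round(duration/dt) = {n_expected}"
            )

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.values)) * (self.dt / 1000.0)


@dataclass(frozen=True)
class InputEnsemble:
    """A set of input-current trials sharing one sampling grid.

    ``repeated`` ensembles share a single frozen stimulus realization across
    trials with independent noise per trial; ``varying`` ensembles redraw
    both stimulus and noise every trial.
    """

    traces: tuple[CurrentTrace, ...]
    ensemble_kind: EnsembleKind
    stimulus_seeds: tuple[int, ...]
    noise_seeds: tuple[int, ...]
    params: InputParams

    def __post_init__(self) -> None:
        if self.ensemble_kind not in ("repeated", "varying"):
            raise ValueError(f"unknown ensemble_kind {self.ensemble_kind!r}")
        if self.ensemble_kind == "repeated":
            if len(set(self.stimulus_seeds)) != 1:
                raise ValueError("repeated ensembles must share one stimulus seed")
        elif len(set(self.stimulus_seeds)) != len(self.stimulus_seeds):
            raise ValueError("varying ensembles need distinct stimulus seeds")
        if len(set(self.noise_seeds)) != len(self.noise_seeds):
            raise ValueError("noise seeds must be distinct across trials")

    @property
    def n_trials(self) -> int:
        return len(self.traces)


def generate_ou(params: InputParams, seed: int) -> CurrentTrace:
    """Sample one stationary OU path with exact discretization.

    The update ``x[k+1] = a x[k] + xi_k`` uses ``a = exp(-dt/tau)`` and
    Gaussian innovations with variance ``sigma_stat**2 (1 - a**2)``, so the
    sampled path has the exact stationary statistics at any ``dt`` (the step
    only limits resolution, never biases variance or correlation time).  The
    initial value is drawn from the stationary distribution.
    """
    if params.kind != "ou":
        raise ValueError("generate_ou requires params.kind == 'ou'")
    rng = np.random.default_rng(seed)
    n = params.n_samples
    a = np.exp(-params.dt / params.tau_stim)
    sig = params.sigma_stationary
    if sig == 0.0:
        values = np.zeros(n)
    else:
        innovations = rng.standard_normal(n) * (sig * np.sqrt(1.0 - a * a))
        x0 = rng.standard_normal() * sig
        values, _ = lfilter([1.0], [1.0, -a], innovations, zi=np.array([a * x0]))
    return CurrentTrace(values=values, dt=params.dt, duration=params.duration, seed=int(seed))


def generate_bimodal(params: InputParams, seed: int) -> CurrentTrace:
    """Sample i.i.d. draws per time step from a zero-centred Gaussian mixture.

    The mixture defined by ``bimodal_spec`` (location mV, width mV, weight)
    is re-centred to zero mean so the resulting current is always zero mean
    regardless of the component locations.
    """
    if params.kind != "bimodal":
        raise ValueError("generate_bimodal requires params.kind == 'bimodal'")
    rng = np.random.default_rng(seed)
    n = params.n_samples
    locs = np.array([c[0] for c in params.bimodal_spec])
    widths = np.array([c[1] for c in params.bimodal_spec])
    weights = np.array([c[2] for c in params.bimodal_spec])
    locs = locs - np.dot(weights, locs)  # enforce zero mean
    comp = rng.choice(len(locs), size=n, p=weights)
    values = rng.standard_normal(n) * widths[comp] + locs[comp]
    return CurrentTrace(values=values, dt=params.dt, duration=params.duration, seed=int(seed))


def generate_trace(params: InputParams, seed: int) -> CurrentTrace:
    """Dispatch to the generator matching ``params.kind``."""
    if params.kind == "ou":
        return generate_ou(params, seed)
    return generate_bimodal(params, seed)


def mix_stimulus_noise(s: CurrentTrace, n: CurrentTrace, snr: float) -> CurrentTrace:
    """Variance-preserving mixture ``X = snr * s + sqrt(1 - snr**2) * n``."""
    if not 0.0 <= snr < 1.0:
        raise ValueError(f"snr must lie in [0, 1), got {snr}")
    if s.dt != n.dt or len(s.values) != len(n.values):
        raise ValueError("stimulus and noise traces must share dt and duration")
    if snr == 0.0:
        values = n.values
    else:
        values = snr * s.values + np.sqrt(1.0 - snr * snr) * n.values
    seed = (1000003 * s.seed + n.seed) % _SEED_MOD
    return CurrentTrace(values=values, dt=s.dt, duration=s.duration, seed=seed)


def derive_trial_seeds(
    master_seed: int, n_trials: int, ensemble_kind: EnsembleKind
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Counter-based (stimulus, noise) seed derivation from one master seed.

    Stimulus and noise streams never share a seed; repeated ensembles reuse a
    single stimulus seed across trials.
    """
    ss = np.random.SeedSequence(master_seed)
    state = ss.generate_state(2 * n_trials + 1, dtype=np.uint64) % _SEED_MOD
    state = [int(v) for v in state]
    noise_seeds = tuple(state[1 : n_trials + 1])
    if ensemble_kind == "repeated":
        stim_seeds = tuple([state[0]] * n_trials)
    else:
        stim_seeds = tuple(state[n_trials + 1 :])
    if set(stim_seeds) & set(noise_seeds):
        # astronomically unlikely; regenerate deterministically
        return derive_trial_seeds(master_seed + 1, n_trials, ensemble_kind)
    return stim_seeds, noise_seeds


def iter_input_traces(
    params: InputParams,
    n_trials: int,
    ensemble_kind: EnsembleKind,
    master_seed: int,
) -> Iterator[CurrentTrace]:
    """Lazily yield the mixed input trace of each trial (memory friendly)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    stim_seeds, noise_seeds = derive_trial_seeds(master_seed, n_trials, ensemble_kind)
    frozen_stim: CurrentTrace | None = None
    for i in range(n_trials):
        noise = generate_trace(params, noise_seeds[i])
        if params.snr == 0.0:
            yield noise
            continue
        if ensemble_kind == "repeated":
            if frozen_stim is None:
                frozen_stim = generate_trace(params, stim_seeds[i])
            stim = frozen_stim
        else:
            stim = generate_trace(params, stim_seeds[i])
        yield mix_stimulus_noise(stim, noise, params.snr)


def build_input_ensemble(
    params: InputParams,
    n_trials: int,
    ensemble_kind: EnsembleKind,
    master_seed: int,
) -> InputEnsemble:
    """Build an in-memory trial ensemble; a pure function of (params, seed)."""
    stim_seeds, noise_seeds = derive_trial_seeds(master_seed, n_trials, ensemble_kind)
    traces = tuple(iter_input_traces(params, n_trials, ensemble_kind, master_seed))
    return InputEnsemble(
        traces=traces,
        ensemble_kind=ensemble_kind,
        stimulus_seeds=stim_seeds,
        noise_seeds=noise_seeds,
        params=params,
    )
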