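"""The four spiking neuron models: TB, LIF, aLIF and EIF.

All models are driven by a zero-mean input current ``X(t)`` (mV, input
resistance absorbed) and operate in the subthreshold regime: with no input
fluctuations the voltage stays at zero and no spikes occur.

* **TB** (threshold-based / level-crossing): the membrane voltage is the
  first-order low-pass filter of ``X(t)`` with time constant ``tau_mem``; a
  spike marks every upward crossing of ``V_th``.  There is no reset, so the
  spike times carry the full temporal structure of the voltage process.
* **LIF**: same leaky integration, but crossing ``V_th`` resets the voltage
  to ``V_reset``.
* **aLIF**: LIF plus a linear adaptation variable, giving a subthreshold
  frequency preference::

      tau_mem dV/dt = -V + alpha * w + X(t)
      tau_w   dw/dt = -w + beta * V

  with threshold/reset on ``V`` only; ``w`` is continuous through spikes.
  ``alpha = -2, beta = 4`` (negative feedback loop) are the reference values.
* **EIF**: LIF plus the exponential spike-initiation term
  ``Delta_T exp((V - V_th)/Delta_T)``; a spike is registered when ``V``
  reaches ``V_th``, then the voltage resets.

Subthreshold linear dynamics use exact exponential (matrix-exponential for
aLIF) updates, so the integration step only limits spike-time resolution.
Each trial starts from ``V = 0`` and a settling window of ten times the
slowest intrinsic time constant is discarded to enforce stationarity (the
input itself is stationary from the first sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy.linalg import expm
from scipy.signal import lfilter

from ._kernels import alif_kernel, eif_kernel, lif_kernel
from .inputs import (
    CurrentTrace,
    InputEnsemble,
    InputParams,
    InvalidResolutionError,
    iter_input_traces,
)

__all__ = [
    "NeuronParams",
    "SpikeTrain",
    "SpikeTrainEnsemble",
    "simulate",
    "simulate_ensemble",
    "simulate_threshold_based",
    "simulate_lif",
    "simulate_alif",
    "simulate_eif",
    "tb_membrane_voltage",
]

Model = Literal["TB", "LIF", "aLIF", "EIF"]


@dataclass(frozen=True)
class NeuronParams:
    """Neuron model parameters (time constants ms, voltages mV)."""

    model: Model
    tau_mem: float              # ms
    v_th: float                 # mV
    v_reset: float | None = None    # mV (LIF / aLIF / EIF)
    alpha: float | None = None      # aLIF coupling (dimensionless)
    beta: float | None = None       # aLIF coupling (dimensionless)
    tau_w: float | None = None      # ms (aLIF)
    delta_t: float | None = None    # mV (EIF slope factor)

    def __post_init__(self) -> None:
        if self.model not in ("TB", "LIF", "aLIF", "EIF"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.tau_mem <= 0:
            raise ValueError("tau_mem must be positive")
        if self.model != "TB" and self.v_reset is None:
            raise ValueError(f"{self.model} requires v_reset")
        if self.model == "TB" and self.v_reset is not None:
            raise ValueError("TB model has no reset")
        if self.model == "aLIF" and None in (self.alpha, self.beta, self.tau_w):
            raise ValueError("aLIF requires alpha, beta and tau_w")
        if self.model == "EIF":
            if self.delta_t is None or self.delta_t <= 0:
                raise ValueError("EIF requires delta_t > 0")


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (s) within [0, duration)."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = self.times
        if len(t) and (t[0] < 0 or t[-1] >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    @property
    def rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class SpikeTrainEnsemble:
    """Trial-indexed spike trains sharing a common duration."""

    trains: tuple[SpikeTrain, ...]
    ensemble_kind: str
    duration: float

    def __post_init__(self) -> None:
        if any(abs(tr.duration - self.duration) > 1e-9 for tr in self.trains):
            raise ValueError("all trains must share the ensemble duration")

    @property
    def n_trials(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains)

    @property
    def mean_rate(self) -> float:
        """Trial-averaged firing rate nu (Hz)."""
        return self.n_spikes / (self.n_trials * self.duration)

    def pooled_isis(self) -> np.ndarray:
        """Within-trial interspike intervals pooled across trials (s)."""
        chunks = [np.diff(tr.times) for tr in self.trains if tr.n_spikes >= 2]
        if not chunks:
            return np.empty(0)
        return np.concatenate(chunks)


def _check_resolution(neuron: NeuronParams, dt: float) -> None:
    if dt > neuron.tau_mem / 10.0:
        raise InvalidResolutionError(
            f"dt={dt} ms too coarse for tau_mem={neuron.tau_mem} ms "
            "(require dt <= tau_mem/10)"
        )


def _settle_seconds(neuron: NeuronParams, settle_s: float | None) -> float:
    if settle_s is not None:
        return float(settle_s)
    slowest = neuron.tau_mem
    if neuron.tau_w is not None:
        slowest = max(slowest, neuron.tau_w)
    return 10.0 * slowest / 1000.0


def tb_membrane_voltage(neuron: NeuronParams, trace: CurrentTrace) -> np.ndarray:
    """Low-pass filtered input current of the TB model (exact update, mV)."""
    a = np.exp(-trace.dt / neuron.tau_mem)
    return lfilter([1.0 - a], [1.0, -a], trace.values)


def _tb_times_ms(neuron: NeuronParams, trace: CurrentTrace) -> np.ndarray:
    v = tb_membrane_voltage(neuron, trace)
    idx = np.nonzero((v[:-1] < neuron.v_th) & (v[1:] >= neuron.v_th))[0]
    frac = (neuron.v_th - v[idx]) / (v[idx + 1] - v[idx])
    return (idx + frac) * trace.dt


def _lif_times_ms(neuron: NeuronParams, trace: CurrentTrace) -> np.ndarray:
    a = np.exp(-trace.dt / neuron.tau_mem)
    return lif_kernel(
        np.ascontiguousarray(trace.values, dtype=np.float64),
        a, neuron.v_th, neuron.v_reset, 0.0, trace.dt,
    )


def _alif_update_matrices(neuron: NeuronParams, dt: float):
    """Exact per-step propagator of the linear (V, w) system under ZOH input."""
    a_mat = np.array(
        [
            [-1.0 / neuron.tau_mem, neuron.alpha / neuron.tau_mem],
            [neuron.beta / neuron.tau_w, -1.0 / neuron.tau_w],
        ]
    )
    e_mat = expm(a_mat * dt)
    b_vec = np.array([1.0 / neuron.tau_mem, 0.0])
    g_vec = np.linalg.solve(a_mat, (e_mat - np.eye(2)) @ b_vec)
    return e_mat, g_vec


def _alif_times_ms(neuron: NeuronParams, trace: CurrentTrace) -> np.ndarray:
    e_mat, g_vec = _alif_update_matrices(neuron, trace.dt)
    return alif_kernel(
        np.ascontiguousarray(trace.values, dtype=np.float64),
        e_mat[0, 0], e_mat[0, 1], e_mat[1, 0], e_mat[1, 1],
        g_vec[0], g_vec[1],
        neuron.v_th, neuron.v_reset, 0.0, 0.0, trace.dt,
    )


def _eif_times_ms(neuron: NeuronParams, trace: CurrentTrace) -> np.ndarray:
    a = np.exp(-trace.dt / neuron.tau_mem)
    return eif_kernel(
        np.ascontiguousarray(trace.values, dtype=np.float64),
        a, neuron.delta_t, neuron.v_th, neuron.v_reset, 0.0, trace.dt,
    )


_TRACE_SIMULATORS = {
    "TB": _tb_times_ms,
    "LIF": _lif_times_ms,
    "aLIF": _alif_times_ms,
    "EIF": _eif_times_ms,
}


def _finalize(times_ms: np.ndarray, trace: CurrentTrace, settle: float) -> SpikeTrain:
    times = times_ms / 1000.0
    times = times[times >= settle] - settle
    duration = trace.duration - settle
    # guard against a crossing interpolated exactly onto the end of the trace
    times = times[times < duration]
    return SpikeTrain(times=times, duration=duration)


def _run(
    neuron: NeuronParams,
    traces: Iterable[CurrentTrace],
    ensemble_kind: str,
    settle_s: float | None,
) -> SpikeTrainEnsemble:
    settle = _settle_seconds(neuron, settle_s)
    step = _TRACE_SIMULATORS[neuron.model]
    trains = []
    duration = None
    for trace in traces:
        _check_resolution(neuron, trace.dt)
        if trace.duration <= settle:
            raise ValueError(
                f"trace duration {trace.duration} s does not exceed the "
                f"settling window {settle} s"
            )
        trains.append(_finalize(step(neuron, trace), trace, settle))
        duration = trace.duration - settle
    if not trains:
        raise ValueError("no input traces")
    return SpikeTrainEnsemble(
        trains=tuple(trains), ensemble_kind=ensemble_kind, duration=duration
    )


def simulate(
    neuron: NeuronParams, inputs: InputEnsemble, settle_s: float | None = None
) -> SpikeTrainEnsemble:
    """Simulate every trial of an in-memory input ensemble."""
    return _run(neuron, inputs.traces, inputs.ensemble_kind, settle_s)


def simulate_ensemble(
    neuron: NeuronParams,
    params: InputParams,
    n_trials: int,
    ensemble_kind: str,
    master_seed: int,
    settle_s: float | None = None,
) -> SpikeTrainEnsemble:
    """Generate inputs lazily (one trial at a time) and simulate them.

    Produces bit-identical spike trains to ``simulate(neuron,
    build_input_ensemble(params, ...))`` while holding only one current trace
    in memory, which matters for long recordings.
    """
    traces = iter_input_traces(params, n_trials, ensemble_kind, master_seed)
    return _run(neuron, traces, ensemble_kind, settle_s)


def simulate_threshold_based(
    neuron: NeuronParams, inputs: InputEnsemble, settle_s: float | None = None
) -> SpikeTrainEnsemble:
    """Level-crossing model: a spike at each upward crossing of ``V_th``."""
    if neuron.model != "TB":
        raise ValueError("simulate_threshold_based requires model='TB'")
    return simulate(neuron, inputs, settle_s)


def simulate_lif(
    neuron: NeuronParams, inputs: InputEnsemble, settle_s: float | None = None
) -> SpikeTrainEnsemble:
    if neuron.model != "LIF":
        raise ValueError("simulate_lif requires model='LIF'")
    return simulate(neuron, inputs, settle_s)


def simulate_alif(
    neuron: NeuronParams, inputs: InputEnsemble, settle_s: float | None = None
) -> SpikeTrainEnsemble:
    if neuron.model != "aLIF":
        raise ValueError("simulate_alif requires model='aLIF'")
    return simulate(neuron, inputs, settle_s)


def simulate_eif(
    neuron: NeuronParams, inputs: InputEnsemble, settle_s: float | None = None
) -> SpikeTrainEnsemble:
    if neuron.model != "EIF":
        raise ValueError("simulate_eif requires model='EIF'")
    return simulate(neuron, inputs, settle_s)
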