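import numpy as np
import pytest

from spikeinfo.neurons import SpikeTrain, SpikeTrainEnsemble


def make_poisson_ensemble(rate, duration, n_trials, seed, kind="varying"):
    """Homogeneous Poisson spike-train ensemble (trials independent)."""
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_trials):
        n = rng.poisson(rate * duration)
        t = np.unique(np.sort(rng.random(n) * duration))
        trains.append(SpikeTrain(times=t, duration=duration))
    return SpikeTrainEnsemble(trains=tuple(trains), ensemble_kind=kind, duration=duration)


def make_inhomogeneous_poisson(rate_t, dt_s, n_trials, seed, kind="repeated"):
    """Poisson trains driven by a frozen rate trace rate_t (Hz per sample)."""
    rng = np.random.default_rng(seed)
    duration = len(rate_t) * dt_s
    p = np.clip(rate_t * dt_s, 0.0, 1.0)
    trains = []
    for _ in range(n_trials):
        idx = np.nonzero(rng.random(len(p)) < p)[0]
        t = np.sort(idx * dt_s + rng.random(len(idx)) * dt_s)
        trains.append(SpikeTrain(times=t, duration=duration))
    return SpikeTrainEnsemble(trains=tuple(trains), ensemble_kind=kind, duration=duration)


@pytest.fixture(scope="session")
def poisson_factory():
    return make_poisson_ensemble


@pytest.fixture(scope="session")
def inhomogeneous_poisson_factory():
    return make_inhomogeneous_poisson
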