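"""Plain-text spike-file input/output.

Format (tab separated, one spike per row)::

    # spikeinfo-spikes v1  duration_s=<float>  ensemble_kind=<repeated|varying>  n_trials=<int>
    0   0.012345678
    0   0.104500000
    1   0.001200000

Trial indices are 0-based; times are seconds with nanosecond precision.
Trials with zero spikes are represented implicitly through ``n_trials`` in
the header.  Rows must be grouped by trial with strictly increasing times
within a trial; malformed rows are rejected with their line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .inputs import CurrentTrace
from .neurons import SpikeTrain, SpikeTrainEnsemble

__all__ = [
    "read_spike_file",
    "write_spike_file",
    "write_trace_file",
    "SpikeFileError",
]

_MAGIC = "# spikeinfo-spikes v1"


class SpikeFileError(ValueError):
    """Raised for malformed spike files; carries the offending line number."""


def write_spike_file(path: str | Path, ens: SpikeTrainEnsemble) -> None:
    path = Path(path)
    lines = [
        f"{_MAGIC}\tduration_s={ens.duration:.9f}"
        f"\tensemble_kind={ens.ensemble_kind}\tn_trials={ens.n_trials}"
    ]
    for i, train in enumerate(ens.trains):
        lines.extend(f"{i}\t{t:.9f}" for t in train.times)
    path.write_text("\n".join(lines) + "\n")


def write_trace_file(path: str | Path, trace: CurrentTrace) -> None:
    """Export a current trace as two-column delimited text (time_s, value_mV)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# current-trace dt_ms={trace.dt} duration_s={trace.duration}\n")
        fh.write("time_s\tvalue_mV\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{t:.6f}\t{v:.6g}\n")


def read_spike_file(path: str | Path) -> SpikeTrainEnsemble:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(_MAGIC):
            raise SpikeFileError(f"{path}: missing spike-file header")
        fields = {}
        for token in header.split("\t")[1:]:
            key, _, value = token.partition("=")
            fields[key] = value
        try:
            duration = float(fields["duration_s"])
            kind = fields["ensemble_kind"]
            n_trials = int(fields["n_trials"])
        except (KeyError, ValueError) as exc:
            raise SpikeFileError(f"{path}: malformed header ({exc})") from exc
        if kind not in ("repeated", "varying"):
            raise SpikeFileError(f"{path}: unknown ensemble_kind {kind!r}")

        times: list[list[float]] = [[] for _ in range(n_trials)]
        current = -1
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SpikeFileError(f"{path}:{lineno}: expected 'trial<TAB>time_s'")
            try:
                trial = int(parts[0])
                t = float(parts[1])
            except ValueError:
                raise SpikeFileError(f"{path}:{lineno}: non-numeric field") from None
            if not 0 <= trial < n_trials:
                raise SpikeFileError(
                    f"{path}:{lineno}: trial index {trial} outside 0..{n_trials - 1}"
                )
            if trial < current:
                raise SpikeFileError(f"{path}:{lineno}: rows not grouped by trial")
            current = trial
            if t < 0:
                raise SpikeFileError(f"{path}:{lineno}: negative spike time {t}")
            if t >= duration:
                raise SpikeFileError(
                    f"{path}:{lineno}: spike time {t} not below duration {duration}"
                )
            if times[trial] and t <= times[trial][-1]:
                raise SpikeFileError(
                    f"{path}:{lineno}: spike times not strictly increasing"
                )
            times[trial].append(t)
    trains = tuple(
        SpikeTrain(times=np.asarray(ts, dtype=float), duration=duration) for ts in times
    )
    return SpikeTrainEnsemble(trains=trains, ensemble_kind=kind, duration=duration)
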