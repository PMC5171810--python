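"""Experiment drivers chaining simulation, estimation and information.

An :class:`ExperimentConfig` bundles an input block, a neuron block,
estimation settings and a sweep (a list of override mappings applied on top
of the base blocks, e.g. ``{"input.tau_stim": 5.0, "neuron.v_th": 1.58}``).
:func:`run_experiment` produces a tidy table with one row per sweep point
and estimator, carrying the seeds and config hash needed to regenerate any
row exactly.  :func:`reproduce` exposes pre-baked configurations for the
reference simulation studies (threshold-based, LIF, aLIF and EIF neurons
under OU input) at ``reduced`` (desk-scale), ``full`` or ``smoke`` scale.

Convention: configuration times are in milliseconds except durations, which
are seconds; spike files are always seconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .correlations import bin_ensemble, estimate_spectra, isi_statistics
from .direct import direct_info
from .information import (
    info_correlation_theory,
    info_isi,
    info_lower_bound,
    info_psth_poisson,
)
from .inputs import InputParams
from .neurons import NeuronParams, simulate_ensemble

__all__ = [
    "EstimationSettings",
    "ExperimentConfig",
    "run_experiment",
    "reproduce",
    "figure_config",
    "FIGURE_IDS",
    "BIMODAL_DEFAULT",
]

log = logging.getLogger(__name__)

#: default bimodal mixture: equal-weight Gaussian components at +-33 mV,
#: width 13 mV; with the reference LIF (tau_mem=10 ms, V_th=-V_reset=3 mV,
#: SNR=0.5) this puts the model at its documented ~12 Hz operating point
BIMODAL_DEFAULT: tuple[tuple[float, float, float], ...] = (
    (-33.0, 13.0, 0.5),
    (33.0, 13.0, 0.5),
)


@dataclass(frozen=True)
class EstimationSettings:
    """Estimation block: binning, spectral and estimator settings."""

    bin_width_ms: float = 0.5
    t_seg_s: float = 4.0
    cutoff_hz: float | None = None
    n_repeats: int = 64
    repeat_duration_s: float = 12.0
    n_varying: int = 10
    varying_duration_s: float = 30.0
    estimators: tuple[str, ...] = ("correlation", "lower_bound", "psth_poisson")
    direct_dt_ms: float = 2.0
    direct_l_grid: tuple[int, ...] = tuple(range(2, 11))
    direct_fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125)
    isi_quantiles: int = 32
    isi_context_bin_ms: float = 5.0


@dataclass(frozen=True)
class ExperimentConfig:
    input: InputParams
    neuron: NeuronParams
    estimation: EstimationSettings = EstimationSettings()
    sweep: tuple[dict, ...] = field(default_factory=tuple)
    master_seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        inp = dict(data.get("input", {}))
        if "bimodal_spec" in inp and inp["bimodal_spec"]:
            inp["bimodal_spec"] = tuple(tuple(c) for c in inp["bimodal_spec"])
        est = dict(data.get("estimation", {}))
        for key in ("estimators", "direct_l_grid", "direct_fractions"):
            if key in est:
                est[key] = tuple(est[key])
        sweep = tuple(dict(s) for s in data.get("sweep", []))
        return cls(
            input=InputParams(**inp),
            neuron=NeuronParams(**data["neuron"]),
            estimation=EstimationSettings(**est),
            sweep=sweep,
            master_seed=int(data.get("master_seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _apply_overrides(cfg: ExperimentConfig, overrides: dict):
    """Apply 'input.x' / 'neuron.y' overrides to the base blocks."""
    inp_kw, neu_kw = {}, {}
    for key, value in overrides.items():
        block, _, name = key.partition(".")
        if block == "input":
            inp_kw[name] = value
        elif block == "neuron":
            neu_kw[name] = value
        else:
            raise ValueError(f"unknown override target {key!r}")
    inp = replace(cfg.input, **inp_kw) if inp_kw else cfg.input
    neu = replace(cfg.neuron, **neu_kw) if neu_kw else cfg.neuron
    return inp, neu


def _point_seed(master_seed: int, point: int, stream: int) -> int:
    return int(
        np.random.SeedSequence([master_seed, point, stream]).generate_state(1)[0]
        % (2**31 - 1)
    )


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Simulate and estimate every sweep point; one row per estimator.

    Estimator failures are recorded in the row's ``error`` column and the
    run continues.  Every row carries the config hash and the seeds used.
    """
    est = cfg.estimation
    sweep = cfg.sweep or ({},)
    chash = cfg.config_hash()
    rows = []
    for point, overrides in enumerate(sweep):
        inp, neuron = _apply_overrides(cfg, overrides)
        seed_rep = _point_seed(cfg.master_seed, point, 0)
        seed_var = _point_seed(cfg.master_seed, point, 1)
        log.info("sweep point %d/%d: %s", point + 1, len(sweep), overrides or "base")

        inp_rep = replace(inp, duration=est.repeat_duration_s)
        ens_rep = simulate_ensemble(neuron, inp_rep, est.n_repeats, "repeated", seed_rep)
        nu = ens_rep.mean_rate
        binned = bin_ensemble(ens_rep, est.bin_width_ms)
        sp = estimate_spectra(binned, min(est.t_seg_s, binned.duration))

        ens_var = None
        needs_varying = any(e in est.estimators for e in ("isi",))
        if needs_varying:
            inp_var = replace(inp, duration=est.varying_duration_s)
            ens_var = simulate_ensemble(neuron, inp_var, est.n_varying, "varying", seed_var)

        base_row = {
            "point": point,
            "overrides": json.dumps(overrides, sort_keys=True),
            "firing_rate_hz": nu,
            "config_hash": chash,
            "seed_repeated": seed_rep,
            "seed_varying": seed_var if needs_varying else None,
        }
        for name in est.estimators:
            row = dict(base_row, estimator=name, error=None)
            try:
                if name == "correlation":
                    spectrum, res = info_correlation_theory(sp, est.cutoff_hz)
                    row["clipped_fraction"] = spectrum.clipped_fraction
                elif name == "lower_bound":
                    res = info_lower_bound(sp, est.cutoff_hz)
                elif name == "psth_poisson":
                    res = info_psth_poisson(sp, cutoff_hz=est.cutoff_hz)
                elif name == "isi":
                    res = info_isi(
                        ens_rep,
                        ens_var,
                        n_quantiles=est.isi_quantiles,
                        context_bin_ms=est.isi_context_bin_ms,
                    )
                elif name == "direct":
                    binned_rep_d = bin_ensemble(ens_rep, est.direct_dt_ms)
                    binned_var_d = (
                        bin_ensemble(ens_var, est.direct_dt_ms) if ens_var else None
                    )
                    de = direct_info(
                        binned_rep_d,
                        binned_var_d,
                        l_grid=est.direct_l_grid,
                        fractions=est.direct_fractions,
                    )
                    row.update(
                        rate_bits_per_s=de.info,
                        bits_per_spike=de.info / nu if nu > 0 else np.nan,
                        h_total=de.h_total,
                        h_noise=de.h_noise,
                    )
                    rows.append(row)
                    continue
                else:
                    raise ValueError(f"unknown estimator {name!r}")
                row.update(rate_bits_per_s=res.rate, bits_per_spike=res.per_spike)
            except Exception as exc:  # noqa: BLE001 - recorded per row
                log.warning("estimator %s failed at point %d: %s", name, point, exc)
                row.update(rate_bits_per_s=np.nan, bits_per_spike=np.nan, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pre-baked figure configurations (Table-1 parameter rows)
# --------------------------------------------------------------------------

_TB = dict(model="TB", tau_mem=5.0, v_th=0.6)

_FIG5B_PAIRS = tuple(
    {"input.tau_stim": ts, "neuron.v_th": vt}
    for ts, vt in zip((1.0, 2.0, 5.0, 10.0, 20.0), (0.46, 0.81, 1.58, 2.41, 3.29))
)

# 9 stimulus time constants are swept but only 8 thresholds are specified for
# the 50 Hz LIF study; the default pairing below covers the first 8 values
# and is deliberately exposed here so it can be edited in config.
_FIG5A_PAIRS = tuple(
    {"input.tau_stim": ts, "neuron.v_th": vt, "neuron.v_reset": -vt}
    for ts, vt in zip(
        (0.2, 0.5, 1.0, 2.0, 10.0, 20.0, 50.0, 100.0),
        (0.03, 0.06, 0.12, 0.21, 0.65, 1.01, 1.69, 2.45),
    )
)

_TAU_MEM_GRID = ({"neuron.tau_mem": v} for v in (3.2, 10.0, 31.6, 100.0))

_FIG6F_INSET_PAIRS = tuple(
    {"neuron.tau_w": tw, "neuron.v_th": vt}
    for tw, vt in zip(
        (3.2, 5.0, 10.0, 31.0, 100.0, 316.0),
        (0.63, 0.7, 0.82, 1.09, 1.4, 1.61),
    )
)


def _figure_definitions() -> dict[str, ExperimentConfig]:
    snr_grid = tuple({"input.snr": s} for s in (0.0, 0.15, 0.3, 0.45, 0.6, 0.75, 0.9))
    tau_grid = tuple({"neuron.tau_mem": v} for v in (1.0, 3.2, 10.0, 31.6, 100.0))
    return {
        "fig3": ExperimentConfig(
            input=InputParams(kind="ou", tau_stim=3.0, sigma_eta=0.45, snr=0.8),
            neuron=NeuronParams(model="TB", tau_mem=5.0, v_th=0.6),
        ),
        "fig4a": ExperimentConfig(
            # sigma_eta and V_th are calibrated via the Rice crossing formula
            # to the 8.3 Hz operating point of this study
            input=InputParams(kind="ou", tau_stim=10.0, sigma_eta=1.0, snr=0.0),
            neuron=NeuronParams(model="TB", tau_mem=20.0, v_th=1.0),
            sweep=snr_grid,
        ),
        "fig4bc": ExperimentConfig(
            input=InputParams(kind="ou", tau_stim=10.0, sigma_eta=1.0, snr=0.6),
            neuron=NeuronParams(model="TB", tau_mem=10.0, v_th=1.0),
            sweep=tau_grid,
        ),
        "fig5a": ExperimentConfig(
            input=InputParams(kind="ou", tau_stim=10.0, sigma_eta=1.0, snr=0.6),
            neuron=NeuronParams(model="LIF", tau_mem=10.0, v_th=1.01, v_reset=-1.01),
            sweep=_FIG5A_PAIRS,
            estimation=EstimationSettings(
                estimators=("correlation", "psth_poisson", "isi")
            ),
        ),
        "fig5b": ExperimentConfig(
            input=InputParams(kind="ou", tau_stim=10.0, sigma_eta=1.0, snr=0.6),
            neuron=NeuronParams(model="TB", tau_mem=10.0, v_th=2.41),
            sweep=_FIG5B_PAIRS,
            estimation=EstimationSettings(
                estimators=("correlation", "psth_poisson", "isi")
            ),
        ),
        "fig6a": ExperimentConfig(
            input=InputParams(kind="ou", tau_stim=10.0, sigma_eta=1.0, snr=0.6),
            neuron=NeuronParams(model="TB", tau_mem=10.0, v_th=1.0),
            sweep=tau_grid,
            estimation=EstimationSettings(estimators=("correlation", "direct")),
        ),
        "fig6e": ExperimentConfig(
            input=InputParams(kind="ou", tau_stim=10.0, sigma_eta=1.0, snr=0.6),
            neuron=NeuronParams(model="LIF", tau_mem=10.0, v_th=1.0, v_reset=-1.0),
            sweep=tuple(_TAU_MEM_GRID),
            estimation=EstimationSettings(estimators=("correlation", "direct")),
        ),
        "fig6f": ExperimentConfig(
            input=InputParams(kind="ou", tau_stim=20.0, sigma_eta=1.0, snr=0.6),
            neuron=NeuronParams(
                model="aLIF", tau_mem=10.0, v_th=0.7, v_reset=-1.0,
                alpha=-2.0, beta=4.0, tau_w=5.0,
            ),
            sweep=tuple({"neuron.tau_mem": v} for v in (3.2, 10.0, 31.6, 100.0)),
            estimation=EstimationSettings(estimators=("correlation", "direct")),
        ),
        "fig6f_inset": ExperimentConfig(
            input=InputParams(kind="ou", tau_stim=20.0, sigma_eta=1.0, snr=0.6),
            neuron=NeuronParams(
                model="aLIF", tau_mem=10.0, v_th=0.82, v_reset=-1.0,
                alpha=-2.0, beta=4.0, tau_w=10.0,
            ),
            sweep=_FIG6F_INSET_PAIRS,
            estimation=EstimationSettings(estimators=("correlation", "direct")),
        ),
        "fig6g": ExperimentConfig(
            input=InputParams(kind="ou", tau_stim=10.0, sigma_eta=1.0, snr=0.5),
            neuron=NeuronParams(
                model="EIF", tau_mem=10.0, v_th=1.25, v_reset=-1.25, delta_t=0.5
            ),
            sweep=tuple({"neuron.tau_mem": v} for v in (3.2, 10.0, 31.6, 100.0)),
            estimation=EstimationSettings(estimators=("correlation", "direct")),
        ),
    }


FIGURE_IDS = tuple(sorted(_figure_definitions()))

_SCALES = {
    # (n_repeats, repeat_duration_s, n_varying, varying_duration_s)
    "full": (1000, 40.0, 25, 400.0),
    "reduced": (96, 16.0, 10, 60.0),
    "smoke": (8, 4.0, 2, 8.0),
}


def figure_config(
    figure_id: str, scale: str = "reduced", master_seed: int = 0
) -> ExperimentConfig:
    """Pre-baked config for one reference study at the requested scale."""
    defs = _figure_definitions()
    if figure_id not in defs:
        raise ValueError(
            f"unknown figure id {figure_id!r}; valid ids: {', '.join(sorted(defs))}"
        )
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}; valid: {', '.join(_SCALES)}")
    cfg = defs[figure_id]
    n_rep, t_rep, n_var, t_var = _SCALES[scale]
    est = replace(
        cfg.estimation,
        n_repeats=n_rep,
        repeat_duration_s=t_rep,
        n_varying=n_var,
        varying_duration_s=t_var,
    )
    return replace(cfg, estimation=est, master_seed=master_seed)


def reproduce(
    figure_id: str,
    scale: str = "reduced",
    master_seed: int = 0,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run a pre-baked study; optionally write the tidy table (and a plot).

    The plot is drawn only when matplotlib is importable and ``out_dir`` is
    given; the CSV table is always written in that case.
    """
    cfg = figure_config(figure_id, scale=scale, master_seed=master_seed)
    table = run_experiment(cfg)
    table.insert(0, "figure", figure_id)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        csv_path = out_dir / f"{figure_id}_{scale}.csv"
        table.to_csv(csv_path, index=False)
        log.info("wrote %s", csv_path)
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 3.5))
            for name, grp in table.groupby("estimator"):
                ax.plot(grp["point"], grp["rate_bits_per_s"], "o-", label=name)
            ax.set_xlabel("sweep point")
            ax.set_ylabel("information rate (bits/s)")
            ax.set_title(f"{figure_id} ({scale})")
            ax.legend(fontsize=8)
            fig.tight_layout()
            fig.savefig(out_dir / f"{figure_id}_{scale}.png", dpi=120)
            plt.close(fig)
        except ImportError:
            pass
    return table
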