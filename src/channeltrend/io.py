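"""On-disk formats, pipeline configuration, and the end-to-end pipeline.

Spike trains travel in two interchangeable formats:

* a delimited spike-time text format: ``#`` header lines of ``key: value``
  metadata (``factor``, ``bin_width``, ``duration`` required), then one
  line per trial of comma-separated spike times in ms (empty line = silent
  trial);
* a binned binary matrix in HDF5 (dataset ``spikes``, metadata as attrs).

The text format doubles as the import path for externally simulated spike
trains (e.g. full morphological NEURON models), so published biophysical
models can be plugged into the statistical half of the pipeline unchanged.

``run_pipeline`` glues all stages: stimulus generation -> conductance-scan
simulation (or import) -> joint trend-filtered fitting with lambda*
selection per channel -> sum-of-slopes screen, writing every artifact plus
a resolved-config snapshot and a machine-readable summary, deterministic
for fixed seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from ._exceptions import FormatError, InvalidInputError
from .basis import make_cosine_basis
from .model import ConductanceTrendGLM
from .neuron import (DEFAULT_FACTORS, NeuronModel, ScalingExperiment, SpikeTrainSet,
                     default_neuron_model, run_scaling_experiment)
from .screen import screen_channels
from .stimulus import StimulusEnsemble, generate_stimulus_ensemble
from .trend import DEFAULT_ZETA

__all__ = [
    "PipelineConfig", "save_stimulus", "load_stimulus", "save_spike_trains_text",
    "load_spike_trains_text", "save_spike_trains_hdf5", "load_spike_trains_hdf5",
    "load_spike_trains", "run_pipeline",
]

log = logging.getLogger("channeltrend")


# ---------------------------------------------------------------------------
# stimulus containers

def save_stimulus(ensemble: StimulusEnsemble, path: str | Path, fmt: str = "hdf5") -> None:
    """Write a stimulus ensemble (HDF5, or delimited text fallback)."""
    path = Path(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("waveforms", data=ensemble.waveforms)
            for key in ("dt", "duration", "n_trials", "dc_offset", "noise_sd",
                        "trial_correlation", "parent_seed", "noise_seed", "tau"):
                d.attrs[key] = getattr(ensemble, key)
    elif fmt == "text":
        header = " ".join(
            f"{k}={getattr(ensemble, k)}"
            for k in ("dt", "duration", "n_trials", "dc_offset", "noise_sd",
                      "trial_correlation", "parent_seed", "noise_seed", "tau"))
        np.savetxt(path, ensemble.waveforms.T, delimiter="\t", header=header)
    else:
        raise FormatError(f"unknown stimulus format {fmt!r}")


def load_stimulus(path: str | Path) -> StimulusEnsemble:
    path = Path(path)
    with h5py.File(path, "r") as f:
        d = f["waveforms"]
        attrs = dict(d.attrs)
        return StimulusEnsemble(
            dt=float(attrs["dt"]), duration=float(attrs["duration"]),
            n_trials=int(attrs["n_trials"]), dc_offset=float(attrs["dc_offset"]),
            noise_sd=float(attrs["noise_sd"]),
            trial_correlation=float(attrs["trial_correlation"]),
            parent_seed=int(attrs["parent_seed"]), noise_seed=int(attrs["noise_seed"]),
            tau=float(attrs["tau"]), waveforms=np.asarray(d),
        )


# ---------------------------------------------------------------------------
# spike-train containers

def save_spike_trains_text(sts: SpikeTrainSet, path: str | Path) -> None:
    """Write one condition as the delimited spike-time format."""
    path = Path(path)
    w = sts.bin_width
    with open(path, "w") as f:
        f.write(f"# factor: {sts.factor}\n")
        f.write(f"# channel: {sts.channel}\n")
        f.write(f"# bin_width: {w}\n")
        f.write(f"# duration: {sts.n_bins * w}\n")
        for row in sts.spikes:
            # bin centers as nominal spike times
            times = (np.flatnonzero(row) + 0.5) * w
            f.write(",".join(f"{t:g}" for t in times) + "\n")


def load_spike_trains_text(path: str | Path) -> SpikeTrainSet:
    """Parse a delimited spike-time file into a binned binary matrix."""
    path = Path(path)
    meta: dict[str, str] = {}
    trials: list[np.ndarray] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        if not line:
            trials.append(np.array([]))
            continue
        try:
            trials.append(np.array([float(tok) for tok in line.split(",") if tok.strip()]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable spike time ({exc})") from exc
    if "factor" not in meta:
        raise FormatError(f"{path}: missing required '# factor:' metadata header")
    if "bin_width" not in meta or "duration" not in meta:
        raise FormatError(f"{path}: missing '# bin_width:'/'# duration:' metadata")
    bin_width = float(meta["bin_width"])
    duration = float(meta["duration"])
    n_bins = int(round(duration / bin_width))
    spikes = np.zeros((len(trials), n_bins), dtype=np.int8)
    for i, times in enumerate(trials):
        if times.size and (times.min() < 0 or times.max() >= duration):
            raise FormatError(
                f"{path}: trial {i}: spike time outside [0, {duration}) ms")
        spikes[i, (times // bin_width).astype(int) if times.size else []] = 1
    channel = meta.get("channel")
    return SpikeTrainSet(spikes, bin_width, None if channel in (None, "None") else channel,
                         float(meta["factor"]), dict(meta))


def save_spike_trains_hdf5(sets: dict[float, SpikeTrainSet], path: str | Path) -> None:
    with h5py.File(Path(path), "w") as f:
        for factor, sts in sets.items():
            d = f.create_dataset(f"factor_{factor:g}", data=sts.spikes)
            d.attrs["factor"] = factor
            d.attrs["bin_width"] = sts.bin_width
            if sts.channel:
                d.attrs["channel"] = sts.channel


def load_spike_trains_hdf5(path: str | Path) -> dict[float, SpikeTrainSet]:
    out: dict[float, SpikeTrainSet] = {}
    with h5py.File(Path(path), "r") as f:
        for name in f:
            d = f[name]
            spikes = np.asarray(d)
            if not np.isin(spikes, (0, 1)).all():
                raise FormatError(f"{path}:{name}: non-binary spike matrix")
            out[float(d.attrs["factor"])] = SpikeTrainSet(
                spikes, float(d.attrs["bin_width"]), d.attrs.get("channel"),
                float(d.attrs["factor"]))
    return out


def load_spike_trains(paths, fmt: str = "text",
                      expected_bin_width: float | None = None) -> dict[float, SpikeTrainSet]:
    """Load a per-factor collection of spike-train files.

    ``paths`` is a list of text files (one condition each) or a single HDF5
    file.  Trial counts must agree across conditions, and the bin width is
    checked against the configuration when given.
    """
    if fmt == "hdf5":
        out = load_spike_trains_hdf5(paths if isinstance(paths, (str, Path)) else paths[0])
    elif fmt == "text":
        out = {}
        for p in ([paths] if isinstance(paths, (str, Path)) else paths):
            sts = load_spike_trains_text(p)
            out[sts.factor] = sts
    else:
        raise FormatError(f"unknown spike-train format {fmt!r}")
    counts = {s.n_trials for s in out.values()}
    if len(counts) > 1:
        raise FormatError(f"inconsistent trial counts across conditions: {sorted(counts)}")
    if expected_bin_width is not None:
        for factor, s in out.items():
            if not np.isclose(s.bin_width, expected_bin_width):
                raise FormatError(
                    f"factor {factor}: bin width {s.bin_width} != configured "
                    f"{expected_bin_width}")
    return out


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Fully serializable description of one end-to-end run."""

    # stimulus
    tau: float = 3.0
    dt: float = 0.025
    duration: float = 3000.0
    n_trials: int = 100
    dc_offset: float = 3.5
    noise_sd: float = 2.0
    trial_correlation: float = 0.8
    parent_seed: int = 0
    noise_seed: int = 1
    # simulation / import
    channels: tuple[str, ...] = ("ka",)
    factors: tuple[float, ...] = DEFAULT_FACTORS
    spike_files: dict | None = None  # {channel: [paths]} to import instead of simulating
    # GLM / bases
    bin_width: float = 1.0
    n_bases_stim: int = 10
    n_bases_hist: int = 10
    span_stim: float = 100.0
    span_hist: float = 100.0
    # penalty path / selection
    zeta: float = DEFAULT_ZETA
    fraction_train: float = 0.7
    split_seed: int = 0
    # output
    output_dir: str = "channeltrend_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "channels" in raw:
            raw["channels"] = tuple(raw["channels"])
        if "factors" in raw:
            raw["factors"] = tuple(raw["factors"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig, model: NeuronModel | None = None) -> dict:
    """Execute stimulus -> simulate/import -> fit -> screen, writing artifacts.

    Returns a summary dict (also written as ``summary.json``); every stage
    failure is re-raised with the stage name attached, and all randomness
    flows from the seeds in the config, so two runs with the same config
    produce identical outputs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.save(out_dir / "resolved_config.yaml")
    model = model or default_neuron_model()

    stage = "stimulus"
    try:
        ensemble = generate_stimulus_ensemble(
            tau=config.tau, dt=config.dt, duration=config.duration,
            n_trials=config.n_trials, dc_offset=config.dc_offset,
            noise_sd=config.noise_sd, trial_correlation=config.trial_correlation,
            parent_seed=config.parent_seed, noise_seed=config.noise_seed)
        save_stimulus(ensemble, out_dir / "stimulus.h5")
        binned_stim = ensemble.bin_average(config.bin_width)

        basis_K = make_cosine_basis("stimulus", config.n_bases_stim, config.span_stim,
                                    dt=config.bin_width)
        basis_H = make_cosine_basis("history", config.n_bases_hist, config.span_hist,
                                    dt=config.bin_width)

        paths = {}
        summary: dict = {"channels": {}, "config": config.to_dict()}
        for channel in config.channels:
            stage = f"simulate[{channel}]"
            if config.spike_files:
                spike_trains = load_spike_trains(config.spike_files[channel],
                                                 expected_bin_width=config.bin_width)
            else:
                experiment = ScalingExperiment(channel, ensemble, tuple(config.factors))
                spike_trains = run_scaling_experiment(model, experiment,
                                                      bin_width=config.bin_width)
                save_spike_trains_hdf5(spike_trains, out_dir / f"spikes_{channel}.h5")

            stage = f"fit[{channel}]"
            glm = ConductanceTrendGLM(spike_trains, binned_stim, basis_K=basis_K,
                                      basis_H=basis_H, channel=channel)
            res = glm.fit(fraction_train=config.fraction_train,
                          split_seed=config.split_seed, zeta=config.zeta)
            paths[channel] = res.path
            np.save(out_dir / f"coeffs_{channel}.npy", res.coeffs)
            summary["channels"][channel] = {
                "factors_fit": [float(g) for g in glm.grid.factors],
                "mean_rate_hz": {
                    f"{f:g}": s.mean_rate_hz for f, s in spike_trains.items()},
                "lambda_max": res.lambda_max,
                "lambda_star": res.lambda_star,
                "val_loglik": [float(v) for v in res.path.val_loglik],
                "converged": [bool(f.converged) for f in res.path.fits],
            }
            grid = glm.grid

        stage = "screen"
        table = screen_channels(paths, grid, basis_K=basis_K, basis_H=basis_H)
        table.to_csv(out_dir / "ss_screen.csv", index=False)
        summary["screen_rows"] = len(table)
        with open(out_dir / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
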