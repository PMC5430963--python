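"""Configuration loading, output serialization and run manifests.

Configs are JSON whose keys mirror the model parameter symbols (``T_U``,
``theta_v``, ``lambda_U``, ...). Omitted fields fall back to the published
defaults for the selected model; unknown keys are rejected with a
field-path diagnostic. Times in output tables are written with fixed
4-decimal formatting so that identical (config, seed) pairs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lif import LifParams, LifResult, SlnRuleParams, UpDownConfig, latency_stats
from .sif import SifNeuronParams, SifPlasticityParams, SimResult, VolleyConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "write_outputs"]

log = logging.getLogger("sln")

_SECTIONS = {
    "sif": {"neuron": SifNeuronParams, "input": VolleyConfig,
            "plasticity": SifPlasticityParams},
    "lif": {"neuron": LifParams, "input": UpDownConfig,
            "plasticity": SlnRuleParams},
}


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


@dataclass
class RunConfig:
    """Validated model + input + plasticity configuration for one run."""

    model: str = "sif"
    neuron: object = None
    input: object = None
    plasticity: object = None
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.model not in _SECTIONS:
            raise ConfigError(f"model: must be 'sif' or 'lif', got "
                              f"{self.model!r}")
        for name, cls in _SECTIONS[self.model].items():
            if getattr(self, name) is None:
                setattr(self, name, cls())

    def to_dict(self) -> dict:
        out = {"model": self.model, "seed": self.seed,
               "out_dir": self.out_dir, "log_level": self.log_level}
        for name in ("neuron", "input", "plasticity"):
            out[name] = dataclasses.asdict(getattr(self, name))
        return out


def _build_section(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"{path}.{key}: unknown key (valid: "
                              f"{sorted(fields)})")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        obj = cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    for key in kwargs:
        default = fields[key].default
        if default is not dataclasses.MISSING and kwargs[key] != default:
            log.info("config override %s.%s = %r (default %r)", path, key,
                     kwargs[key], default)
    return obj


def load_config(path: str | Path, model: str | None = None) -> RunConfig:
    """Read and validate a JSON run configuration.

    An empty file yields the full default configuration (Table defaults of
    the selected model). ``model`` overrides/provides the model key.
    """
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    if not isinstance(data, dict):
        raise ConfigError("top level must be a JSON object")
    model = model or data.pop("model", "sif")
    if model not in _SECTIONS:
        raise ConfigError(f"model: must be 'sif' or 'lif', got {model!r}")
    known_top = {"neuron", "input", "plasticity", "seed", "out_dir",
                 "log_level"}
    extra = set(data) - known_top
    if extra:
        raise ConfigError(f"{sorted(extra)[0]}: unknown key (valid: "
                          f"{sorted(known_top | {'model'})})")
    sections = {name: _build_section(cls, data.get(name, {}), name)
                for name, cls in _SECTIONS[model].items()}
    return RunConfig(model=model, seed=int(data.get("seed", 0)),
                     out_dir=str(data.get("out_dir", ".")),
                     log_level=str(data.get("log_level", "INFO")),
                     **sections)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2,
                                     sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# outputs


def _fmt_time(t: float) -> str:
    return f"{t:.4f}"


def _write(path: Path, text: str, manifest: dict) -> None:
    path.write_text(text)
    manifest[path.name] = hashlib.sha256(text.encode()).hexdigest()


def _df_text(df: pd.DataFrame, sep: str = ",") -> str:
    return df.to_csv(index=False, sep=sep, float_format="%.4f")


def write_outputs(result: SimResult | LifResult, out_dir: str | Path,
                  config: RunConfig | None = None,
                  input_cfg=None) -> dict:
    """Write the run's tables plus ``meta.json`` and a checksum manifest.

    Volley-model results produce ``trajectory.csv`` and ``weights.csv``;
    leaky-model results produce ``spikes_pre.tsv``, ``spikes_post.tsv``,
    ``weights.csv``, ``traces.csv`` and ``latency.json``. Returns the
    manifest mapping file names to SHA-256 digests (also written to
    ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    if isinstance(result, SimResult):
        traj = pd.DataFrame({"update_index": result.update_index,
                             "volley_index": result.volley_index,
                             "total_input_weight": result.total_weight,
                             "n_strong": result.n_strong})
        _write(out / "trajectory.csv", _df_text(traj), manifest)
        last = int(result.update_index[-1]) if len(result.update_index) else 0
        weights = pd.DataFrame({
            "update_index": np.full(len(result.final_weights), last),
            "synapse_id": np.arange(len(result.final_weights)),
            "weight": result.final_weights})
        _write(out / "weights.csv", _df_text(weights), manifest)
    elif isinstance(result, LifResult):
        pre = pd.DataFrame({"neuron_id": result.pre_ids,
                            "time_ms": result.pre_times})
        _write(out / "spikes_pre.tsv", _df_text(pre, sep="\t"), manifest)
        post = pd.DataFrame({"time_ms": result.post_times,
                             "is_dsp": result.post_is_dsp.astype(int)})
        _write(out / "spikes_post.tsv", _df_text(post, sep="\t"), manifest)
        wev = pd.DataFrame({"time_ms": result.event_times,
                            "synapse_id": result.event_synapses,
                            "weight": result.event_new})
        _write(out / "weights.csv", _df_text(wev), manifest)
        n_samp, d = result.trace_samples.shape
        tr = pd.DataFrame(result.trace_samples,
                          columns=[f"syn_{j}" for j in range(d)])
        tr.insert(0, "time_ms", result.trace_sample_times)
        _write(out / "traces.csv", _df_text(tr), manifest)
        if input_cfg is not None:
            stats = latency_stats(result.post_times, input_cfg,
                                  result.duration)
            payload = {"r_hat": stats.r_hat,
                       "spikes_per_up": stats.spikes_per_up,
                       "rate_hz": stats.rate,
                       "n_phases": stats.n_phases}
            _write(out / "latency.json",
                   json.dumps(payload, indent=2, sort_keys=True) + "\n",
                   manifest)
    else:
        raise TypeError(f"unsupported result type {type(result).__name__}")

    meta = {"package_version": __version__}
    if config is not None:
        meta["config"] = config.to_dict()
        meta["seed"] = config.seed
    _write(out / "meta.json", json.dumps(meta, indent=2, sort_keys=True) + "\n",
           manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest
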