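"""Run configuration: a single YAML/JSON file mapping onto the model types.

Layout::

    model:   {a1: 0.8, a2: 0.85, b1: 0.2, b2: 1.0, k1: 1.0, k2: 1.0,
              theta: 0.5, n: 4}
    noise:   {D: 0.02, seed: 1}
    <command blocks, passed through to the CLI subcommands>

``a1`` and ``a2`` must be given explicitly; the remaining kinetic
constants default to the standard parameter set (k1 = k2 = 1, theta = 0.5,
n = 4, b1 = 0.2, b2 = 1).  Unknown keys are rejected so that typos do not
silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .model import ModelParams
from .stochastic import NoiseSpec

__all__ = ["RunConfig", "ConfigError", "load_config"]

SCHEMA_VERSION = 1

_KNOWN_BLOCKS = {
    "model", "noise", "schema_version",
    "fixed_points", "phase_diagram", "bifurcation", "critical_hill",
    "simulate", "occupancy", "landscape", "mfpt", "mfpt_mc",
    "noise_threshold", "reproduce",
}


class ConfigError(ValueError):
    """The configuration file violates the schema."""


@dataclass
class RunConfig:
    params: ModelParams
    noise: NoiseSpec | None = None
    options: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def provenance(self) -> dict:
        """Everything needed to re-run this configuration bit-identically."""
        out = {"schema_version": self.schema_version,
               "model": self.params.to_dict()}
        if self.noise is not None:
            out["noise"] = {"D": self.noise.D, "seed": self.noise.seed}
        out.update(self.options)
        return out


def _build_params(block: dict) -> ModelParams:
    known = {f.name for f in fields(ModelParams)}
    bad = set(block) - known
    if bad:
        raise ConfigError(f"unknown model parameter keys: {sorted(bad)}")
    missing = {"a1", "a2"} - set(block)
    if missing:
        raise ConfigError(
            f"model parameters {sorted(missing)} must be given explicitly")
    try:
        return ModelParams(**{k: float(v) for k, v in block.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid model parameters: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML (or JSON) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    bad = set(raw) - _KNOWN_BLOCKS
    if bad:
        raise ConfigError(f"unknown config blocks: {sorted(bad)}")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    params = _build_params(raw.get("model", {}) or {})
    noise = None
    if "noise" in raw and raw["noise"] is not None:
        nb = dict(raw["noise"])
        bad = set(nb) - {"D", "seed"}
        if bad:
            raise ConfigError(f"unknown noise keys: {sorted(bad)}")
        if "D" not in nb:
            raise ConfigError("noise block requires D")
        try:
            noise = NoiseSpec(D=float(nb["D"]), seed=int(nb.get("seed", 0)))
        except ValueError as exc:
            raise ConfigError(f"invalid noise block: {exc}") from exc
    options = {k: v for k, v in raw.items()
               if k not in ("model", "noise", "schema_version")}
    return RunConfig(params, noise, options, version)
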