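"""Configuration, presets, and run manifests.

Run configurations are schema-validated (unknown keys rejected) and
normalised to SI units on load: the file format accepts milliseconds for
transient decay times, inter-pulse intervals and lags — matching how these
quantities are usually quoted — while the library works in seconds
throughout.  A run manifest (JSON) captures the full configuration, seed
and a configuration hash, enough to reproduce any run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .scheme import KineticScheme, RateParams, build_scheme

__all__ = ["PresetSpec", "PulseSpec", "ProtocolSpec", "RunConfig",
           "load_preset", "preset_names", "load_config", "run_manifest",
           "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PresetSpec(_Strict):
    """Named kinetic parameter set (rates in s^-1)."""

    name: str
    n_states: int = Field(ge=3, le=6)
    alpha: float = Field(gt=0)
    rho: float = Field(gt=0)
    beta: Optional[float] = Field(default=None, gt=0)
    lambda1: Optional[float] = Field(default=None, ge=0)
    lambda2: Optional[float] = Field(default=None, ge=0)
    n_total: int = Field(default=10_000, gt=0)

    @model_validator(mode="after")
    def _check_rates(self) -> "PresetSpec":
        if self.beta is None and self.lambda1 is None:
            raise ValueError("preset needs either beta or lambda coefficients")
        return self

    def rate_params(self) -> RateParams:
        if self.beta is not None:
            return RateParams.from_beta(self.alpha, self.beta, self.rho)
        lam2 = self.lambda2 if self.lambda2 is not None else self.lambda1
        return RateParams(self.alpha, self.lambda1, lam2, self.rho)

    def scheme(self) -> KineticScheme:
        return build_scheme(self.n_states, self.rate_params())


def preset_names() -> list[str]:
    root = resources.files("vesikin") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> PresetSpec:
    """Load one of the shipped presets (cat4, frog4, frog5, frog6)."""
    root = resources.files("vesikin") / "presets"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError as exc:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}") from exc
    return PresetSpec(**yaml.safe_load(text))


class PulseSpec(_Strict):
    """One pulse in configuration units (times in ms)."""

    t_s_ms: float
    I_e: float = Field(ge=0)
    tau_e_ms: float = Field(gt=0)


class ProtocolSpec(_Strict):
    """Stimulation protocol: a named template or an explicit pulse list.

    Templates: "spontaneous" (no pulses), "impulse_series" (n_stimuli at a
    recovery interval), "mallart_martin" (3 conditioning pulses 30 ms apart
    plus a test pulse 250 ms later), "chelator" (same, with a briefer
    tau_e on the third conditioning pulse), "betz_lag_sweep" (conditioning
    train plus a test pulse at each of a list of lags).
    """

    template: Literal["spontaneous", "impulse_series", "mallart_martin",
                      "chelator", "betz_lag_sweep", "custom"] = "custom"
    pulses: Optional[list[PulseSpec]] = None
    I_e: Optional[float] = Field(default=None, ge=0)
    tau_e_ms: Optional[float] = Field(default=None, gt=0)
    n_stimuli: int = 250
    recovery_s: float = 5.0
    n_cond: int = 3
    ipi_ms: float = 30.0
    test_lag_ms: float = 250.0
    lags_ms: Optional[list[float]] = None
    chelator_tau_e_ms: float = 0.3
    duration_s: float = 300.0

    @model_validator(mode="after")
    def _check(self) -> "ProtocolSpec":
        if self.template == "custom" and self.pulses is None:
            raise ValueError("custom protocol requires an explicit pulse list")
        return self


class RunConfig(_Strict):
    """Complete description of one reproducible run."""

    preset: Optional[str] = None
    params: Optional[PresetSpec] = None
    protocol: ProtocolSpec = ProtocolSpec(template="spontaneous")
    n_trials: int = Field(default=100, gt=0)
    seed: int
    equilibration: Literal["fast", "cold"] = "fast"
    method: Literal["exact", "naive"] = "exact"
    output_dir: str = "."

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if (self.preset is None) == (self.params is None):
            raise ValueError("exactly one of preset/params must be given")
        return self

    def preset_spec(self) -> PresetSpec:
        return load_preset(self.preset) if self.preset else self.params

    def scheme(self) -> KineticScheme:
        return self.preset_spec().scheme()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    A missing seed or an unknown key is a validation error: every run must
    be reproducible from its configuration alone.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_manifest(config: RunConfig, results: dict, outputs: list[str] | None = None,
                 path: str | Path | None = None) -> dict:
    """Assemble (and optionally write) the JSON run manifest."""
    import vesikin
    manifest = {
        "package": "vesikin",
        "version": vesikin.__version__,
        "config": config.model_dump(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "results": results,
        "outputs": outputs or [],
    }
    if path is not None:
        Path(path).write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
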