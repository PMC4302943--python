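"""Run configuration: nested, validated sections for every pipeline stage.

Config files are JSON; keys may be nested objects or flat dotted keys
(``"synth.f0": 100``), which diff cleanly in tests.  Unknown keys are
rejected by name, absent keys fall back to defaults, and the fully
resolved config is embedded in every output manifest for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator


class FilterSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(default=0.1, ge=0)
    beta: float = Field(default=1.0, ge=0)
    dt: float = Field(default=0.001, gt=0)
    n_bins: int = Field(default=100, ge=8)
    gain: float = Field(default=50.0, gt=0)


class MappingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    # boundary frequencies default to the fit through the vowel fixture
    f1_lo: float | None = None
    f1_hi: float | None = None
    f2_lo: float | None = None
    f2_hi: float | None = None
    transform: str = "cartesian"

    @model_validator(mode="after")
    def _check_transform(self):
        if self.transform not in ("cartesian", "polar"):
            raise ValueError(f"mapping.transform must be cartesian|polar, got {self.transform!r}")
        return self


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fs_audio: int = Field(default=16000, gt=0)
    f0: float = Field(default=120.0, gt=0)
    b1: float = Field(default=80.0, gt=0)
    b2: float = Field(default=90.0, gt=0)
    f3_hz: float = Field(default=2900.0, gt=0)
    b3: float = Field(default=150.0, gt=0)
    use_f3: bool = True
    amplitude: float = Field(default=0.9, gt=0, le=1)


class SessionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_vowel: int = Field(default=5, ge=1)
    trial_s: float = Field(default=5.0, gt=0)
    break_s: float = Field(default=2.0, ge=0)
    control_hz: int = Field(default=1000, gt=0)
    initial_rest_s: float = Field(default=0.25, ge=0)


class SimulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    profile: str = "healthy"
    reach_time: float = Field(default=1.0, ge=0)
    sdn_coeff: float | None = None  # None -> profile default
    cocontraction: float | None = None
    tremor_amp: float = Field(default=0.0, ge=0)
    tremor_hz: float = Field(default=5.0, ge=0)
    n_listeners: int = Field(default=4, ge=1)
    listener_noise_hz: float = Field(default=50.0, ge=0)

    @model_validator(mode="after")
    def _check_profile(self):
        if self.profile not in ("healthy", "cp"):
            raise ValueError(f"simulation.profile must be healthy|cp, got {self.profile!r}")
        return self


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    filter: FilterSection = FilterSection()
    mapping: MappingSection = MappingSection()
    synth: SynthSection = SynthSection()
    session: SessionSection = SessionSection()
    simulation: SimulationSection = SimulationSection()
    seed: int = 0
    outdir: str | None = None


def _undot(flat: dict) -> dict:
    """Expand dotted keys ("synth.f0") into nested dicts."""
    nested: dict = {}
    for key, value in flat.items():
        parts = key.split(".")
        node = nested
        for p in parts[:-1]:
            node = node.setdefault(p, {})
            if not isinstance(node, dict):
                raise ValueError(f"config key {key!r} conflicts with a scalar section")
        if isinstance(value, dict):
            node.setdefault(parts[-1], {}).update(value)
        else:
            node[parts[-1]] = value
    return nested


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a config file (or defaults) with optional dotted-key overrides.

    An empty or absent file yields all defaults; unknown keys raise an
    error naming the key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8").strip()
        if text:
            data = json.loads(text)
            if not isinstance(data, dict):
                raise ValueError(f"{path}: config must be a JSON object")
    if overrides:
        merged = _undot({**data})
        for section, vals in _undot(overrides).items():
            if isinstance(vals, dict):
                merged.setdefault(section, {})
                merged[section].update(vals)
            else:
                merged[section] = vals
        data = merged
    else:
        data = _undot(data)
    return RunConfig.model_validate(data)
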