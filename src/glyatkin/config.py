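"""Run configuration: one validated object covering assay constants,
fitting controls and simulation-design overrides, loadable from YAML.

Unknown keys are rejected by name rather than silently ignored, so a typo
in a config file fails loudly instead of reverting to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from os import PathLike

import yaml

from .assay_processing import AssayConstants
from .exceptions import ConfigError
from .kinetic_model import DEFAULT_MOLAR_MASS

__all__ = ["FittingControls", "RunConfig"]


@dataclass(frozen=True)
class FittingControls:
    n_starts: int = 5
    h_min: float = 0.5
    h_max: float = 6.0

    def __post_init__(self) -> None:
        if self.n_starts < 0:
            raise ConfigError("n_starts must be >= 0")
        if not (0 < self.h_min < self.h_max):
            raise ConfigError("need 0 < h_min < h_max")


@dataclass(frozen=True)
class RunConfig:
    assay: AssayConstants = field(default_factory=AssayConstants)
    fitting: FittingControls = field(default_factory=FittingControls)
    simulation: dict = field(default_factory=dict)  # SimulationDesign overrides
    molar_mass: float = DEFAULT_MOLAR_MASS
    seed: int = 0
    verbosity: int = 1
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ConfigError("molar_mass must be positive")
        from .synthetic_data import SimulationDesign
        allowed = {f.name for f in dataclasses.fields(SimulationDesign)}
        unknown = set(self.simulation) - allowed
        if unknown:
            raise ConfigError(
                f"unknown simulation keys: {sorted(unknown)}"
            )

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root in {path} must be a mapping")
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "assay" in kwargs:
            kwargs["assay"] = _build(AssayConstants, kwargs["assay"], "assay")
        if "fitting" in kwargs:
            kwargs["fitting"] = _build(FittingControls, kwargs["fitting"],
                                       "fitting")
        return cls(**kwargs)

    def config_hash(self) -> str:
        import hashlib
        import json
        payload = {
            "assay": dataclasses.asdict(self.assay),
            "fitting": dataclasses.asdict(self.fitting),
            "simulation": self.simulation,
            "molar_mass": self.molar_mass,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, mapping, section: str):
    if not isinstance(mapping, dict):
        raise ConfigError(f"config section {section!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown keys in section {section!r}: {sorted(unknown)}"
        )
    return cls(**mapping)
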