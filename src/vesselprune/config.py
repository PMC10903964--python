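"""Run configuration: a flat key namespace mirroring the dataclass
fields of the generators, rheology, boundary, perfusion, and pruning
components, loadable from YAML with CLI overrides layered on top."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from .generators import ForkingSpec, HexSpec, TumourFixtureSpec
from .haemodynamics import BoundaryConditions, PerfusionConfig, RheologyParams

__all__ = ["RunConfig", "load_config", "config_hash"]

STOCHASTIC_GENERATORS = ("hexagonal", "fixture")


@dataclass
class RunConfig:
    """Everything needed to drive one end-to-end simulation."""

    generator: str = "forking"
    forking: ForkingSpec = field(default_factory=ForkingSpec)
    hexagonal: HexSpec = field(default_factory=HexSpec)
    fixture: TumourFixtureSpec = field(default_factory=TumourFixtureSpec)
    rheology: RheologyParams = field(default_factory=RheologyParams)
    boundaries: BoundaryConditions = field(default_factory=BoundaryConditions)
    perfusion: PerfusionConfig = field(default_factory=PerfusionConfig)
    pruning_mode: str = "one_by_one"
    dosages: List[int] = field(default_factory=lambda: list(range(25, 226, 25)))
    output_dir: str = "."
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.generator not in ("forking", "hexagonal", "fixture"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.generator in STOCHASTIC_GENERATORS and self.seed is None:
            raise ValueError(
                f"generator {self.generator!r} is stochastic: a seed is required")
        if self.pruning_mode not in ("one_by_one", "batch_ties"):
            raise ValueError(f"unknown pruning mode {self.pruning_mode!r}")
        self.rheology.validate()
        self.boundaries.validate()
        self.perfusion.validate()

    def to_dict(self) -> Dict[str, Any]:
        return asdict(self)


_SECTIONS = {
    "forking": ForkingSpec,
    "hexagonal": HexSpec,
    "fixture": TumourFixtureSpec,
    "rheology": RheologyParams,
    "boundaries": BoundaryConditions,
    "perfusion": PerfusionConfig,
}


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[Dict[str, Any]] = None) -> RunConfig:
    """Build a config from an optional YAML file plus overrides.

    The file uses one mapping per component (``forking:``,
    ``rheology:``, ...) plus top-level scalars; overrides use
    dotted keys (``forking.alpha``) or top-level names.
    """
    data: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if "." in key:
            section, name = key.split(".", 1)
            data.setdefault(section, {})[name] = value
        else:
            data[key] = value

    cfg = RunConfig()
    for section, cls in _SECTIONS.items():
        if section in data:
            allowed = {f.name for f in fields(cls)}
            unknown = set(data[section]) - allowed
            if unknown:
                raise ValueError(f"unknown {section} keys {sorted(unknown)}")
            # seed propagates from the top level when a section omits it
            payload = dict(data[section])
            if "seed" in allowed and "seed" not in payload and data.get("seed") is not None:
                payload["seed"] = data["seed"]
            setattr(cfg, section, cls(**payload))
        elif "seed" in {f.name for f in fields(cls)} and data.get("seed") is not None:
            setattr(cfg, section, cls(seed=data["seed"]))
    for name in ("generator", "pruning_mode", "output_dir", "seed"):
        if name in data:
            setattr(cfg, name, data[name])
    if "dosages" in data:
        cfg.dosages = [int(k) for k in data["dosages"]]
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, for provenance."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
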