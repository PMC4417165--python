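"""Run configuration: YAML-backed, echoed into every output directory.

Precedence: built-in defaults < config file < command-line flags.  A fixed
seed makes a simulate+analyze run fully deterministic, including output
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "Thresholds", "Stages"]


@dataclass
class Thresholds:
    hbond_dmax: float = 3.5
    hbond_theta_min: float = 135.0
    breathing_threshold: float = 45.0
    breathing_min_frames: int = 2
    alpha: float = 0.05
    alpha_t: float = 0.01
    cluster_cutoff: float = 1.0
    promiscuity: float = 0.05
    ion_half_thickness: float = 1.7

    def validate(self):
        for f in dataclasses.fields(self):
            if float(getattr(self, f.name)) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")
        return self


@dataclass
class Stages:
    params: bool = True
    pairing: bool = True
    grooves: bool = True
    ions: bool = True
    ensemble: bool = True
    transfer: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "mmdna_out"
    environment: str = "f1"
    watson_base: str = "A"
    crick_base: str = "A"
    n_frames: int = 100
    frame_dt: float = 1.0
    chi: float | None = None
    covariance: object = None  # None = study defaults; list = variances
    breathing_events: list[dict] = field(default_factory=list)
    ion_molarity: float | None = None
    ion_r_max: float = 16.0
    trajectory: str | None = None
    control_trajectory: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: Stages = field(default_factory=Stages)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        thr = Thresholds(**raw.pop("thresholds", {})).validate()
        stages = Stages(**raw.pop("stages", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=thr, stages=stages, **raw)

    def override(self, **kwargs) -> "RunConfig":
        out = dataclasses.replace(self)
        for k, v in kwargs.items():
            if v is not None:
                setattr(out, k, v)
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def echo(self, directory: Path):
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "run_config.yaml").write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True))
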