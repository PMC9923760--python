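"""Pipeline configuration: nested sections, YAML round-trip, provenance hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .disorder import DisorderSpec
from .geometry import LatticeSpec
from .spectra import ApodizationSpec

__all__ = ["RunSpec", "PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunSpec:
    """Problem sizes and stage toggles of one pipeline run."""

    seed: int = 1
    tube_radius: float = 7.3          # nm, tube used for spectroscopy
    tube_length: float = 35.0         # nm (builds slightly longer, truncates)
    donor_fraction: float = 0.7
    n_frames: int = 2500
    n_configs_linear: int = 10
    coherence_time_linear: float = 128.0   # fs
    run_twod: bool = False
    twod_radius: float = 2.6          # nm, reduced tube for the 2D stage
    twod_length: float = 12.0         # nm
    n_configs_twod: int = 2
    coherence_time_twod: float = 192.0     # fs
    twod_sample_dt: float = 8.0            # fs
    twod_max_sites: int = 600
    analysis_bin_width: float = 50.0       # cm^-1


@dataclass
class PipelineConfig:
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    disorder: DisorderSpec = field(default_factory=DisorderSpec)
    apodization: ApodizationSpec = field(default_factory=ApodizationSpec)
    run: RunSpec = field(default_factory=RunSpec)

    def to_dict(self) -> dict:
        def enc(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(map(list, v)) if k in ("dynamic_components",) else
                        (list(v) if isinstance(v, tuple) else v))
                    for k, v in d.items()}

        return {
            "lattice": enc(self.lattice),
            "disorder": enc(self.disorder),
            "apodization": enc(self.apodization),
            "run": enc(self.run),
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return PipelineConfig(
            lattice=self.lattice,
            disorder=dataclasses.replace(self.disorder, seed=seed),
            apodization=self.apodization,
            run=dataclasses.replace(self.run, seed=seed),
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    lattice = LatticeSpec(**_tupled(raw.get("lattice", {}), "radii"))
    disorder = DisorderSpec(**_tupled(raw.get("disorder", {}), "dynamic_components"))
    apod = ApodizationSpec(**raw.get("apodization", {}))
    run = RunSpec(**raw.get("run", {}))
    return PipelineConfig(lattice=lattice, disorder=disorder, apodization=apod, run=run)


def _tupled(section: dict, key: str) -> dict:
    out = dict(section)
    if key in out:
        val = out[key]
        out[key] = tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in val)
    return out


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
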