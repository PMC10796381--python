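"""YAML run configuration with strict key checking and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .occupancy import OccupancyConfig
from .pipeline import PipelineParams
from .simulate import AcquisitionConfig, KineticsConfig, NanorodDesign

__all__ = ["RunConfig", "load_config", "write_resolved_config",
           "write_manifest", "sha256_file"]


@dataclass(frozen=True)
class SampleConfig:
    """Field composition for the simulator."""

    density_per_um2: float = 0.9
    labeling_p: float = 0.9
    bend_sd_rad: float = 0.1
    drift_step_sd_nm: float = 0.0


@dataclass(frozen=True)
class Cy5Config:
    psf_sigma_nm: float = 150.0
    background: float = 100.0
    noise_sd: float = 5.0
    spot_intensity: float = 120.0


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one run; every run writes it back out."""

    design: NanorodDesign = field(default_factory=lambda: NanorodDesign(4))
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    sample: SampleConfig = field(default_factory=SampleConfig)
    cy5: Cy5Config = field(default_factory=Cy5Config)
    analysis: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "design": NanorodDesign,
    "acquisition": AcquisitionConfig,
    "kinetics": KineticsConfig,
    "sample": SampleConfig,
    "cy5": Cy5Config,
    "analysis": PipelineParams,
}


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in '{where}': {', '.join(sorted(unknown))}")
    if cls is PipelineParams and "occupancy" in data:
        data = dict(data)
        data["occupancy"] = _build(OccupancyConfig, data["occupancy"] or {},
                                   f"{where}.occupancy")
    return cls(**data)


def load_config(path_or_dict) -> RunConfig:
    """Load a run config from YAML (or a dict); unknown keys are rejected."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    design = {"n_sites": 4, **(raw.get("design") or {})}
    kwargs = {
        name: _build(cls, design if name == "design" else (raw.get(name) or {}),
                     name)
        for name, cls in _SECTIONS.items()
    }
    kwargs["seed"] = int(raw.get("seed", 0))
    return RunConfig(**kwargs)


def write_resolved_config(config: RunConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir) / "resolved_config.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return out


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, seed: int,
                   files: list[str | Path]) -> Path:
    """Record content hashes of every output so reruns are checkable."""
    out_dir = Path(out_dir)
    manifest = {
        "seed": int(seed),
        "files": {Path(f).name: sha256_file(f) for f in files},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
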