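"""Run configuration: model constants + analysis settings, round-tripped via YAML."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .simulate import SheetModelParams

__all__ = ["AnalysisParams", "RunConfig", "load_config", "config_hash"]


@dataclass
class AnalysisParams:
    n_trials: int = 20
    slice_thickness_nm: float = 60.0
    camera_pixel_nm: float = 160.0
    band_lo_nm: float = 3.0
    band_hi_nm: float = 10.0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if self.slice_thickness_nm <= 0 or self.camera_pixel_nm <= 0:
            raise ValueError("slice thickness and camera pixel must be > 0")
        if not 0 < self.band_lo_nm < self.band_hi_nm:
            raise ValueError("band bounds must satisfy 0 < lo < hi")


@dataclass
class RunConfig:
    model: SheetModelParams = field(default_factory=SheetModelParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"model": asdict(self.model), "analysis": asdict(self.analysis),
                "seed": int(self.seed)}

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            model=SheetModelParams(**d.get("model", {})),
            analysis=AnalysisParams(**d.get("analysis", {})),
            seed=int(d.get("seed", 0)),
        )


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    try:
        return RunConfig.from_dict(data)
    except TypeError as exc:  # unknown field name
        raise ValueError(f"{path}: invalid configuration: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical YAML form, for provenance headers."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
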