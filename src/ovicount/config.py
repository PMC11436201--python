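"""Single-file pipeline configuration with strict round-tripping.

All module knobs live in one YAML mapping so a run is reproducible from
its config + seed alone. Unknown keys are rejected rather than ignored —
a typo in a threshold name must not silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .counting import FilterConfig
from .plate import PlateGrid
from .segment import DetectorConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    grid: PlateGrid = field(default_factory=PlateGrid)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    est_diameter: float = 520.0
    backend: str = "reference"
    welch: bool = True
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "grid": {"n_rows": self.grid.n_rows, "n_cols": self.grid.n_cols},
            "detector": dataclasses.asdict(self.detector),
            "filters": dataclasses.asdict(self.filters),
            "est_diameter": self.est_diameter,
            "backend": self.backend,
            "welch": self.welch,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for section, klass in (("grid", PlateGrid), ("detector", DetectorConfig),
                               ("filters", FilterConfig)):
            if section in data:
                sub = data.pop(section)
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(sub) - known
                if unknown:
                    raise ValueError(f"unknown keys in {section!r}: {sorted(unknown)}")
                kwargs[section] = klass(**sub)
        known_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs, **data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
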