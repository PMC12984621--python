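"""Run-level configuration: every stage threshold in one place.

Defaults are the pipeline's reference settings (demux removal rules
30 %/10/30 %, genotyping depth 10 / GQ 30 / cell AF 35 %, variant filters
3/6 cells and 300 bp, population AF 0.1 %, panel uniformity 80 %, criteria
10 %/1 %, relapse fold-change 10, EC-NGS posterior 1 % with UAO >= 3, LoD
z = 3.08).  The whole structure round-trips through YAML so a run is fully
described by one file plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .clones import CloneConfig
from .demux import DemuxConfig
from .scfilter import FilterConfig
from .selection import CriteriaConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    clones: CloneConfig = field(default_factory=CloneConfig)
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    relapse_fold: float = 10.0
    ecngs_posterior_threshold: float = 0.01
    ecngs_uao_min: int = 3
    lod_z: float = 3.08
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(
            demux=DemuxConfig(**data.get("demux", {})),
            filters=FilterConfig(**data.get("filters", {})),
            clones=CloneConfig(**data.get("clones", {})),
            criteria=CriteriaConfig(**data.get("criteria", {})),
            relapse_fold=data.get("relapse_fold", 10.0),
            ecngs_posterior_threshold=data.get("ecngs_posterior_threshold", 0.01),
            ecngs_uao_min=data.get("ecngs_uao_min", 3),
            lod_z=data.get("lod_z", 3.08),
            seed=data.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
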