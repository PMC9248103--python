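"""Run configuration for the end-to-end pipeline.

Collects every tunable constant — acoustic analysis settings, frailty
criterion cut-offs, simulation settings, statistics options — into one
serializable object with YAML round-trip support, so a run is fully
described by (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acoustics import AcousticConfig
from .frailty import FrailtyThresholds
from .synthdata import CohortConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class StatsSettings:
    stratify_sex: bool = True
    ci_method: str = "wald"  # only Wald intervals are implemented


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    acoustics: AcousticConfig = field(default_factory=AcousticConfig)
    frailty: FrailtyThresholds = field(default_factory=FrailtyThresholds)
    stats: StatsSettings = field(default_factory=StatsSettings)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["effect_ors"] = dict(d["cohort"]["effect_ors"])
        d["cohort"]["sex_interaction"] = {
            k: list(v) for k, v in d["cohort"]["sex_interaction"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = dict(d.get("cohort", {}))
        if "sex_interaction" in cohort:
            cohort["sex_interaction"] = {k: tuple(v) for k, v in cohort["sex_interaction"].items()}
        if "feature_means_robust" in cohort:
            cohort["feature_means_robust"] = dict(cohort["feature_means_robust"])
        return cls(
            seed=int(d.get("seed", 0)),
            cohort=CohortConfig(**cohort),
            acoustics=AcousticConfig(**d.get("acoustics", {})),
            frailty=FrailtyThresholds(**d.get("frailty", {})),
            stats=StatsSettings(**d.get("stats", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
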