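"""Run configuration: one YAML file covering every tunable parameter.

Unknown keys are rejected so a typo cannot silently fall back to a
default; the effective configuration is echoed to the log on every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import TextIO

import yaml

from clonecall.discovery import VoteParams
from clonecall.genotyper import GenotypeParams
from clonecall.gsnv_filter import BulkFilterThresholds, RegionScreenParams
from clonecall.simulator import SimParams

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vote: VoteParams = field(default_factory=VoteParams)
    genotype: GenotypeParams = field(default_factory=GenotypeParams)
    sim: SimParams = field(default_factory=SimParams)
    bulk_filter: BulkFilterThresholds = field(default_factory=BulkFilterThresholds)
    region_screen: RegionScreenParams = field(default_factory=RegionScreenParams)
    seed: int = 0
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, stream: TextIO) -> None:
        yaml.safe_dump(self.to_dict(), stream, sort_keys=True)

    @property
    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def log_effective(self) -> None:
        log.info("effective config (sha256 %s): %s", self.digest, self.to_dict())

    @classmethod
    def load(cls, stream: TextIO) -> "RunConfig":
        raw = yaml.safe_load(stream) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        sections = {
            "vote": VoteParams,
            "genotype": GenotypeParams,
            "sim": SimParams,
            "bulk_filter": BulkFilterThresholds,
            "region_screen": RegionScreenParams,
        }
        kwargs: dict = {}
        for key, value in raw.items():
            if key in sections:
                klass = sections[key]
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                if "clone_sizes" in value:
                    value["clone_sizes"] = tuple(value["clone_sizes"])
                kwargs[key] = klass(**value)
            elif key in ("seed", "verbosity"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)
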