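"""Run configuration: every analysis parameter in one serializable object."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .classify import ClassifierConfig, EpitopeDefinition
from .fingerprint import InteractionCutoffs
from .occupancy import DEFAULT_HIGH_THRESHOLD

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    cutoffs: InteractionCutoffs = field(default_factory=InteractionCutoffs)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    epitope: EpitopeDefinition = field(default_factory=EpitopeDefinition)
    high_occupancy_threshold: float = DEFAULT_HIGH_THRESHOLD
    output_format: str = "tsv"  # or "json"

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["epitope"]["key_partner_res"] = list(self.epitope.key_partner_res)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        cutoffs = InteractionCutoffs(**data.get("cutoffs", {}))
        classifier = ClassifierConfig(**data.get("classifier", {}))
        epi = dict(data.get("epitope", {}))
        if "key_partner_res" in epi:
            epi["key_partner_res"] = tuple(epi["key_partner_res"])
        epitope = EpitopeDefinition(**epi)
        return cls(cutoffs=cutoffs, classifier=classifier, epitope=epitope,
                   high_occupancy_threshold=data.get(
                       "high_occupancy_threshold", DEFAULT_HIGH_THRESHOLD),
                   output_format=data.get("output_format", "tsv"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
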