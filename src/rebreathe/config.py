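"""Run configuration: one JSON-serialisable document for a whole run.

Defaults mirror the study conditions: dead space 0.148 L, second-breath
weight 0.57, FRC/ELV constant 0.82, DV/TV window 0.10-0.25.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .estimator import DeadSpaceConfig, EstimatorConfig

SCHEMA = "rebreathe/1"


@dataclass
class RunConfig:
    """Serializable configuration for CLI runs."""

    units: str = "kpa"
    dead_space_l: float = 0.148
    dead_space_tolerance_l: float = 0.003
    weight: float | str = 0.57
    k_constant: float = 0.82
    dv_tv_low: float = 0.10
    dv_tv_high: float = 0.25
    regularity_cv_limit: float = 0.25
    seed: int | None = None
    simulator: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units not in ("kpa", "mmhg"):
            raise ValueError("units must be 'kpa' or 'mmhg'")
        # delegate numeric validation to the domain configs
        self.dead_space()
        self.estimator()

    def dead_space(self) -> DeadSpaceConfig:
        return DeadSpaceConfig(
            volume=self.dead_space_l,
            volume_tolerance=self.dead_space_tolerance_l,
        )

    def estimator(self) -> EstimatorConfig:
        weight = self.weight if self.weight == "auto" else float(self.weight)
        return EstimatorConfig(
            weight=weight,
            k_constant=self.k_constant,
            dv_tv_low=self.dv_tv_low,
            dv_tv_high=self.dv_tv_high,
            regularity_cv_limit=self.regularity_cv_limit,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"schema": SCHEMA, **dataclasses.asdict(self)}
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        doc.pop("schema", None)
        return cls(**doc)
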