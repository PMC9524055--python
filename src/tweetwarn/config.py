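"""Pipeline configuration: a single YAML file, flags override file values."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .detect import SignalConfig
from .stream import TopicRates

__all__ = ["TopicOverride", "PipelineConfig"]


class TopicOverride(BaseModel):
    """Per-topic detection overrides (alert confidence, downweight strength)."""

    alpha: Optional[float] = None
    downweight_strength: Optional[str] = None


class PipelineConfig(BaseModel):
    """Everything a pipeline run needs; defaults mirror routine operation.

    The geolocation acceptance threshold defaults to 10 and the detection
    baseline to the trailing 7 days; the four study languages are covered.
    """

    topics: list[TopicRates] = Field(
        default_factory=lambda: [
            TopicRates(name="measles", rates={"FR": 10.0, "ES": 10.0}),
            TopicRates(name="cholera", rates={"BR": 10.0, "AR": 10.0}),
        ]
    )
    languages: tuple[str, ...] = ("en", "fr", "pt", "es")
    min_score: float = 10.0
    min_candidate_score: float = Field(default=0.5, ge=0, le=1)
    signal: SignalConfig = Field(default_factory=SignalConfig)
    topic_overrides: dict[str, TopicOverride] = Field(default_factory=dict)
    gazetteer_path: Optional[Path] = None  # None -> bundled toy gazetteer
    common_words_path: Optional[Path] = None
    output_dir: Path = Path("out")
    seed: int = 0

    @field_validator("languages")
    @classmethod
    def _langs(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("at least one language required")
        return tuple(s.lower() for s in v)

    def signal_config_for(self, topic: str) -> SignalConfig:
        ov = self.topic_overrides.get(topic)
        if ov is None:
            return self.signal
        updates = {k: v for k, v in ov.model_dump().items() if v is not None}
        return self.signal.model_copy(update=updates)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = self.model_dump(mode="json")
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
        return path
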