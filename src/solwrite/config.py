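"""Application configuration: session + detection parameters, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .detection import DetectionParams
from .engine import SessionConfig

__all__ = ["AppConfig"]


@dataclass(frozen=True)
class AppConfig:
    """Validated configuration for the whole pipeline.

    Bundles the session parameters (drawing radius, pinch threshold,
    time limit) with the detection parameters (Canny thresholds, Hough
    and merge tolerances), the Hough seed and the display geometry.
    Radius bounds [20, 40] px are enforced on construction.
    """

    session: SessionConfig = field(default_factory=SessionConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    seed: int = 0
    display_width: int = 1280
    display_height: int = 720
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "session": asdict(self.session),
            "detection": asdict(self.detection),
            "seed": self.seed,
            "display_width": self.display_width,
            "display_height": self.display_height,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AppConfig":
        known_session = {f.name for f in fields(SessionConfig)}
        known_detect = {f.name for f in fields(DetectionParams)}
        sess = d.get("session", {})
        det = d.get("detection", {})
        bad = (set(sess) - known_session) | (set(det) - known_detect)
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(
            session=SessionConfig(**sess),
            detection=DetectionParams(**det),
            seed=int(d.get("seed", 0)),
            display_width=int(d.get("display_width", 1280)),
            display_height=int(d.get("display_height", 720)),
            log_level=str(d.get("log_level", "INFO")),
        )

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path) -> "AppConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
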