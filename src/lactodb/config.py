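"""Run configuration: registry source, transcription conventions, seed."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .functions import LUCAS_INTERCEPT, LUCAS_SLOPE, Registry, load_registry

_ENUMS = {
    "agp_slope_sign": ("negative", "printed"),
    "hsa_grouping": ("centered", "printed"),
    "variance_convention": ("population", "sample"),
    "log_level": ("DEBUG", "INFO", "WARNING", "ERROR"),
}


@dataclass
class RunConfig:
    """Resolved settings for one run; round-trips through JSON."""

    registry: str = "builtin"  # "builtin" or a path to a registry JSON
    agp_slope_sign: str = "negative"
    hsa_grouping: str = "centered"
    variance_convention: str = "population"
    lucas_intercept: float = LUCAS_INTERCEPT
    lucas_slope: float = LUCAS_SLOPE
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, allowed in _ENUMS.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {getattr(self, name)!r}")

    def load_registry(self) -> Registry:
        path = None if self.registry == "builtin" else Path(self.registry)
        return load_registry(
            path, agp_slope_sign=self.agp_slope_sign, hsa_grouping=self.hsa_grouping
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
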