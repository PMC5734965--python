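"""Run configuration: match conventions, band thresholds, seed, verbosity.

Serializable to/from YAML so every run can echo the exact convention it
used.  Defaults equal the calibrated convention: sigma 3, end markers on,
the first name of a pair is the stored word, denominator = word letters
(+2 for the marker channels), in-order binding.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .coding import MatchParams, ValidationError
from .risk import Thresholds

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    sigma: float = 3.0
    end_markers: bool = True
    denominator_mode: str = "word"
    word_role: str = "first_name"
    binding_mode: str = "in_order"
    code_series: str = "descending_unit"
    sigma_squared_exponent: bool = False
    high_threshold: float = 66.0
    medium_threshold: float = 33.0
    low_threshold: float = 1.0
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        self.match_params()  # validates enums and sigma
        self.thresholds()

    def match_params(self) -> MatchParams:
        return MatchParams(
            sigma=self.sigma,
            end_markers=self.end_markers,
            denominator_mode=self.denominator_mode,
            word_role=self.word_role,
            binding_mode=self.binding_mode,
            code_series=self.code_series,
            sigma_squared_exponent=self.sigma_squared_exponent,
        )

    def thresholds(self) -> Thresholds:
        return Thresholds(
            high=self.high_threshold,
            medium=self.medium_threshold,
            low=self.low_threshold,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs: object) -> "RunConfig":
        """New config with the non-None entries of kwargs applied."""
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**data)
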