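"""Run configuration shared by the CLI entry points."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .acoustics import AcousticConstants, FocusOptions
from .analysis import StftParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated bundle of the knobs every pipeline stage shares."""

    fs: float = 44100.0
    seed: int = 0
    er_band: tuple[float, float] = (1000.0, 2000.0)
    er_fmax: float = 8000.0
    er_variant: str = "printed"
    transition_threshold: float = 0.35
    transition_hysteresis: float = 0.1
    transition_min_hold: float = 0.1
    constants: AcousticConstants = field(default_factory=AcousticConstants)
    stft: StftParams = field(default_factory=StftParams)
    focus: FocusOptions = field(default_factory=FocusOptions)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        fL, fH = self.er_band
        if not 0 <= fL < fH <= self.er_fmax:
            raise ValueError("need 0 <= fL < fH <= er_fmax")
        if self.er_variant not in ("printed", "power"):
            raise ValueError("er_variant must be 'printed' or 'power'")
        if not 0 < self.transition_threshold < 1:
            raise ValueError("transition_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("constants", AcousticConstants), ("stft", StftParams), ("focus", FocusOptions)):
            if key in raw:
                raw[key] = sub(**raw[key])
        if "er_band" in raw:
            raw["er_band"] = tuple(raw["er_band"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["er_band"] = list(self.er_band)
        return d
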