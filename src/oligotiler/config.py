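"""Design configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Tuple

import yaml

__all__ = ["DesignConfig"]


@dataclass(frozen=True)
class DesignConfig:
    """Full pipeline configuration.

    ``target_len`` (20-30 bp) is the nominal overlap length, so oligos come
    out near twice that; ``overlap_bounds`` is a soft band keeping refined
    overlaps at 20-30 bp (and oligos at 40-60 bp); ``budget`` is the max
    bases the optimizer may shrink per overlap in gapped mode; ``seed``
    drives every stochastic choice (tail generation).
    """

    target_len: int = 25
    mode: str = "gapless"
    var_threshold: float = 0.001
    budget: int = 3
    min_overlap_len: int = 15
    na_molar: float = 0.05
    ct_molar: float = 1e-6
    seed: int = 0
    allow_tail: bool = True
    overlap_bounds: Optional[Tuple[int, int]] = (20, 30)

    def __post_init__(self) -> None:
        if not 20 <= self.target_len <= 30:
            raise ValueError("target_len must be in [20, 30]")
        if self.mode not in ("gapless", "gapped"):
            raise ValueError("mode must be 'gapless' or 'gapped'")
        if self.var_threshold <= 0:
            raise ValueError("var_threshold must be > 0")
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if self.min_overlap_len < 10:
            raise ValueError("min_overlap_len must be >= 10")
        if self.na_molar <= 0 or self.ct_molar <= 0:
            raise ValueError("concentrations must be > 0")
        if self.overlap_bounds is not None:
            lo, hi = self.overlap_bounds
            if not self.min_overlap_len <= lo <= hi:
                raise ValueError("overlap_bounds must satisfy min_overlap_len <= lo <= hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["overlap_bounds"] is not None:
            d["overlap_bounds"] = list(d["overlap_bounds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if d.get("overlap_bounds") is not None:
            d["overlap_bounds"] = tuple(d["overlap_bounds"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "DesignConfig":
        return cls.from_dict(yaml.safe_load(text))
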