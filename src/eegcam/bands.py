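"""Canonical clinical EEG frequency bands."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict


@dataclass(frozen=True)
class BandDef:
    """A contiguous frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"band {self.name!r}: require 0 < f_lo < f_hi")


# Conventional clinical band edges; bands partition 1-30 Hz.
BANDS: Dict[str, BandDef] = {
    "delta": BandDef("delta", 1.0, 4.0),
    "theta": BandDef("theta", 4.0, 8.0),
    "alpha": BandDef("alpha", 8.0, 13.0),
    "beta": BandDef("beta", 13.0, 30.0),
}


def get_band(name: str) -> BandDef:
    try:
        return BANDS[name]
    except KeyError:
        raise ValueError(f"unknown band {name!r}; known: {sorted(BANDS)}") from None
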