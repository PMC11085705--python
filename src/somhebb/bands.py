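"""Frequency band definitions shared by the simulator and the extractor."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")


ALPHA = Band("alpha", 8.0, 13.0)
BETA = Band("beta", 14.0, 30.0)
THETA = Band("theta", 4.0, 7.0)

#: Feature layout order: alpha block, beta block, theta block.
DEFAULT_BANDS: tuple[Band, ...] = (ALPHA, BETA, THETA)
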