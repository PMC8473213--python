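"""Frequency-band definitions used throughout the package.

The six bands cover 1-30 Hz: delta (1-4), theta (4-8), alpha (8-12),
sigma (12-15), low beta (15-20) and high beta (20-30).  Interior edges are
shared between adjacent bands, so band-power integration treats each band as
the half-open interval [low, high); only the top band includes its upper
edge.  Center frequencies drive the oscillatory component of the synthetic
generator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low


CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("sigma", 12.0, 15.0),
    BandDefinition("low_beta", 15.0, 20.0),
    BandDefinition("high_beta", 20.0, 30.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


def get_band(name: str) -> BandDefinition:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ConfigurationError(f"unknown band {name!r}; known: {BAND_NAMES}") from None
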