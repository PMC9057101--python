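"""Canonical EEG frequency-band definitions.

Band power is computed for the five main clinical EEG bands:
delta 1-4 Hz, theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz and gamma
30-80 Hz.  Band intervals are half-open ``[lo, hi)`` so the five
default bands tile 1-80 Hz without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandDefinition", "DEFAULT_BANDS", "BAND_NAMES"]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi})"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)
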