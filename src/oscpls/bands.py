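"""Frequency-band definitions for band-power extraction.

The default bands are theta 2-7 Hz, alpha 9-14 Hz and beta 15-30 Hz. A
variant set defines theta as 4-7 Hz, reflecting the convention that
activity below 4 Hz belongs to the delta range; both sets are selectable
wherever bands enter an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["BandDefinition", "standard_bands", "theta47_bands", "band_set"]


@dataclass(frozen=True)
class BandDefinition:
    """A named closed frequency interval [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )

    def contains(self, freq: float) -> bool:
        return self.f_lo <= freq <= self.f_hi


def standard_bands() -> tuple[BandDefinition, ...]:
    """Theta 2-7, alpha 9-14, beta 15-30 Hz."""
    return (
        BandDefinition("theta", 2.0, 7.0),
        BandDefinition("alpha", 9.0, 14.0),
        BandDefinition("beta", 15.0, 30.0),
    )


def theta47_bands() -> tuple[BandDefinition, ...]:
    """Variant with theta restricted to 4-7 Hz; alpha and beta unchanged."""
    return (
        BandDefinition("theta", 4.0, 7.0),
        BandDefinition("alpha", 9.0, 14.0),
        BandDefinition("beta", 15.0, 30.0),
    )


def band_set(variant: str = "standard") -> tuple[BandDefinition, ...]:
    """Look up a named band set: ``"standard"`` (theta 2-7) or ``"theta-4-7"``."""
    if variant in ("standard", "2-7"):
        return standard_bands()
    if variant in ("theta-4-7", "4-7"):
        return theta47_bands()
    raise ValueError(f"unknown band variant {variant!r}")


def validate_bands(bands: Sequence[BandDefinition]) -> None:
    """Reject overlapping bands within one configuration."""
    ordered = sorted(bands, key=lambda b: b.f_lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.f_lo <= a.f_hi:
            raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise ValueError("band names must be unique")
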