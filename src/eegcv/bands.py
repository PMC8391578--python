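"""Canonical EEG rhythm bands.

The five classical scalp-EEG rhythms, defined so that they partition the
0.5-48 Hz analysis band without gaps or overlaps: delta 0.5-4, theta 4-8,
alpha 8-12, beta 12-25, gamma 25-48 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class Band:
    """A frequency band [low_hz, high_hz) in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if self.name not in BAND_NAMES:
            raise ValueError(f"unknown band name {self.name!r}; expected one of {BAND_NAMES}")
        if not 0.0 < self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: need 0 < low_hz < high_hz, got [{self.low_hz}, {self.high_hz})")

    @property
    def width_hz(self) -> float:
        return self.high_hz - self.low_hz


DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 25.0),
    Band("gamma", 25.0, 48.0),
)

ANALYSIS_BAND = (0.5, 48.0)  # broadband conditioning filter edges, Hz


def check_partition(bands: tuple[Band, ...], low: float = ANALYSIS_BAND[0], high: float = ANALYSIS_BAND[1]) -> None:
    """Raise unless *bands* tile [low, high) contiguously in order."""
    if not bands:
        raise ValueError("no bands given")
    ordered = sorted(bands, key=lambda b: b.low_hz)
    if ordered[0].low_hz != low or ordered[-1].high_hz != high:
        raise ValueError(f"bands span [{ordered[0].low_hz}, {ordered[-1].high_hz}), expected [{low}, {high})")
    for a, b in zip(ordered, ordered[1:]):
        if a.high_hz != b.low_hz:
            raise ValueError(f"gap or overlap between {a.name} and {b.name}")
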