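"""Closed IQ-score intervals.

Every confidence-interval-based comparability rule in this package reduces to
a question about closed intervals on the IQ scale, so the interval primitive
lives in its own module and is shared by the battery and comparability layers.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Interval:
    """A closed interval [lower, upper] in IQ points (bounds real-valued)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"interval lower bound {self.lower} exceeds upper {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def intervals_overlap(a: Interval, b: Interval) -> bool:
    """True iff the two closed intervals share at least one point.

    Touching endpoints count as overlap: [90, 100] and [100, 110] overlap.
    """
    return bool(a.lower <= b.upper and b.lower <= a.upper)


def intersection_length(a: Interval, b: Interval) -> float:
    """Length of the intersection of two closed intervals, 0 if disjoint."""
    return max(0.0, min(a.upper, b.upper) - max(a.lower, b.lower))
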