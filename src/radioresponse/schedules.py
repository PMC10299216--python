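"""Fractionation protocols as time-stamped dose events.

Four named regimens are built in:

* ``SP`` — standard fractionation: 2 Gy on weekdays for 5 weeks (25 x 2 Gy).
* ``DP`` — DAHANCA-style acceleration: 2 Gy, 6 days a week for 4 weeks
  (24 x 2 Gy by default; the fraction count is overridable since the
  regimen is sometimes quoted with an extra fraction).
* ``PP`` — continuous daily: 2 Gy on 25 consecutive days (25 x 2 Gy).
* ``CP`` — CHART: 36 x 1.5 Gy, three fractions per day at 6-h spacing on
  12 consecutive days.

Fractions are placed a fixed lead-in after simulation start (72 h by
default, an untreated growth phase) and thereafter at 24-h day spacing;
the within-day delivery hour is arbitrary but fixed for reproducibility.
Custom schedules load from a two-column CSV (time_h, dose_Gy).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["FractionEvent", "Protocol", "build_protocol", "load_schedule_csv",
           "PROTOCOL_NAMES"]

PROTOCOL_NAMES = ("SP", "DP", "PP", "CP")

DEFAULT_LEAD_IN = 72.0
DEFAULT_DOSE = 2.0
CHART_DOSE = 1.5


@dataclass(frozen=True)
class FractionEvent:
    """A single fraction: delivery time (h since simulation start) and dose (Gy)."""

    time: float
    dose: float

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("fraction time must be >= 0")
        if self.dose <= 0:
            raise ValueError("fraction dose must be > 0")


@dataclass(frozen=True)
class Protocol:
    """An ordered fractionation schedule."""

    name: str
    events: tuple[FractionEvent, ...]
    lead_in: float = DEFAULT_LEAD_IN

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("fraction times must be strictly increasing")

    @property
    def n_fractions(self) -> int:
        return len(self.events)

    @property
    def total_dose(self) -> float:
        return sum(e.dose for e in self.events)

    @property
    def last_fraction_time(self) -> float:
        return self.events[-1].time if self.events else self.lead_in

    def scaled(self, dose_scale: float) -> "Protocol":
        """Protocol with every fraction dose multiplied by ``dose_scale``."""
        if dose_scale <= 0:
            raise ValueError("dose_scale must be > 0")
        return Protocol(
            self.name,
            tuple(FractionEvent(e.time, e.dose * dose_scale) for e in self.events),
            self.lead_in,
        )

    def times(self) -> list[float]:
        return [e.time for e in self.events]


def _daily_events(days: Sequence[int], lead_in: float, dose: float):
    return tuple(FractionEvent(lead_in + 24.0 * day, dose) for day in days)


def build_protocol(
    name: str,
    lead_in: float = DEFAULT_LEAD_IN,
    dose_scale: float = 1.0,
    dahanca_fractions: int = 24,
) -> Protocol:
    """Build one of the named protocols (SP, DP, PP, CP).

    ``dose_scale`` multiplies every fraction dose (used for total-dose
    sweeps); timing is unaffected. ``dahanca_fractions`` resolves the
    ambiguity in the accelerated regimen's fraction count (24 default,
    6 per week; 25 extends one day into a fifth week).
    """
    key = name.upper()
    if key == "SP":  # weekdays (days 0-4 of each week) for 5 weeks
        days = [7 * w + d for w in range(5) for d in range(5)]
        events = _daily_events(days, lead_in, DEFAULT_DOSE)
    elif key == "DP":  # 6 days a week
        days = [7 * (i // 6) + (i % 6) for i in range(dahanca_fractions)]
        events = _daily_events(days, lead_in, DEFAULT_DOSE)
    elif key == "PP":  # 25 consecutive days, weekends included
        events = _daily_events(range(25), lead_in, DEFAULT_DOSE)
    elif key == "CP":  # 3 x 1.5 Gy per day, 6 h apart, 12 consecutive days
        events = tuple(
            FractionEvent(lead_in + 24.0 * day + 6.0 * j, CHART_DOSE)
            for day in range(12)
            for j in range(3)
        )
    else:
        raise ValueError(
            f"unknown protocol {name!r}; expected one of {PROTOCOL_NAMES}"
        )
    protocol = Protocol(key, events, lead_in)
    return protocol.scaled(dose_scale) if dose_scale != 1.0 else protocol


def load_schedule_csv(path: str | Path, name: str = "custom") -> Protocol:
    """Load a custom schedule from CSV with columns time_h, dose_Gy."""
    df = pd.read_csv(path)
    missing = {"time_h", "dose_Gy"} - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing column(s): {sorted(missing)}")
    df = df.sort_values("time_h")
    events = tuple(
        FractionEvent(float(t), float(d))
        for t, d in zip(df["time_h"], df["dose_Gy"])
    )
    lead_in = events[0].time if events else 0.0
    return Protocol(name, events, lead_in)
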