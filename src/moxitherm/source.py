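"""Moxa-stick burning-end temperature schedule.

The glowing end of a moxa stick does not burn at a constant temperature.
Two processes shape it: a slow envelope — the freshly lit stick burns near
its peak, then ash gradually accumulates and shields the ember so the
temperature decays over the whole burn — and fast per-minute dips when the
ash is cleaned (the stick is briefly withdrawn and the effective source
temperature drops to 50 degC; not 0 degC, because the surroundings have
been heated).  The envelope is modelled as a cosine,
T_a(t) = (peak − A) + A·cos(2π t / P), peak at t = 0, with amplitude
A = 200 degC and period P = 500 min by default, so that on a 15-minute
treatment the source decays gently from its peak — which is what both the
measured and the reference simulated skin-temperature series imply (a
monotone rise flattening after a few minutes, with only small per-minute
structure).  Shorter periods (an oscillating ember) are a config knob.
Cleaning windows open just after each whole-minute tick, so a sample taken
exactly on the minute still sees the harmonic value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = ["BurnSchedule", "source_temperature", "schedule_for_max",
           "temperature_series", "in_cleaning_window"]


@dataclass(frozen=True)
class BurnSchedule:
    """Periodic burning-temperature law with ash-cleaning overrides.

    The harmonic is (max_temperature − amplitude) + amplitude·cos(2πt/period),
    so the peak is ``max_temperature`` and the trough is
    ``max_temperature − 2·amplitude``.
    """

    max_temperature: float = 600.0  # degC at the cosine peak
    amplitude: float = 200.0  # degC
    period: float = 30000.0  # s (500 min): slow ash-accumulation envelope
    clean_interval: float = 60.0  # s between cleanings
    clean_duration: float = 5.0  # s per cleaning window
    clean_temperature: float = 50.0  # degC during cleaning

    def __post_init__(self) -> None:
        if self.max_temperature <= self.amplitude:
            raise ValueError("max_temperature must exceed amplitude")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not (self.clean_interval > self.clean_duration >= 0):
            raise ValueError("clean_interval must exceed clean_duration >= 0")
        if self.clean_temperature >= self.max_temperature - self.amplitude:
            raise ValueError("clean_temperature must lie below the harmonic offset")

    @property
    def offset(self) -> float:
        """Mean level of the harmonic (degC)."""
        return self.max_temperature - self.amplitude

    @property
    def trough(self) -> float:
        """Minimum harmonic temperature (degC)."""
        return self.max_temperature - 2.0 * self.amplitude


def in_cleaning_window(t: float, schedule: BurnSchedule) -> bool:
    """True when t falls inside an ash-cleaning window.

    Windows are the open intervals (k·interval, k·interval + duration) for
    k = 1, 2, ...: cleaning begins just after each whole-minute tick, so a
    sample taken exactly on the tick (or exactly at the window end) reports
    the harmonic value.
    """
    if schedule.clean_duration == 0 or t <= schedule.clean_interval:
        return False
    offset = math.fmod(t, schedule.clean_interval)
    return 0.0 < offset < schedule.clean_duration


def source_temperature(t: float, schedule: BurnSchedule) -> float:
    """Burning-end temperature (degC) at time t (s)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if in_cleaning_window(t, schedule):
        return schedule.clean_temperature
    return schedule.offset + schedule.amplitude * math.cos(
        2.0 * math.pi * t / schedule.period)


def schedule_for_max(max_temperature: float,
                     base: BurnSchedule | None = None) -> BurnSchedule:
    """Schedule identical to ``base`` (default: the standard one) but with
    the cosine peak shifted to ``max_temperature``; amplitude and period
    are unchanged."""
    base = base if base is not None else BurnSchedule()
    if max_temperature <= base.amplitude:
        raise ValueError("max_temperature must exceed the amplitude")
    return replace(base, max_temperature=max_temperature)


def temperature_series(schedule: BurnSchedule, duration: float,
                       dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the source temperature on the closed grid 0, dt, ..., duration.

    Returns (times, temperatures) arrays.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    temps = np.array([source_temperature(float(t), schedule) for t in times])
    return times, temps
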