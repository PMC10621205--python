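"""Shared domain types for the accelerometry pipeline.

The behavioral vocabulary is the four-class ethogram used for kangaroo-rat
accelerometry classification (motionless, travel, foraging, grooming); the
light-phase vocabulary is the eight-phase diel cycle defined by solar
altitude bands plus the first/last hour of daylight.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np


class BehaviorClass(str, enum.Enum):
    """Four-class behavioral vocabulary for classification."""

    MOTIONLESS = "motionless"
    TRAVEL = "travel"
    FORAGING = "foraging"
    GROOMING = "grooming"

    @classmethod
    def parse(cls, s: str) -> "BehaviorClass":
        try:
            return cls(s.strip().lower())
        except ValueError:
            allowed = ", ".join(b.value for b in cls)
            raise ValueError(
                f"unknown behavior {s!r}; allowed values are: {allowed}"
            ) from None


BEHAVIORS: tuple[BehaviorClass, ...] = tuple(BehaviorClass)
BEHAVIOR_NAMES: tuple[str, ...] = tuple(b.value for b in BehaviorClass)


class LightPhase(str, enum.Enum):
    """Eight diel light phases defined by solar altitude and time of day.

    evening            last hour before sunset (sun above horizon)
    dusk               sun 0-6 degrees below horizon, setting
    evening_twilight   sun 6-18 degrees below horizon, setting
    night              sun more than 18 degrees below horizon
    morning_twilight   sun 18-6 degrees below horizon, rising
    dawn               sun 6-0 degrees below horizon, rising
    morning            first hour after sunrise (sun above horizon)
    day                remaining above-horizon time
    """

    EVENING = "evening"
    DUSK = "dusk"
    EVENING_TWILIGHT = "evening_twilight"
    NIGHT = "night"
    MORNING_TWILIGHT = "morning_twilight"
    DAWN = "dawn"
    MORNING = "morning"
    DAY = "day"


#: Canonical within-night ordering of the phases, starting at evening.
PHASE_ORDER: tuple[LightPhase, ...] = (
    LightPhase.EVENING,
    LightPhase.DUSK,
    LightPhase.EVENING_TWILIGHT,
    LightPhase.NIGHT,
    LightPhase.MORNING_TWILIGHT,
    LightPhase.DAWN,
    LightPhase.MORNING,
    LightPhase.DAY,
)

#: Phases during which the sun is below the horizon ("night phases"); the
#: moonlight analyses are restricted to these.
SUN_DOWN_PHASES: frozenset[LightPhase] = frozenset(
    {
        LightPhase.DUSK,
        LightPhase.EVENING_TWILIGHT,
        LightPhase.NIGHT,
        LightPhase.MORNING_TWILIGHT,
        LightPhase.DAWN,
    }
)


def as_utc(t: datetime) -> datetime:
    """Coerce a datetime to timezone-aware UTC (naive input is taken as UTC)."""
    if t.tzinfo is None:
        return t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration series for one deployment.

    Sample ``i`` is at time ``t0 + i / fs``.  Values are in g; the logger
    records forces in the range [-10, +10] g.
    """

    deployment_id: str
    fs: float
    t0: datetime
    samples: np.ndarray  # shape (n, 3), columns x, y, z in g

    SENSOR_RANGE_G: float = field(default=10.0, repr=False)

    def __post_init__(self) -> None:
        self.t0 = as_utc(self.t0)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("acceleration samples must be finite")
        amax = float(np.abs(self.samples).max(initial=0.0))
        if amax > self.SENSOR_RANGE_G + 1e-9:
            raise ValueError(
                f"sample magnitude {amax:.3f} g exceeds the +/-10 g sensor range"
            )

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def times(self) -> np.ndarray:
        """Per-sample timestamps as a numpy datetime64[ns] array."""
        t0 = np.datetime64(self.t0.replace(tzinfo=None), "ns")
        step = np.round(1e9 / self.fs).astype("timedelta64[ns]")
        return t0 + np.arange(len(self)) * step


@dataclass
class Bout:
    behavior: BehaviorClass
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        self.start = as_utc(self.start)
        self.end = as_utc(self.end)
        if not self.start < self.end:
            raise ValueError("bout start must precede bout end")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class AnnotationSet:
    """Behavior bouts (start/end in UTC) for one deployment.

    Bouts must not overlap; they need not be contiguous (unobserved time is
    simply unannotated).
    """

    deployment_id: str
    bouts: list[Bout]

    def __post_init__(self) -> None:
        self.bouts = sorted(self.bouts, key=lambda b: b.start)
        for a, b in zip(self.bouts, self.bouts[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping bouts: {a.behavior.value} ending {a.end.isoformat()} "
                    f"vs {b.behavior.value} starting {b.start.isoformat()}"
                )

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)
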