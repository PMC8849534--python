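"""Workweek configurations and per-day schedules.

Simulation time is measured in hours since midnight of day 0, and day 0 is
a Monday (``weekday(d) = d mod 7`` with Mon = 0).  A workweek configuration
names the set of working weekdays and the daily work duration; the work
window always opens at the same clock time (08:30 by default), so longer
days run later into the evening.

Six standard layouts are provided, spanning the usual Mon-Fri week,
a mid-week-break variant, compressed weeks (the same weekly hours packed
into 4 or 3 days) and spread-out weeks (6 or 7 short days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

__all__ = [
    "DAY_NAMES",
    "WorkweekConfig",
    "DaySchedule",
    "parse_working_days",
    "resolve_schedule",
    "hours_per_day",
    "format_duration",
    "standard_configurations",
    "standard_week",
]

logger = logging.getLogger(__name__)

DAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
_DAY_INDEX = {name: i for i, name in enumerate(DAY_NAMES)}

#: Default clock times, in hours after midnight.
DEFAULT_WAKE_TIME = 7.0
DEFAULT_WORK_START = 8.5

#: The six standard workweek layouts (name, working-day pattern).
STANDARD_LAYOUTS = (
    ("#1", "Mon-Fri"),
    ("#2", "Mon-Tue and Thu-Sat"),
    ("#3", "Mon-Tue and Thu-Fri"),
    ("#4", "Mon-Tue and Thu"),
    ("#5", "Mon-Sat"),
    ("#6", "Mon-Sun"),
)


def parse_working_days(text: str) -> frozenset[int]:
    """Parse a day-set string like ``"Mon-Fri"`` or ``"Mon-Tue and Thu-Sat"``.

    Segments are separated by ``and`` or commas; each segment is a single
    day name or an inclusive range ``First-Last``.
    """
    days: set[int] = set()
    for chunk in text.replace(" and ", ",").split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            first, last = (part.strip() for part in chunk.split("-", 1))
            if first not in _DAY_INDEX or last not in _DAY_INDEX:
                raise ValueError(f"unknown day name in range {chunk!r}")
            lo, hi = _DAY_INDEX[first], _DAY_INDEX[last]
            if hi < lo:
                raise ValueError(f"day range {chunk!r} runs backwards")
            days.update(range(lo, hi + 1))
        else:
            if chunk not in _DAY_INDEX:
                raise ValueError(f"unknown day name {chunk!r}")
            days.add(_DAY_INDEX[chunk])
    if not days:
        raise ValueError(f"no working days in {text!r}")
    return frozenset(days)


def format_working_days(days: frozenset[int]) -> str:
    return ",".join(DAY_NAMES[d] for d in sorted(days))


@dataclass(frozen=True)
class WorkweekConfig:
    """Which weekdays are worked, for how long, and from when.

    ``hours_per_day`` is the daily work duration in hours; ``work_start``
    the clock time (hours after midnight) at which the window opens.
    """

    name: str
    working_days: frozenset[int]
    hours_per_day: float
    work_start: float = DEFAULT_WORK_START

    def __post_init__(self) -> None:
        object.__setattr__(self, "working_days", frozenset(self.working_days))
        if not self.working_days or not self.working_days <= set(range(7)):
            raise ValueError("working_days must be a non-empty subset of 0..6")
        if not 0 < self.hours_per_day <= 24:
            raise ValueError(
                f"hours_per_day must be in (0, 24], got {self.hours_per_day}"
            )
        if not 0 <= self.work_start < 24:
            raise ValueError("work_start must be a clock time in [0, 24)")

    @property
    def weekly_hours(self) -> float:
        return self.hours_per_day * len(self.working_days)

    @property
    def work_end(self) -> float:
        """Clock time at which work ends (may exceed 24 for overnight days)."""
        return self.work_start + self.hours_per_day

    @classmethod
    def from_weekly_hours(
        cls,
        name: str,
        working_days: frozenset[int] | str,
        weekly_hours: float,
        work_start: float = DEFAULT_WORK_START,
    ) -> "WorkweekConfig":
        if isinstance(working_days, str):
            working_days = parse_working_days(working_days)
        return cls(
            name=name,
            working_days=frozenset(working_days),
            hours_per_day=hours_per_day(working_days, weekly_hours),
            work_start=work_start,
        )


@dataclass(frozen=True)
class DaySchedule:
    """Resolved schedule of one simulation day.

    ``work_window`` is ``(start, end)`` in hours since simulation start, or
    ``None`` on non-working days.  ``wake_time`` is a clock time.
    """

    day_index: int
    wake_time: float
    work_window: tuple[float, float] | None

    @property
    def wake_abs(self) -> float:
        """Waking moment in hours since simulation start."""
        return 24.0 * self.day_index + self.wake_time


def resolve_schedule(
    config: WorkweekConfig, day_index: int, wake: float = DEFAULT_WAKE_TIME
) -> DaySchedule:
    """Resolve the work window of one simulation day.

    Day 0 is a Monday.  On working days the window is
    ``[work_start, work_start + hours_per_day]`` converted to hours since
    simulation start.  A window running past midnight (possible for the most
    compressed long-hour layouts) is allowed but logged, since it implies
    work during the normal sleep period.
    """
    if day_index < 0:
        raise ValueError("day_index must be >= 0")
    weekday = day_index % 7
    if weekday not in config.working_days:
        return DaySchedule(day_index=day_index, wake_time=wake, work_window=None)
    start = 24.0 * day_index + config.work_start
    end = start + config.hours_per_day
    if config.work_end > 24.0:
        key = (config.name, config.work_start, config.hours_per_day)
        if key not in _overnight_warned:
            _overnight_warned.add(key)
            logger.warning(
                "work window of %s runs past midnight (ends %s after midnight)",
                config.name,
                format_duration(config.work_end - 24.0),
            )
    return DaySchedule(day_index=day_index, wake_time=wake, work_window=(start, end))


_overnight_warned: set[tuple[str, float, float]] = set()


def hours_per_day(working_days: frozenset[int] | int, weekly_hours: float) -> float:
    """Daily work duration implied by a weekly total spread over the working days."""
    n_days = working_days if isinstance(working_days, int) else len(working_days)
    if n_days <= 0:
        raise ValueError("need at least one working day")
    if weekly_hours <= 0:
        raise ValueError("weekly_hours must be > 0")
    return weekly_hours / n_days


def format_duration(hours: float) -> str:
    """Format a duration as ``"8h"`` / ``"13h20m"``, rounded to the nearest minute."""
    total_minutes = round(hours * 60)
    h, m = divmod(total_minutes, 60)
    return f"{h}h" if m == 0 else f"{h}h{m:02d}m"


def standard_configurations(
    weekly_hours: float = 40.0, work_start: float = DEFAULT_WORK_START
) -> list[WorkweekConfig]:
    """The six standard workweek layouts at a given weekly-hours total."""
    return [
        WorkweekConfig.from_weekly_hours(name, pattern, weekly_hours, work_start)
        for name, pattern in STANDARD_LAYOUTS
    ]


def standard_week(hours_per_day: float = 8.0) -> WorkweekConfig:
    """The benchmark configuration: Mon-Fri at ``hours_per_day`` hours per day."""
    return WorkweekConfig(
        name="#1", working_days=parse_working_days("Mon-Fri"), hours_per_day=hours_per_day
    )
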