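"""Realisation of per-person impulse trains on a continuous time axis.

Each simulated day a person receives a Poisson number of *night impulses*
(circadian HPA-axis drive, clustered exponentially just before waking) and,
on working days, a Poisson number of *work impulses* (stressors, uniform
over the work window).  Impulses have binary intensity and a fixed 30-minute
duration, so the forcing seen by the cortisol equation at any grid step is
simply the count of impulses active at that step.

The expected daily work-impulse count scales linearly with the length of
the working day relative to the 8-hour reference day, so layouts with equal
weekly hours carry equal expected weekly stressor counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .population import PersonParams
from .schedule import DEFAULT_WAKE_TIME, WorkweekConfig, resolve_schedule

__all__ = [
    "NIGHT",
    "WORK",
    "IMPULSE_DURATION",
    "REFERENCE_WORKDAY_HOURS",
    "Impulse",
    "ImpulseTrain",
    "scaled_work_rate",
    "daily_count",
    "draw_night_times",
    "draw_work_times",
    "build_train",
    "rasterize",
]

logger = logging.getLogger(__name__)

NIGHT = "night"
WORK = "work"

#: Fixed impulse duration, hours (mirrors the ~30 min acute cortisol response).
IMPULSE_DURATION = 0.5

#: Workday length at which ``lambda_work`` is defined.
REFERENCE_WORKDAY_HOURS = 8.0


@dataclass(frozen=True)
class Impulse:
    """A single binary-intensity impulse."""

    onset: float
    kind: str
    duration: float = IMPULSE_DURATION


class ImpulseTrain:
    """Timed night/work impulses of one person, sorted by onset."""

    def __init__(self, person_id: int, onsets, kinds):
        onsets = np.asarray(onsets, dtype=float)
        kinds = np.asarray(kinds, dtype=object)
        if onsets.shape != kinds.shape:
            raise ValueError("onsets and kinds must have the same length")
        order = np.argsort(onsets, kind="stable")
        self.person_id = int(person_id)
        self.onsets = onsets[order]
        self.kinds = kinds[order]

    def __len__(self) -> int:
        return len(self.onsets)

    def __iter__(self):
        for onset, kind in zip(self.onsets, self.kinds):
            yield Impulse(onset=float(onset), kind=str(kind))

    def count(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self)
        return int(np.sum(self.kinds == kind))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": self.person_id,
                "onset_hours": self.onsets,
                "kind": self.kinds.astype(str),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ImpulseTrain":
        ids = frame["person_id"].unique()
        if len(ids) != 1:
            raise ValueError("frame must describe exactly one person")
        return cls(int(ids[0]), frame["onset_hours"].to_numpy(), frame["kind"].to_numpy())


def scaled_work_rate(lambda_work: float, hours_per_day: float) -> float:
    """Effective expected daily work-impulse count for a given day length.

    ``lambda_work`` is defined per 8-hour reference day; longer days expose
    the person to proportionally more stressors.
    """
    if hours_per_day <= 0:
        raise ValueError("hours_per_day must be > 0")
    return lambda_work * hours_per_day / REFERENCE_WORKDAY_HOURS


def daily_count(lam: float, rng: np.random.Generator) -> int:
    """Poisson draw of a day's impulse count with expectation ``lam``."""
    if lam < 0:
        raise ValueError("expected count must be >= 0")
    return int(rng.poisson(lam))


def draw_night_times(
    count: int, wake_abs: float, rng: np.random.Generator
) -> np.ndarray:
    """Onsets of night impulses, clustered exponentially before waking.

    Each onset is ``wake_abs - e`` with ``e ~ Exponential(rate 1/h)``, so the
    impulse density rises towards the waking moment, where it peaks.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    return wake_abs - rng.exponential(1.0, count)


def draw_work_times(
    count: int, window: tuple[float, float] | None, rng: np.random.Generator
) -> np.ndarray:
    """Onsets of work impulses, i.i.d. uniform over the work window."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if window is None:
        if count > 0:
            raise ValueError("cannot place work impulses on a day without a work window")
        return np.empty(0)
    start, end = window
    if not start < end:
        raise ValueError("work window must have start < end")
    return rng.uniform(start, end, count)


def build_train(
    person: PersonParams,
    config: WorkweekConfig,
    days: int,
    rng: np.random.Generator,
    work_rng: np.random.Generator | None = None,
    wake: float = DEFAULT_WAKE_TIME,
    anticipation_scaling: bool = False,
) -> ImpulseTrain:
    """Realise a person's full impulse train over ``days`` simulation days.

    Night impulses occur every day (the circadian drive never pauses);
    work impulses only within work windows, with the daily expectation
    scaled to the configuration's day length.  ``work_rng``, when given,
    draws the work side from a separate stream so night realisations are
    identical across workweek configurations (common random numbers).

    With ``anticipation_scaling`` (meant for populations whose night rate
    is coupled to the work rate) the work-rate component of the night rate
    follows the configuration's day length too: the morning peak reflects
    anticipation of the *actual* upcoming daily demand, so the effective
    nightly rate becomes ``lambda_night + lambda_work * (h - 8) / 8`` for an
    ``h``-hour workday.  At the 8-hour reference day this is the identity.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    wrng = work_rng if work_rng is not None else rng

    night_rate = person.lambda_night
    if anticipation_scaling:
        night_rate = max(
            0.0,
            night_rate
            + scaled_work_rate(person.lambda_work, config.hours_per_day)
            - person.lambda_work,
        )

    wake_abs = 24.0 * np.arange(days) + wake
    night_counts = rng.poisson(night_rate, days)
    night_onsets = np.repeat(wake_abs, night_counts) - rng.exponential(
        1.0, int(night_counts.sum())
    )

    windows = [
        resolve_schedule(config, d, wake).work_window for d in range(days)
    ]
    windows = [w for w in windows if w is not None]
    if windows:
        rate = scaled_work_rate(person.lambda_work, config.hours_per_day)
        work_counts = wrng.poisson(rate, len(windows))
        starts = np.repeat([w[0] for w in windows], work_counts)
        widths = np.repeat([w[1] - w[0] for w in windows], work_counts)
        work_onsets = starts + wrng.uniform(0.0, 1.0, int(work_counts.sum())) * widths
    else:
        work_onsets = np.empty(0)

    onsets = np.concatenate([night_onsets, work_onsets])
    kinds = np.array([NIGHT] * len(night_onsets) + [WORK] * len(work_onsets), dtype=object)
    return ImpulseTrain(person.person_id, onsets, kinds)


def rasterize(
    train: ImpulseTrain,
    dt: float,
    horizon: float,
    t_start: float = 0.0,
) -> np.ndarray:
    """Grid the train into per-step active-impulse counts.

    The grid covers ``[t_start, horizon)`` in steps of ``dt``; an impulse
    occupies exactly the step containing its onset (the impulse duration
    equals the default step), and simultaneous impulses add up -- a larger
    count acts as a stronger forcing.  Onsets outside the grid are dropped;
    those also outside the 24 h pre-roll margin are logged.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_steps_f = (horizon - t_start) / dt
    n_steps = round(n_steps_f)
    if abs(n_steps_f - n_steps) > 1e-9 or n_steps <= 0:
        raise ValueError("horizon - t_start must be a positive multiple of dt")

    idx = np.floor((train.onsets - t_start) / dt).astype(np.int64)
    in_grid = (idx >= 0) & (idx < n_steps)
    far_out = (train.onsets < min(t_start, -24.0)) | (train.onsets >= horizon)
    if far_out.any():
        logger.warning(
            "dropping %d impulse(s) outside [%g, %g) for person %d",
            int(far_out.sum()),
            min(t_start, -24.0),
            horizon,
            train.person_id,
        )
    return np.bincount(idx[in_grid], minlength=n_steps)
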