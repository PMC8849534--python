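"""Sampling of per-person trait parameters.

Every simulated person carries three fixed traits:

* ``lambda_night`` -- expected number of night impulses per night (the
  circadian drive behind the cortisol morning peak),
* ``lambda_work`` -- expected number of work-stressor impulses per standard
  8-hour workday,
* ``rho_c`` -- first-order cortisol decay constant, per hour.

Two population scenarios are supported.  Under Scenario I the night and work
rates are drawn independently.  Under Scenario II -- modelling anticipation
of the upcoming workday -- the night rate is the work rate plus an
independent gamma draw, which induces a strong positive correlation between
the two without changing the work-rate marginal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import GammaSpec, NormalSpec, UniformSpec

__all__ = [
    "Scenario",
    "ScenarioSpec",
    "PersonParams",
    "Population",
    "sample_decay_constants",
    "sample_person_rates",
    "build_population",
]


class Scenario(str, enum.Enum):
    """Population-generation variant: uncorrelated (I) or coupled (II) rates."""

    I = "I"
    II = "II"


@dataclass(frozen=True)
class ScenarioSpec:
    """How person-level impulse rates are generated.

    ``night_rate_dist`` is used only under Scenario I; ``coupling_dist``
    (the additive anticipation term) only under Scenario II.
    """

    scenario: Scenario
    work_rate_dist: GammaSpec | UniformSpec
    night_rate_dist: GammaSpec | None = None
    coupling_dist: GammaSpec | None = None

    def __post_init__(self) -> None:
        scenario = Scenario(self.scenario)
        object.__setattr__(self, "scenario", scenario)
        if scenario is Scenario.I and self.night_rate_dist is None:
            raise ValueError("Scenario I requires night_rate_dist")
        if scenario is Scenario.II and self.coupling_dist is None:
            raise ValueError("Scenario II requires coupling_dist")


@dataclass(frozen=True)
class PersonParams:
    """Fixed traits of one simulated person."""

    person_id: int
    lambda_work: float
    lambda_night: float
    rho_c: float

    def __post_init__(self) -> None:
        if not self.lambda_night > 0:
            raise ValueError("lambda_night must be > 0")
        if self.lambda_work < 0:
            raise ValueError("lambda_work must be >= 0")
        if not self.rho_c > 0:
            raise ValueError("rho_c must be > 0")


@dataclass
class Population:
    """Column-oriented container of :class:`PersonParams`.

    Iterating or indexing yields `PersonParams`; the array attributes are
    what the vectorised simulators consume.
    """

    lambda_work: np.ndarray
    lambda_night: np.ndarray
    rho_c: np.ndarray
    person_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lambda_work = np.asarray(self.lambda_work, dtype=float)
        self.lambda_night = np.asarray(self.lambda_night, dtype=float)
        self.rho_c = np.asarray(self.rho_c, dtype=float)
        n = len(self.lambda_work)
        if self.person_id is None:
            self.person_id = np.arange(n)
        self.person_id = np.asarray(self.person_id, dtype=int)
        if not (len(self.lambda_night) == len(self.rho_c) == len(self.person_id) == n):
            raise ValueError("population columns must have equal length")

    def __len__(self) -> int:
        return len(self.person_id)

    def __getitem__(self, i: int) -> PersonParams:
        return PersonParams(
            person_id=int(self.person_id[i]),
            lambda_work=float(self.lambda_work[i]),
            lambda_night=float(self.lambda_night[i]),
            rho_c=float(self.rho_c[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": self.person_id,
                "lambda_work": self.lambda_work,
                "lambda_night": self.lambda_night,
                "rho_c": self.rho_c,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Population":
        required = {"person_id", "lambda_work", "lambda_night", "rho_c"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"population table missing columns: {sorted(missing)}")
        return cls(
            lambda_work=frame["lambda_work"].to_numpy(),
            lambda_night=frame["lambda_night"].to_numpy(),
            rho_c=frame["rho_c"].to_numpy(),
            person_id=frame["person_id"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Population":
        return cls.from_frame(pd.read_csv(path))


def sample_decay_constants(
    n: int,
    spec: NormalSpec,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> np.ndarray:
    """Draw ``n`` cortisol decay constants (per hour), all strictly positive.

    Non-positive normal draws are redrawn; with the default distribution
    (mean 0.52, SD 0.05) a non-positive draw is a ~10-sigma event, so the
    redraw loop is effectively never entered.  A spec with non-positive mean
    is rejected outright because redrawing would then dominate.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if spec.mean <= 0:
        raise ValueError(f"decay-constant mean must be > 0, got {spec.mean}")
    values = np.atleast_1d(np.asarray(spec.sample(rng, n), dtype=float))
    if n == 0:
        return np.empty(0)
    for _ in range(max_redraws):
        bad = values <= 0
        if not bad.any():
            return values
        values[bad] = spec.sample(rng, int(bad.sum()))
    raise RuntimeError(
        f"could not draw {n} positive decay constants within "
        f"{max_redraws} redraw rounds from {spec}"
    )


def sample_person_rates(
    n: int,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    night_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` pairs of (work rate, night rate).

    ``night_rng``, when given, supplies the night-side draws from a separate
    stream so that the work-rate sequence does not depend on how many night
    draws were consumed (used for reproducible populations).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    second = night_rng if night_rng is not None else rng
    lam_w = np.atleast_1d(np.asarray(spec.work_rate_dist.sample(rng, n), dtype=float))
    if n == 0:
        return np.empty(0), np.empty(0)
    if spec.scenario is Scenario.I:
        lam_n = np.atleast_1d(
            np.asarray(spec.night_rate_dist.sample(second, n), dtype=float)
        )
    else:
        lam_n = lam_w + np.asarray(spec.coupling_dist.sample(second, n), dtype=float)
    return lam_w, lam_n


def build_population(
    n: int,
    scenario: ScenarioSpec,
    decay: NormalSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> Population:
    """Sample a full population of ``n`` persons.

    When ``seed`` is an integer or a :class:`~numpy.random.SeedSequence`,
    three independent substreams are spawned (work rates, night/coupling
    draws, decay constants) so that person ``i``'s traits do not depend on
    the population size: growing ``n`` appends people without disturbing
    earlier ones.  Passing a bare ``Generator`` uses it sequentially.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if isinstance(seed, np.random.Generator):
        rng_work = rng_night = rng_decay = seed
    else:
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        rng_work, rng_night, rng_decay = (np.random.default_rng(c) for c in ss.spawn(3))
    lam_w, lam_n = sample_person_rates(n, scenario, rng_work, night_rng=rng_night)
    rho = sample_decay_constants(n, decay, rng_decay)
    return Population(lambda_work=lam_w, lambda_night=lam_n, rho_c=rho)
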