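"""Run configuration: defaults, TOML loading/saving and validation.

A :class:`RunConfig` fully determines one seeded experiment.  Unset fields
take the reference defaults of the corresponding study:

* study 1 (cortisol time courses): 10,000 people, 200 days, Scenario I,
  gamma-distributed work rates;
* study 2 (robustness sweep of the stress-disease link): 5,000 people,
  Scenario II, uniform work rates for even exposure coverage, and the
  3 x 3 x 3 grid over recovery coefficient and thresholds;
* study 3 (workweek configurations): 5,000 people, Scenario II, uniform
  work rates, six layouts at 30/40/50 weekly hours against the Mon-Fri
  40 h benchmark.

Configs are TOML documents; unknown keys are rejected with the offending
key named, and every field is validated against the owning module's
invariants before any simulation starts.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .distributions import GammaSpec, NormalSpec, UniformSpec
from .dynamics import DynamicsParams
from .epi import DEFAULT_CHECKPOINT_DAYS, DEFAULT_SWEEP, SweepGrid
from .population import Scenario, ScenarioSpec
from .schedule import (
    DEFAULT_WAKE_TIME,
    DEFAULT_WORK_START,
    WorkweekConfig,
    format_working_days,
    parse_working_days,
)

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "NIGHT_QUANTITY",
    "WORK_QUANTITY_GAMMA",
    "WORK_QUANTITY_UNIFORM",
    "ANTICIPATION_COUPLING",
    "DECAY_DISTRIBUTION",
]

# Reference trait distributions.
NIGHT_QUANTITY = GammaSpec(shape=3.0, scale=14.0)
WORK_QUANTITY_GAMMA = GammaSpec(shape=3.0, scale=6.0)
WORK_QUANTITY_UNIFORM = UniformSpec(lower=1.0, upper=50.0)
ANTICIPATION_COUPLING = GammaSpec(shape=1.0, scale=8.0)
DECAY_DISTRIBUTION = NormalSpec(mean=0.52, sd=0.05)


@dataclass
class RunConfig:
    """Validated settings of one seeded simulation experiment."""

    study: int = 1
    n_people: int = 10_000
    n_days: int = 200
    sampling_per_hour: int = 2
    seed: int = 0
    scenario: ScenarioSpec = field(
        default_factory=lambda: ScenarioSpec(
            scenario=Scenario.I,
            work_rate_dist=WORK_QUANTITY_GAMMA,
            night_rate_dist=NIGHT_QUANTITY,
            coupling_dist=ANTICIPATION_COUPLING,
        )
    )
    decay: NormalSpec = DECAY_DISTRIBUTION
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    workweek: WorkweekConfig = field(
        default_factory=lambda: WorkweekConfig(
            name="#1",
            working_days=parse_working_days("Mon-Fri"),
            hours_per_day=8.0,
            work_start=DEFAULT_WORK_START,
        )
    )
    wake: float = DEFAULT_WAKE_TIME
    checkpoint_days: tuple[int, ...] = DEFAULT_CHECKPOINT_DAYS
    sweep: SweepGrid = DEFAULT_SWEEP
    weekly_hours: tuple[float, ...] = (30.0, 40.0, 50.0)
    benchmark_weekly_hours: float = 40.0
    n_timecourses: int = 0

    def __post_init__(self) -> None:
        if self.study not in (1, 2, 3):
            raise ValueError(f"study must be 1, 2 or 3, got {self.study}")
        if self.n_people < 0:
            raise ValueError("n_people must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.sampling_per_hour < 1:
            raise ValueError("sampling_per_hour must be >= 1")
        expected_dt = 1.0 / self.sampling_per_hour
        if abs(self.dynamics.dt - expected_dt) > 1e-12:
            self.dynamics = dataclasses.replace(self.dynamics, dt=expected_dt)
        self.checkpoint_days = tuple(int(d) for d in self.checkpoint_days)
        if any(d < 0 for d in self.checkpoint_days):
            raise ValueError("checkpoint days must be >= 0")
        self.weekly_hours = tuple(float(h) for h in self.weekly_hours)


def _study_defaults(study: int) -> RunConfig:
    if study == 1:
        return RunConfig(study=1)
    scenario = ScenarioSpec(
        scenario=Scenario.II,
        work_rate_dist=WORK_QUANTITY_UNIFORM,
        night_rate_dist=NIGHT_QUANTITY,
        coupling_dist=ANTICIPATION_COUPLING,
    )
    return RunConfig(study=study, n_people=5_000, scenario=scenario)


def _parse_dist(value, key: str):
    if not isinstance(value, dict) or "dist" not in value:
        raise ValueError(f"{key} must be a table with a 'dist' entry")
    spec = dict(value)
    kind = spec.pop("dist")
    try:
        if kind == "gamma":
            return GammaSpec(**spec)
        if kind == "uniform":
            return UniformSpec(**spec)
        if kind == "normal":
            return NormalSpec(**spec)
    except TypeError as exc:
        raise ValueError(f"bad parameters for {key}: {exc}") from exc
    raise ValueError(f"{key}: unknown distribution kind {kind!r}")


def _pop(table: dict, key: str, default):
    return table.pop(key, default)


def _reject_unknown(table: dict, context: str) -> None:
    if table:
        raise ValueError(f"unknown key(s) in {context}: {sorted(table)}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration.

    An empty file yields the full study-1 defaults.  Unknown keys raise a
    :class:`ValueError` naming the key.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> RunConfig:
    doc = dict(doc)
    study = int(_pop(doc, "study", 1))
    base = _study_defaults(study)

    n_people = int(_pop(doc, "n_people", base.n_people))
    n_days = int(_pop(doc, "n_days", base.n_days))
    sampling = int(_pop(doc, "sampling_per_hour", base.sampling_per_hour))
    if sampling < 1:
        raise ValueError("sampling_per_hour must be >= 1")
    seed = int(_pop(doc, "seed", base.seed))
    scenario_name = str(_pop(doc, "scenario", base.scenario.scenario.value))
    checkpoints = tuple(_pop(doc, "checkpoint_days", base.checkpoint_days))
    n_timecourses = int(_pop(doc, "n_timecourses", base.n_timecourses))

    dists = dict(_pop(doc, "distributions", {}))
    work = (
        _parse_dist(dists.pop("work_quantity"), "distributions.work_quantity")
        if "work_quantity" in dists
        else base.scenario.work_rate_dist
    )
    night = (
        _parse_dist(dists.pop("night_quantity"), "distributions.night_quantity")
        if "night_quantity" in dists
        else base.scenario.night_rate_dist
    )
    coupling = (
        _parse_dist(dists.pop("coupling"), "distributions.coupling")
        if "coupling" in dists
        else base.scenario.coupling_dist
    )
    if "decay" in dists:
        decay_tbl = dict(dists.pop("decay"))
        decay = NormalSpec(
            mean=float(_pop(decay_tbl, "mean", DECAY_DISTRIBUTION.mean)),
            sd=float(_pop(decay_tbl, "sd", DECAY_DISTRIBUTION.sd)),
        )
        _reject_unknown(decay_tbl, "distributions.decay")
    else:
        decay = base.decay
    _reject_unknown(dists, "distributions")

    dyn_tbl = dict(_pop(doc, "dynamics", {}))
    dyn_base = base.dynamics
    dynamics = DynamicsParams(
        kappa_hpa=float(_pop(dyn_tbl, "kappa_hpa", dyn_base.kappa_hpa)),
        tau=float(_pop(dyn_tbl, "tau", dyn_base.tau)),
        rho_r=float(_pop(dyn_tbl, "rho_r", dyn_base.rho_r)),
        eps_l=float(_pop(dyn_tbl, "eps_l", dyn_base.eps_l)),
        eps_d=float(_pop(dyn_tbl, "eps_d", dyn_base.eps_d)),
        dt=1.0 / sampling,
        decay_mode=str(_pop(dyn_tbl, "decay_mode", dyn_base.decay_mode)),
    )
    _reject_unknown(dyn_tbl, "dynamics")

    sched_tbl = dict(_pop(doc, "schedule", {}))
    wake = float(_pop(sched_tbl, "wake", base.wake))
    work_start = float(_pop(sched_tbl, "work_start", base.workweek.work_start))
    working_days = _pop(sched_tbl, "working_days", None)
    hours = float(_pop(sched_tbl, "hours_per_day", base.workweek.hours_per_day))
    _reject_unknown(sched_tbl, "schedule")
    days_set = (
        parse_working_days(str(working_days))
        if working_days is not None
        else base.workweek.working_days
    )
    workweek = WorkweekConfig(
        name="#1", working_days=days_set, hours_per_day=hours, work_start=work_start
    )

    sweep_tbl = dict(_pop(doc, "sweep", {}))
    sweep = SweepGrid(
        rho_r=tuple(_pop(sweep_tbl, "rho_r", base.sweep.rho_r)),
        eps_l=tuple(_pop(sweep_tbl, "eps_l", base.sweep.eps_l)),
        eps_d=tuple(_pop(sweep_tbl, "eps_d", base.sweep.eps_d)),
    )
    _reject_unknown(sweep_tbl, "sweep")

    s3_tbl = dict(_pop(doc, "study3", {}))
    weekly_hours = tuple(_pop(s3_tbl, "weekly_hours", base.weekly_hours))
    benchmark_hours = float(
        _pop(s3_tbl, "benchmark_weekly_hours", base.benchmark_weekly_hours)
    )
    _reject_unknown(s3_tbl, "study3")

    _reject_unknown(doc, "config root")

    scenario = ScenarioSpec(
        scenario=Scenario(scenario_name),
        work_rate_dist=work,
        night_rate_dist=night,
        coupling_dist=coupling,
    )
    return RunConfig(
        study=study,
        n_people=n_people,
        n_days=n_days,
        sampling_per_hour=sampling,
        seed=seed,
        scenario=scenario,
        decay=decay,
        dynamics=dynamics,
        workweek=workweek,
        wake=wake,
        checkpoint_days=checkpoints,
        sweep=sweep,
        weekly_hours=weekly_hours,
        benchmark_weekly_hours=benchmark_hours,
        n_timecourses=n_timecourses,
    )


def _dist_toml(spec) -> str:
    if isinstance(spec, GammaSpec):
        return f'{{dist = "gamma", shape = {spec.shape}, scale = {spec.scale}}}'
    if isinstance(spec, UniformSpec):
        return f'{{dist = "uniform", lower = {spec.lower}, upper = {spec.upper}}}'
    if isinstance(spec, NormalSpec):
        return f'{{dist = "normal", mean = {spec.mean}, sd = {spec.sd}}}'
    raise TypeError(f"cannot serialise {spec!r}")


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as TOML such that :func:`load_config` round-trips it."""
    lines = [
        f"study = {config.study}",
        f"n_people = {config.n_people}",
        f"n_days = {config.n_days}",
        f"sampling_per_hour = {config.sampling_per_hour}",
        f"seed = {config.seed}",
        f'scenario = "{config.scenario.scenario.value}"',
        f"checkpoint_days = {list(config.checkpoint_days)}",
        f"n_timecourses = {config.n_timecourses}",
        "",
        "[distributions]",
        f"work_quantity = {_dist_toml(config.scenario.work_rate_dist)}",
        f"night_quantity = {_dist_toml(config.scenario.night_rate_dist)}",
        f"coupling = {_dist_toml(config.scenario.coupling_dist)}",
        f"decay = {{mean = {config.decay.mean}, sd = {config.decay.sd}}}",
        "",
        "[dynamics]",
        f"kappa_hpa = {config.dynamics.kappa_hpa}",
        f"tau = {config.dynamics.tau}",
        f"rho_r = {config.dynamics.rho_r}",
        f"eps_l = {config.dynamics.eps_l}",
        f"eps_d = {config.dynamics.eps_d}",
        f'decay_mode = "{config.dynamics.decay_mode}"',
        "",
        "[schedule]",
        f"wake = {config.wake}",
        f"work_start = {config.workweek.work_start}",
        f'working_days = "{format_working_days(config.workweek.working_days)}"',
        f"hours_per_day = {config.workweek.hours_per_day}",
        "",
        "[sweep]",
        f"rho_r = {list(config.sweep.rho_r)}",
        f"eps_l = {list(config.sweep.eps_l)}",
        f"eps_d = {list(config.sweep.eps_d)}",
        "",
        "[study3]",
        f"weekly_hours = {list(config.weekly_hours)}",
        f"benchmark_weekly_hours = {config.benchmark_weekly_hours}",
        "",
    ]
    Path(path).write_text("\n".join(lines), encoding="utf-8")
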