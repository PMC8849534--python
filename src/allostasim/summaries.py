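"""Diurnal cortisol summaries: wake-aligned day curves and per-person indices.

The indices are the standard saliva-protocol quantities computed here on
the simulation grid:

* ``AUC_G`` -- trapezoidal area under the curve with respect to ground,
* ``AUC_I`` -- the same area minus the rectangle spanned by the waking
  sample (area with respect to the increase; may be negative),
* wake-to-bed slope -- cortisol change per hour between the waking sample
  and the bedtime sample, by default the two-endpoint difference with
  bedtime fixed at wake + 16 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import PopulationResult, TimeCourse
from .schedule import DEFAULT_WAKE_TIME

__all__ = [
    "DiurnalIndices",
    "auc_g",
    "auc_i",
    "wake_bed_slope",
    "day_curve",
    "diurnal_indices",
]

#: Default span between waking and "bed" samples, hours.
DEFAULT_DAY_SPAN = 16.0


@dataclass(frozen=True)
class DiurnalIndices:
    person_id: int
    auc_g: float
    auc_i: float
    wake_bed_slope: float


def _check_samples(samples: np.ndarray, times: np.ndarray) -> None:
    if len(samples) != len(times):
        raise ValueError("samples and times must have equal length")
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")


def auc_g(samples, times) -> float:
    """Trapezoidal area under the curve with respect to the ground."""
    samples = np.asarray(samples, dtype=float)
    times = np.asarray(times, dtype=float)
    _check_samples(samples, times)
    return float(np.trapezoid(samples, times))


def auc_i(samples, times) -> float:
    """Area under the curve with respect to the increase above the first sample."""
    samples = np.asarray(samples, dtype=float)
    times = np.asarray(times, dtype=float)
    _check_samples(samples, times)
    span = times[-1] - times[0]
    return float(np.trapezoid(samples, times) - samples[0] * span)


def wake_bed_slope(
    samples,
    times,
    wake_t: float,
    bed_t: float | None = None,
    method: str = "endpoints",
) -> float:
    """Cortisol slope between the waking and bedtime samples.

    The samples nearest to ``wake_t`` and ``bed_t`` (default wake + 16 h)
    are used.  ``method="endpoints"`` takes the two-point difference
    quotient; ``method="regression"`` fits an ordinary least-squares line
    over all samples in between.
    """
    samples = np.asarray(samples, dtype=float)
    times = np.asarray(times, dtype=float)
    _check_samples(samples, times)
    if bed_t is None:
        bed_t = wake_t + DEFAULT_DAY_SPAN
    if bed_t <= wake_t:
        raise ValueError("bed time must be after wake time")
    i_wake = int(np.argmin(np.abs(times - wake_t)))
    i_bed = int(np.argmin(np.abs(times - bed_t)))
    if i_bed <= i_wake:
        raise ValueError("no samples between wake and bed times")
    if method == "endpoints":
        return float(
            (samples[i_bed] - samples[i_wake]) / (times[i_bed] - times[i_wake])
        )
    if method == "regression":
        sel = slice(i_wake, i_bed + 1)
        slope, _ = np.polyfit(times[sel], samples[sel], 1)
        return float(slope)
    raise ValueError("method must be 'endpoints' or 'regression'")


def _cortisol_matrix(
    source: PopulationResult | list[TimeCourse],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (t, cortisol matrix, person ids) from a result or time courses."""
    if isinstance(source, PopulationResult):
        if source.cortisol is None:
            raise ValueError(
                "PopulationResult has no stored cortisol; simulate with keep_cortisol=True"
            )
        return source.t, np.asarray(source.cortisol, dtype=float), source.people[
            "person_id"
        ].to_numpy()
    if not source:
        raise ValueError("no time courses given")
    t = source[0].t
    for tc in source:
        if len(tc.t) != len(t) or not np.allclose(tc.t, t):
            raise ValueError("time courses must share a common grid")
    C = np.vstack([tc.cortisol for tc in source])
    ids = np.array([tc.person_id for tc in source])
    return t, C, ids


def day_curve(
    source: PopulationResult | list[TimeCourse],
    day_index: int = 0,
    wake: float = DEFAULT_WAKE_TIME,
    window: tuple[float, float] = (0.0, DEFAULT_DAY_SPAN),
    percentiles: tuple[float, ...] = (2.5, 97.5),
) -> pd.DataFrame:
    """Group mean (and percentile band) cortisol curve, aligned to waking.

    The time axis is re-zeroed at the waking moment of ``day_index``;
    ``window`` is in hours relative to waking and may start negative to
    include the pre-waking night segment.
    """
    t, C, _ = _cortisol_matrix(source)
    wake_abs = 24.0 * day_index + wake
    lo, hi = window
    mask = (t >= wake_abs + lo) & (t <= wake_abs + hi)
    if not mask.any():
        raise ValueError("requested day/window lies outside the simulated horizon")
    out = pd.DataFrame({"t_since_wake_hours": t[mask] - wake_abs})
    out["mean"] = C[:, mask].mean(axis=0)
    for q in percentiles:
        out[f"p{q}".replace(".", "_")] = np.percentile(C[:, mask], q, axis=0)
    return out


def diurnal_indices(
    source: PopulationResult | list[TimeCourse],
    day_index: int = 0,
    wake: float = DEFAULT_WAKE_TIME,
    span: float = DEFAULT_DAY_SPAN,
) -> pd.DataFrame:
    """Per-person AUC_G, AUC_I and wake-to-bed slope for one simulated day."""
    t, C, ids = _cortisol_matrix(source)
    wake_abs = 24.0 * day_index + wake
    mask = (t >= wake_abs) & (t <= wake_abs + span)
    if mask.sum() < 2:
        raise ValueError("day window holds fewer than two samples")
    tt = t[mask]
    rows = []
    for pid, series in zip(ids, C[:, mask]):
        rows.append(
            DiurnalIndices(
                person_id=int(pid),
                auc_g=auc_g(series, tt),
                auc_i=auc_i(series, tt),
                wake_bed_slope=wake_bed_slope(series, tt, wake_t=tt[0], bed_t=tt[-1]),
            )
        )
    return pd.DataFrame(
        {
            "person_id": [r.person_id for r in rows],
            "auc_g": [r.auc_g for r in rows],
            "auc_i": [r.auc_i for r in rows],
            "slope": [r.wake_bed_slope for r in rows],
        }
    )
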