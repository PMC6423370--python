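"""Plot-grid microclimate analytics.

Low-cost sensors cover only a subset of the plots in a field trial, so
per-plot climate for the remaining plots is estimated by inverse-distance
weighting (IDW, power 2) over the measured plots, using Euclidean distance
on the plot grid.  IDW weights are convex, which makes the scheme exact at
measured plots, bounded by the measured range, and translation-equivariant
— all properties the tests exercise.

On top of interpolation sit three consumers: heat-map time series (14-day
frame interval by default, matching how a growing season is summarized),
leave-one-out cross-validation of the sensor network, and a rule-based
detector for late-blight risk periods.  A "Smith Period" is at least two
consecutive days, each with a daily minimum temperature of at least 10 °C
and at least 11 hours of relative humidity at or above 90%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import RiskPeriod, format_utc
from .store import Store

#: Smith rule constants: threshold temperatures/humidity and minimum runs.
SMITH_MIN_TEMP_C = 10.0
SMITH_RH_THRESHOLD_PCT = 90.0
SMITH_MIN_WET_HOURS = 11
SMITH_MIN_RUN_DAYS = 2

#: Default half-width of the temporal aggregation window for one frame.
DEFAULT_WINDOW_HOURS = 12.0
#: Default spacing of heat-map frames across a season.
DEFAULT_INTERVAL_DAYS = 14
#: IDW distance exponent.
IDW_POWER = 2.0


class NoDataError(RuntimeError):
    """No sensor has a reading for the variable in the requested window."""


class InsufficientSensorsError(RuntimeError):
    """Cross-validation needs at least two sensors with data."""


class AlignmentError(ValueError):
    """Paired hourly series do not share the same time index."""


@dataclass(frozen=True)
class ClimateGrid:
    """One variable over the experiment's plot grid at one instant.

    ``values`` is a grid_rows x grid_cols matrix; ``measured_mask`` marks
    plots whose value came straight from a sensor (the rest are
    interpolated).  ``None`` values/mask means an empty frame (no data in
    the window at all).
    """

    experiment_id: str
    variable: str
    at: datetime
    values: Optional[np.ndarray]
    measured_mask: Optional[np.ndarray]

    @property
    def empty(self) -> bool:
        return self.values is None


def idw_weights(
    targets: np.ndarray, sources: np.ndarray, power: float = IDW_POWER
) -> np.ndarray:
    """(n_targets, n_sources) convex weight matrix: w_ij ∝ d_ij^-power,
    rows summing to 1.  A target coinciding with a source snaps to it."""
    d = np.linalg.norm(
        targets[:, None, :].astype(float) - sources[None, :, :].astype(float), axis=2
    )
    w = np.zeros_like(d)
    exact = d < 1e-12
    has_exact = exact.any(axis=1)
    w[has_exact] = exact[has_exact]
    with np.errstate(divide="ignore"):
        w[~has_exact] = d[~has_exact] ** -power
    return w / w.sum(axis=1, keepdims=True)


def _windowed_sensor_means(
    store: Store,
    experiment_id: str,
    variable: str,
    at: datetime,
    window_hours: float,
) -> tuple[list[tuple[int, int]], list[float], int, int]:
    """Per-sensor-plot mean of readings within ±window of ``at``."""
    exp = store.get_experiment(experiment_id)
    half = timedelta(hours=window_hours)
    positions, means = [], []
    for plot in store.plots_for_experiment(experiment_id):
        if plot.device_id is None:
            continue
        readings = store.readings_for(
            plot.device_id, start=at - half, end=at + half, variable=variable
        )
        if readings:
            positions.append((plot.row, plot.col))
            means.append(float(np.mean([r.value for r in readings])))
    return positions, means, exp.grid_rows, exp.grid_cols


def interpolate_plot_grid(
    store: Store,
    experiment_id: str,
    variable: str,
    at: datetime,
    window_hours: float = DEFAULT_WINDOW_HOURS,
) -> ClimateGrid:
    """Fill the whole plot grid for one variable at one instant.

    Sensor-equipped plots carry the mean of their readings within
    ±``window_hours`` of ``at``; every other plot carries the IDW
    combination of those means.  Raises :class:`NoDataError` when no
    sensor has any reading in the window.
    """
    positions, means, n_rows, n_cols = _windowed_sensor_means(
        store, experiment_id, variable, at, window_hours
    )
    if not positions:
        raise NoDataError(
            f"no {variable} readings within +/-{window_hours} h of {format_utc(at)}"
        )
    sources = np.array(positions, dtype=float)
    src_values = np.array(means)
    values = np.empty((n_rows, n_cols))
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for (r, c), v in zip(positions, means):
        values[r, c] = v
        mask[r, c] = True
    targets = np.array(
        [(r, c) for r in range(n_rows) for c in range(n_cols) if not mask[r, c]],
        dtype=float,
    )
    if len(targets):
        interp = idw_weights(targets, sources) @ src_values
        for (r, c), v in zip(targets.astype(int), interp):
            values[r, c] = v
    return ClimateGrid(experiment_id, variable, at, values, mask)


def heatmap_series(
    store: Store,
    experiment_id: str,
    variable: str,
    start: datetime,
    end: datetime,
    interval_days: int = DEFAULT_INTERVAL_DAYS,
    window_hours: float = DEFAULT_WINDOW_HOURS,
) -> list[ClimateGrid]:
    """Interpolated grids on the lattice start, start+interval, ..., end
    (inclusive when end falls on the lattice).  A 56-day span at the
    default 14-day interval yields 5 frames.  Frames with no data are kept
    as explicit empty frames rather than silently skipped."""
    if interval_days < 1:
        raise ValueError("interval_days must be a positive integer")
    if start > end:
        raise ValueError("start after end")
    frames = []
    at = start
    while at <= end:
        try:
            frames.append(
                interpolate_plot_grid(store, experiment_id, variable, at, window_hours)
            )
        except NoDataError:
            frames.append(ClimateGrid(experiment_id, variable, at, None, None))
        at += timedelta(days=interval_days)
    return frames


def loo_validation(
    store: Store,
    experiment_id: str,
    variable: str,
    at: datetime,
    window_hours: float = DEFAULT_WINDOW_HOURS,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out cross-validation of the sensor network.

    Each sensor plot is removed in turn and predicted from the rest with
    the same IDW scheme; the table reports (device, row, col, observed,
    predicted, error) and the pair's RMSE summarizes network coherence.
    """
    positions, means, _, _ = _windowed_sensor_means(
        store, experiment_id, variable, at, window_hours
    )
    if len(positions) < 2:
        raise InsufficientSensorsError(
            f"{len(positions)} sensor(s) with data; need at least 2"
        )
    plots = {
        (p.row, p.col): p.device_id
        for p in store.plots_for_experiment(experiment_id)
        if p.device_id is not None
    }
    rows = []
    pts = np.array(positions, dtype=float)
    vals = np.array(means)
    for i, (pos, observed) in enumerate(zip(positions, means)):
        others = np.delete(pts, i, axis=0)
        other_vals = np.delete(vals, i)
        predicted = float(
            (idw_weights(np.array([pos], dtype=float), others) @ other_vals)[0]
        )
        rows.append(
            {
                "device_id": plots[pos],
                "row": pos[0],
                "col": pos[1],
                "observed": observed,
                "predicted": predicted,
                "error": predicted - observed,
            }
        )
    table = pd.DataFrame(rows)
    rmse = float(np.sqrt(np.mean(table["error"] ** 2)))
    return table, rmse


# -- late-blight risk rule -------------------------------------------------


def smith_day_qualifies(hourly_temp_c: np.ndarray, hourly_rh_pct: np.ndarray) -> bool:
    """One calendar day qualifies iff its minimum temperature is >= 10 °C
    and at least 11 of its hours have RH >= 90%.  Order of hours within
    the day is irrelevant."""
    temp = np.asarray(hourly_temp_c, dtype=float)
    rh = np.asarray(hourly_rh_pct, dtype=float)
    return bool(
        temp.min() >= SMITH_MIN_TEMP_C
        and int((rh >= SMITH_RH_THRESHOLD_PCT).sum()) >= SMITH_MIN_WET_HOURS
    )


def detect_smith_periods(
    hourly_temp: pd.Series, hourly_rh: pd.Series, tz: Optional[str] = None
) -> list[RiskPeriod]:
    """Scan aligned hourly temperature (°C) and relative humidity (%)
    series for late-blight risk periods.

    Days are calendar days (in ``tz`` if given, otherwise in the series'
    own timezone/naive clock); only complete 24-hour days are considered —
    partial days are excluded with a warning.  Maximal runs of at least
    two consecutive qualifying days are returned chronologically.
    """
    if len(hourly_temp) != len(hourly_rh) or not hourly_temp.index.equals(
        hourly_rh.index
    ):
        raise AlignmentError("temperature and humidity series are not aligned")
    idx = pd.DatetimeIndex(hourly_temp.index)
    if tz is not None:
        idx = idx.tz_convert(tz) if idx.tz is not None else idx.tz_localize(tz)
    frame = pd.DataFrame(
        {"temp": hourly_temp.to_numpy(), "rh": hourly_rh.to_numpy()},
        index=idx,
    )
    qualifying_days: list[date] = []
    for day, group in frame.groupby(idx.date):
        if len(group) != 24:
            warnings.warn(
                f"excluding partial day {day} ({len(group)} of 24 hours)",
                stacklevel=2,
            )
            continue
        if smith_day_qualifies(group["temp"].to_numpy(), group["rh"].to_numpy()):
            qualifying_days.append(day)
    return runs_to_periods(sorted(qualifying_days))


def runs_to_periods(
    qualifying_days: Sequence[date], min_run_days: int = SMITH_MIN_RUN_DAYS
) -> list[RiskPeriod]:
    """Collapse a sorted list of qualifying days into maximal consecutive
    runs of at least ``min_run_days``, non-overlapping and chronological."""
    periods: list[RiskPeriod] = []
    run_start: Optional[date] = None
    prev: Optional[date] = None
    for day in qualifying_days:
        if prev is None or (day - prev).days > 1:
            if run_start is not None and (prev - run_start).days + 1 >= min_run_days:
                periods.append(RiskPeriod(run_start, prev))
            run_start = day
        prev = day
    if run_start is not None and (prev - run_start).days + 1 >= min_run_days:
        periods.append(RiskPeriod(run_start, prev))
    return periods


def sensor_correlation(series_a: pd.Series, series_b: pd.Series) -> float:
    """Pearson correlation between two sensor series over pairwise-complete
    points (used e.g. to check that soil temperature tracks ambient
    temperature).  Needs length >= 3 and nonzero variance in both."""
    joined = pd.concat([series_a, series_b], axis=1, keys=["a", "b"]).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 pairwise-complete points")
    if joined["a"].std() == 0 or joined["b"].std() == 0:
        raise ValueError("degenerate series: zero variance")
    return float(joined["a"].corr(joined["b"]))
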