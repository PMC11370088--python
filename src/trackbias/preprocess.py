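"""Path cleaning, gap interpolation, flight segmentation and classification.

A raw deployment alternates flying and non-flying (sitting on the water or
at the colony) periods.  Non-flying periods are detected from a rolling
mean ground speed and removed; the remaining contiguous runs are the
*flights* the bias analysis operates on.  Each flight is classified as
straight or sinuous from its straightness index (net great-circle
displacement over total path length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geodesy import haversine_m, step_distances_m
from .io_gps import RawPath, KMH_TO_MS


@dataclass
class Flight:
    """A contiguous flying segment at uniform nominal interval."""

    flight_id: str
    bird_id: str
    fixes: pd.DataFrame
    nominal_interval: float = 1.0
    si: float | None = None
    flight_class: str | None = None
    speed_source: str = "point_speed"

    @property
    def duration(self) -> float:
        return float(self.fixes["t"].iloc[-1] - self.fixes["t"].iloc[0])

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class ThresholdCurve:
    """Cumulative percent-below curve over candidate SI thresholds."""

    grid: np.ndarray
    percent_below: np.ndarray
    threshold: float
    degenerate: bool = False


@dataclass
class StationaryErrorSummary:
    """Cumulative movement falsely recorded by stationary loggers.

    Truth is zero displacement, so any accumulated distance is error.  Two
    estimates are compared per logger: summed great-circle displacement
    between successive fixes, and summed Doppler point speed x dt.  The
    Welch t-test is run on log-transformed per-logger totals.
    """

    per_logger: pd.DataFrame
    t_total: float
    p_total: float
    t_per_second: float
    p_per_second: float
    df_welch: float


def clean_path(path: RawPath, land_mask=None):
    """Drop duplicate-timestamp fixes (keep first) and on-land fixes.

    ``land_mask`` is a shapely polygonal geometry in lon/lat; fixes strictly
    inside it are removed.  Returns (cleaned RawPath, report dict).
    """
    df = path.fixes
    report = {"duplicate_timestamp": 0, "on_land": 0}
    dup = df["t"].duplicated(keep="first")
    report["duplicate_timestamp"] = int(dup.sum())
    df = df[~dup.to_numpy()]
    if land_mask is not None:
        import shapely

        inside = shapely.contains_xy(
            land_mask, df["lon"].to_numpy(), df["lat"].to_numpy()
        )
        report["on_land"] = int(inside.sum())
        df = df[~inside]
    if len(df) == 0:
        raise ValueError(f"path {path.bird_id!r} empty after cleaning")
    if not np.all(np.diff(df["t"].to_numpy()) > 0):
        # duplicates removed; remaining order violations are data corruption
        raise ValueError(f"timestamps not strictly increasing in {path.bird_id!r}")
    return path.copy_with(df), report


def interpolate_gaps(path: RawPath, max_gap: float = 2.0):
    """Fill 2-s gaps in a 1-s path by linear interpolation.

    Loggers intermittently drop to a 2-s interval; one fix is inserted at
    the midpoint (linear in lat, lon and point_speed).  Gaps longer than
    ``max_gap`` are left untouched and reported as flight-break markers.
    No-op for a 2-s nominal-interval deployment.
    """
    if path.nominal_interval != 1:
        return path, {"inserted": 0, "long_gaps": []}
    t = path.fixes["t"].to_numpy()
    dt = np.diff(t)
    fill = np.flatnonzero(np.isclose(dt, 2.0))
    long_gaps = [
        (float(t[i]), float(t[i + 1])) for i in np.flatnonzero(dt > max_gap)
    ]
    if len(fill) == 0:
        return path, {"inserted": 0, "long_gaps": long_gaps}
    df = path.fixes
    mids = pd.DataFrame(
        {
            col: 0.5 * (df[col].to_numpy()[fill] + df[col].to_numpy()[fill + 1])
            for col in ("t", "lat", "lon", "point_speed")
        }
    )
    out = (
        pd.concat([df, mids], ignore_index=True)
        .sort_values("t", kind="stable")
        .reset_index(drop=True)
    )
    return path.copy_with(out), {"inserted": int(len(fill)), "long_gaps": long_gaps}


def _positional_speed(df: pd.DataFrame) -> np.ndarray:
    """Per-fix speed from successive positions (m/s); last fix repeats."""
    d = step_distances_m(df["lat"].to_numpy(), df["lon"].to_numpy())
    dt = np.diff(df["t"].to_numpy())
    sp = np.empty(len(df))
    sp[:-1] = d / dt
    sp[-1] = sp[-2] if len(df) > 1 else 0.0
    return sp


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs (stop exclusive)."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def segment_flights(
    path: RawPath,
    speed_window: float = 10.0,
    speed_threshold_kmh: float = 10.0,
    min_rest: float = 60.0,
    min_flight_duration: float = 3600.0,
    speed_source: str = "auto",
):
    """Split a cleaned, gap-interpolated path into flights.

    Non-flying periods -- where the rolling mean speed over ``speed_window``
    seconds stays below ``speed_threshold_kmh`` for at least ``min_rest``
    seconds -- are removed; maximal contiguous remaining runs (also broken
    at data gaps longer than the nominal interval) become flights.  All
    flights are returned; callers doing the bias analysis keep only those
    with ``duration > min_flight_duration`` (see :func:`filter_long_flights`).

    ``speed_source``: "point_speed", "positional", or "auto" (point speed
    when present on every fix, else positional step speed).
    """
    df = path.fixes
    window_n = max(1, int(round(speed_window / path.nominal_interval)))
    if len(df) < window_n:
        warnings.warn(
            f"path {path.bird_id!r} shorter than the speed window; no flights"
        )
        return []
    if speed_source == "auto":
        speed_source = (
            "point_speed" if not df["point_speed"].isna().any() else "positional"
        )
    if speed_source == "point_speed":
        speed = df["point_speed"].to_numpy(float)
    elif speed_source == "positional":
        speed = _positional_speed(df)
    else:
        raise ValueError(f"unknown speed_source {speed_source!r}")

    rolling = (
        pd.Series(speed).rolling(window_n, center=True, min_periods=1).mean().to_numpy()
    )
    threshold_ms = speed_threshold_kmh * KMH_TO_MS
    slow = rolling < threshold_ms

    t = df["t"].to_numpy()
    non_flying = np.zeros(len(df), dtype=bool)
    for start, stop in _runs(slow):
        if t[stop - 1] - t[start] >= min_rest:
            non_flying[start:stop] = True

    # break flights at data gaps that interpolation left open
    gap_break = np.concatenate([[False], np.diff(t) > path.nominal_interval + 1e-9])

    flights = []
    for start, stop in _runs(~non_flying):
        # split the run further at gap boundaries
        bounds = [start] + [
            i for i in range(start + 1, stop) if gap_break[i]
        ] + [stop]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < 2:
                continue
            sub = df.iloc[a:b].reset_index(drop=True)
            flights.append(
                Flight(
                    flight_id=f"{path.bird_id}_f{len(flights):03d}",
                    bird_id=path.bird_id,
                    fixes=sub,
                    nominal_interval=path.nominal_interval,
                    speed_source=speed_source,
                )
            )
    return flights


def as_flight(path: RawPath, flight_id: str | None = None) -> Flight:
    """Wrap a whole path (e.g. a full foraging trip) as a single Flight.

    Used when an analysis operates on the complete trip rather than on
    segmented flying bouts (behavioural-state inference keeps rest
    periods in).
    """
    return Flight(
        flight_id=flight_id or f"{path.bird_id}_trip",
        bird_id=path.bird_id,
        fixes=path.fixes.reset_index(drop=True),
        nominal_interval=path.nominal_interval,
    )


def filter_long_flights(flights, min_flight_duration: float = 3600.0):
    """Flights exceeding the minimum duration used in the bias analysis."""
    return [f for f in flights if f.duration > min_flight_duration]


def straightness_index(flight: Flight) -> float:
    """Net great-circle displacement divided by total path length, in [0, 1]."""
    df = flight.fixes
    if len(df) < 2:
        raise ValueError("straightness index needs at least two fixes")
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    total = float(step_distances_m(lat, lon).sum())
    if total <= 0:
        raise ValueError(f"zero total distance: SI undefined for {flight.flight_id}")
    chord = float(haversine_m(lat[0], lon[0], lat[-1], lon[-1]))
    return min(chord / total, 1.0)


def select_si_threshold(flights, grid_step: float = 0.01) -> ThresholdCurve:
    """Choose the straight/sinuous SI threshold from the flight population.

    Builds the percentage of flights with SI below each candidate threshold
    on a regular grid, smooths the curve with a 5-point moving average and
    selects the knee as the grid point maximising the discrete second
    difference -- the acceleration into the steep climb through the straight
    mode.  Ties are broken toward the higher threshold, so with several
    equally sharp rises the knee sits at the base of the straightest mode
    and the spread of more sinuous flights stays below it.
    """
    if len(flights) < 2:
        raise ValueError("threshold selection needs at least two flights")
    si = np.array(
        [f.si if f.si is not None else straightness_index(f) for f in flights]
    )
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    percent = 100.0 * (si[None, :] < grid[:, None]).mean(axis=1)
    if np.allclose(si, si[0]):
        warnings.warn("all SI values equal; degenerate knee")
        return ThresholdCurve(grid, percent, float(si[0]), degenerate=True)
    smooth = pd.Series(percent).rolling(5, center=True, min_periods=1).mean().to_numpy()
    d2 = np.zeros_like(smooth)
    d2[1:-1] = smooth[2:] - 2 * smooth[1:-1] + smooth[:-2]
    knee = len(d2) - 1 - int(np.argmax(d2[::-1]))  # last maximum
    return ThresholdCurve(grid, percent, float(grid[knee]))


def classify_flights(flights, threshold: float):
    """Assign flight_class in place: SI above the threshold is straight."""
    for f in flights:
        if f.si is None:
            f.si = straightness_index(f)
        f.flight_class = "straight" if f.si > threshold else "sinuous"
    return flights


def stationary_error_summary(paths) -> StationaryErrorSummary:
    """Quantify false movement recorded by stationary loggers.

    For each logger the cumulative displacement error (summed great-circle
    distances between successive fixes) is compared with the cumulative
    point-speed error (summed point_speed x dt); truth is zero for both.
    A Welch two-sample t-test on the log-transformed totals (and on the
    per-second means) tests whether displacement error exceeds point-speed
    error.
    """
    if len(paths) < 2:
        raise ValueError("need at least two loggers per comparison arm")
    rows = []
    for p in paths:
        df = p.fixes
        t = df["t"].to_numpy()
        span = float(t[-1] - t[0])
        disp = float(step_distances_m(df["lat"].to_numpy(), df["lon"].to_numpy()).sum())
        spd = float((df["point_speed"].to_numpy()[:-1] * np.diff(t)).sum())
        for name, val in (("displacement", disp), ("point_speed", spd)):
            if val <= 0:
                raise ValueError(
                    f"zero cumulative {name} error for logger {p.bird_id!r}: "
                    "log-transform undefined"
                )
        rows.append(
            {
                "logger": p.bird_id,
                "displacement_error_m": disp,
                "point_speed_error_m": spd,
                "duration_s": span,
                "displacement_error_per_s": disp / span,
                "point_speed_error_per_s": spd / span,
            }
        )
    per_logger = pd.DataFrame(rows)

    def _welch(a, b):
        a, b = np.log(a), np.log(b)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # degenerate: both arms constant; equal means mean no effect
            t = 0.0 if np.isclose(a[0], b[0]) else np.inf
            return t, 1.0 if t == 0.0 else 0.0, float(len(a) + len(b) - 2)
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue), float(res.df)

    t_tot, p_tot, df = _welch(
        per_logger["displacement_error_m"], per_logger["point_speed_error_m"]
    )
    t_sec, p_sec, _ = _welch(
        per_logger["displacement_error_per_s"],
        per_logger["point_speed_error_per_s"],
    )
    return StationaryErrorSummary(
        per_logger=per_logger,
        t_total=t_tot,
        p_total=p_tot,
        t_per_second=t_sec,
        p_per_second=p_sec,
        df_welch=df,
    )
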