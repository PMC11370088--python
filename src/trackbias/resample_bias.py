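"""Sub-sampling bias metrics: the core computation.

A flight recorded at 1 Hz is re-expressed at a coarser sampling interval k
and compared against the native-resolution reference path F0, whose step
distances come from Doppler point speeds (free of positional measurement
error).  The comparison yields:

* PD_k -- proportional distance, total path length at interval k divided by
  the reference length D0.  PD > 1 means distance is overestimated
  (measurement error dominates, very small k), PD < 1 underestimated
  (interpolation error dominates, large k).
* PE_dist / PE_speed / PE_angle -- per-sub-sampled-point absolute
  discrepancies between the step distance / speed / relative turning angle
  at interval k and the corresponding reference-path quantities falling
  within that step's window.

Windows: reference step i spans [t_i, t_{i+1}); it belongs to sub-sampled
step j when t_i lies in [start + j*k, start + (j+1)*k).  With a uniform
1-s reference each window holds exactly k reference steps, which makes
PE_dist = k * PE_speed an exact identity.  Reference turning angles are
attributed to the interior fix where the turn happens; the sub-sampled
angle compared against window j is the turn at sub-sampled fix j+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodesy import step_distances_m, turning_angles_deg
from .preprocess import Flight


@dataclass
class ReferencePath:
    """Native-interval flight with point-speed step distances (F0)."""

    flight_id: str
    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    point_speed: np.ndarray
    dt: float
    step_dist: np.ndarray  # d0_i = point_speed_i * dt, length n-1
    turn_angle: np.ndarray  # signed degrees at interior fixes, length n-2

    @property
    def total_distance(self) -> float:
        """D0: actual path length from point speeds (m)."""
        return float(self.step_dist.sum())


@dataclass
class SubsampledFlight:
    """A flight re-expressed at interval k (F_k)."""

    flight_id: str
    k: float
    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    step_dist: np.ndarray  # great-circle, length m-1
    step_speed: np.ndarray  # step_dist / k
    turn_angle: np.ndarray  # signed degrees, length m-2

    @property
    def total_distance(self) -> float:
        return float(self.step_dist.sum())


def build_reference(flight: Flight) -> ReferencePath:
    """Construct the reference path F0 for a uniform-interval flight.

    Step distances are point_speed x dt (the Doppler proxy), turning
    angles the signed change of great-circle bearing between successive
    native steps.  Every fix must carry a point speed.
    """
    df = flight.fixes
    speed = df["point_speed"].to_numpy(float)
    missing = np.flatnonzero(np.isnan(speed))
    if len(missing) > 0:
        raise ValueError(
            f"point_speed missing at fix indices {missing[:10].tolist()} "
            f"of flight {flight.flight_id}"
        )
    t = df["t"].to_numpy(float)
    dts = np.diff(t)
    if len(dts) == 0:
        raise ValueError("reference path needs at least two fixes")
    if not np.allclose(dts, flight.nominal_interval):
        raise ValueError(
            f"flight {flight.flight_id} not uniform at {flight.nominal_interval} s"
        )
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    dt = float(flight.nominal_interval)
    return ReferencePath(
        flight_id=flight.flight_id,
        t=t,
        lat=lat,
        lon=lon,
        point_speed=speed,
        dt=dt,
        step_dist=speed[:-1] * dt,
        turn_angle=turning_angles_deg(lat, lon),
    )


def subsample(flight: Flight, k: float, snap: bool = False) -> SubsampledFlight:
    """Re-express a flight at sampling interval k seconds.

    Fix positions are taken at exact multiples of k from the flight start,
    linearly interpolated in lat/lon between the bracketing native fixes
    (``snap=True`` instead snaps to the nearest recorded fix).  Step
    distances are great-circle, speeds distance/k, turning angles signed
    bearing changes.
    """
    if k < flight.nominal_interval:
        raise ValueError(f"k={k} below the native interval")
    duration = flight.duration
    if duration < 2 * k:
        raise ValueError(
            f"k={k} leaves fewer than two steps in flight {flight.flight_id}"
        )
    df = flight.fixes
    t = df["t"].to_numpy(float)
    tk = t[0] + k * np.arange(int(np.floor(duration / k)) + 1)
    if snap:
        idx = np.searchsorted(t, tk)
        idx = np.clip(idx, 0, len(t) - 1)
        left = np.clip(idx - 1, 0, len(t) - 1)
        choose_left = np.abs(t[left] - tk) <= np.abs(t[idx] - tk)
        idx = np.where(choose_left, left, idx)
        lat = df["lat"].to_numpy()[idx]
        lon = df["lon"].to_numpy()[idx]
    else:
        lat = np.interp(tk, t, df["lat"].to_numpy())
        lon = np.interp(tk, t, df["lon"].to_numpy())
    dist = step_distances_m(lat, lon)
    return SubsampledFlight(
        flight_id=flight.flight_id,
        k=float(k),
        t=tk,
        lat=lat,
        lon=lon,
        step_dist=dist,
        step_speed=dist / k,
        turn_angle=turning_angles_deg(lat, lon),
    )


def proportional_distance(ref: ReferencePath, sub: SubsampledFlight) -> float:
    """PD_k = total sub-sampled path length / D0.

    Only the portion of the reference path covered by the sub-sampled
    fixes enters D0, so a trailing remainder shorter than k does not bias
    the ratio.
    """
    if ref.flight_id != sub.flight_id:
        raise ValueError("sub-sampled flight does not derive from this reference")
    covered = ref.t < sub.t[-1] - 1e-9  # steps starting before the last sub fix
    d0 = float(ref.step_dist[covered[:-1]].sum())
    if d0 <= 0:
        raise ValueError("reference distance D0 is zero; PD undefined")
    return sub.total_distance / d0


def point_errors(ref: ReferencePath, sub: SubsampledFlight) -> pd.DataFrame:
    """Per-sub-sampled-step discrepancies against the reference path.

    Returns one row per sub-sampled step j with absolute errors
    (pe_dist m, pe_speed m/s, pe_angle deg) and the signed distance/speed
    residuals (reference minus sub-sampled).  The angle error compares the
    mean absolute reference turn inside window j with the sub-sampled turn
    at the window's opening fix j (the turn between steps j-1 and j); the
    first window, which no sub-sampled turn opens, gets NaN.
    """
    if ref.flight_id != sub.flight_id:
        raise ValueError("sub-sampled flight does not derive from this reference")
    k = sub.k
    nsub = len(sub.step_dist)
    # window index of each reference step (by its start time)
    win = np.floor((ref.t[:-1] - sub.t[0]) / k + 1e-9).astype(int)
    valid = (win >= 0) & (win < nsub)
    if not valid.any():
        raise RuntimeError("no reference steps fall inside any window")
    d0_sum = np.bincount(win[valid], weights=ref.step_dist[valid], minlength=nsub)
    n_steps = np.bincount(win[valid], minlength=nsub)
    if (n_steps == 0).any():
        raise RuntimeError("empty reference window; intervals inconsistent")
    mean_speed = np.bincount(
        win[valid], weights=ref.point_speed[:-1][valid], minlength=nsub
    ) / n_steps

    # reference turn angles sit at interior fixes: angle i is at fix i+1,
    # time ref.t[i+1]; attribute it to the window containing that time
    if len(ref.turn_angle) > 0:
        awin = np.floor((ref.t[1:-1] - sub.t[0]) / k + 1e-9).astype(int)
        avalid = (awin >= 0) & (awin < nsub)
        a_sum = np.bincount(
            awin[avalid], weights=np.abs(ref.turn_angle[avalid]), minlength=nsub
        )
        a_n = np.bincount(awin[avalid], minlength=nsub)
        mean_abs_angle = np.divide(
            a_sum, a_n, out=np.full(nsub, np.nan), where=a_n > 0
        )
    else:
        mean_abs_angle = np.full(nsub, np.nan)

    signed_dist = d0_sum - sub.step_dist
    signed_speed = mean_speed - sub.step_speed
    # turn opening window j happens at sub fix j: sub.turn_angle[j-1]
    sub_abs_angle = np.full(nsub, np.nan)
    if len(sub.turn_angle) > 0:
        sub_abs_angle[1 : 1 + len(sub.turn_angle)] = np.abs(sub.turn_angle)
    pe_angle = np.abs(mean_abs_angle - sub_abs_angle)

    return pd.DataFrame(
        {
            "flight_id": ref.flight_id,
            "k": k,
            "j": np.arange(nsub),
            "t_start": sub.t[:-1],
            "pe_dist": np.abs(signed_dist),
            "pe_speed": np.abs(signed_speed),
            "pe_angle": pe_angle,
            "signed_dist": signed_dist,
            "signed_speed": signed_speed,
        }
    )


def default_k_grid(k_max: int = 3600, k_step: int = 1, k_min: int = 1) -> np.ndarray:
    return np.arange(k_min, k_max + 1, k_step)


def compute_bias_tables(flights, k_grid=None):
    """PD and PE tables for a set of flights over a grid of intervals.

    Returns (pd_table, pe_table): long-format DataFrames keyed by
    (flight_id, k).  Intervals too coarse for a flight (k > duration/2)
    are skipped for that flight.  The native interval of each flight sets
    the effective grid spacing (a 2-s deployment only admits even k).
    """
    pd_rows = []
    pe_parts = []
    for flight in flights:
        ref = build_reference(flight)
        grid = default_k_grid() if k_grid is None else np.asarray(k_grid)
        for k in grid:
            if k < flight.nominal_interval or k % flight.nominal_interval != 0:
                continue
            if flight.duration < 2 * k:
                continue
            sub = subsample(flight, float(k))
            pd_rows.append(
                {
                    "flight_id": flight.flight_id,
                    "bird_id": flight.bird_id,
                    "flight_class": flight.flight_class,
                    "k": float(k),
                    "pd": proportional_distance(ref, sub),
                }
            )
            pe = point_errors(ref, sub)
            pe["bird_id"] = flight.bird_id
            pe["flight_class"] = flight.flight_class
            pe_parts.append(pe)
    pd_table = pd.DataFrame(
        pd_rows, columns=["flight_id", "bird_id", "flight_class", "k", "pd"]
    )
    pe_table = (
        pd.concat(pe_parts, ignore_index=True)
        if pe_parts
        else pd.DataFrame(
            columns=[
                "flight_id", "k", "j", "t_start", "pe_dist", "pe_speed",
                "pe_angle", "signed_dist", "signed_speed", "bird_id",
                "flight_class",
            ]
        )
    )
    return pd_table, pe_table


def aggregate_bias(pd_table, pe_table, by: str = "flight_class"):
    """Mean +/- SD curves over k, grouped by flight class / species / bird.

    PD aggregates are over flights (one value per flight per k); PE
    aggregates are over pooled sub-sampled points.  Also returns summary
    scalars per group: mean PD over k > 60 s and the k maximising the mean
    angle error.
    """
    if by not in ("flight_class", "bird_id", "species"):
        raise ValueError(f"unsupported grouping {by!r}")
    pd_agg = (
        pd_table.groupby([by, "k"])["pd"]
        .agg(pd_mean="mean", pd_sd="std", n_flights="count")
        .reset_index()
    )
    pe_agg = (
        pe_table.groupby([by, "k"])[["pe_dist", "pe_speed", "pe_angle"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    pe_agg.columns = [
        "_".join(c).rstrip("_") for c in pe_agg.columns.to_flat_index()
    ]
    summaries = []
    for group, sub in pd_agg.groupby(by):
        tail = sub[sub["k"] > 60]
        angle = pe_agg[pe_agg[by] == group]
        summaries.append(
            {
                by: group,
                "mean_pd_k_gt_60": float(tail["pd_mean"].mean())
                if len(tail)
                else np.nan,
                "k_max_pe_angle": float(
                    angle.loc[angle["pe_angle_mean"].idxmax(), "k"]
                )
                if len(angle)
                else np.nan,
            }
        )
    return pd_agg, pe_agg, pd.DataFrame(summaries)


def apply_distance_bias_correction(reported_distance: float,
                                   underestimate_fraction: float) -> float:
    """Correct a coarse-interval total distance for interpolation bias.

    A trip logged at long intervals underestimates the true path length by
    a flight-mode-dependent fraction (1 - PD); the corrected estimate is
    reported x (1 + fraction).  E.g. an 11,000 km trip at hourly fixes
    becomes 12,100 km with the straight-flight 10% bias or 15,400 km with
    the sinuous 40% bias.
    """
    if underestimate_fraction < 0:
        raise ValueError("underestimate fraction must be non-negative")
    return reported_distance * (1.0 + underestimate_fraction)


def underestimate_fraction_from_pd(pd_value: float) -> float:
    """Fractional underestimate implied by a proportional distance < 1."""
    return max(0.0, 1.0 - pd_value)
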