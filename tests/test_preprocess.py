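"""Cleaning, segmentation, straightness and the stationary-logger check."""

import math

import numpy as np
import pytest
import shapely
from hypothesis import given, settings, strategies as st

from trackbias import preprocess, synthetic_data as sd
from trackbias.geodesy import EARTH_RADIUS_M
from conftest import make_flight, make_path

DEG_PER_M = math.degrees(1.0 / EARTH_RADIUS_M)
KMH = 1 / 3.6


# --- cleaning ---------------------------------------------------------------

def test_duplicate_timestamps_first_kept():
    path = make_path([0, 1, 1, 2], [0, 0, 5, 0], [0, 1e-4, 2e-4, 3e-4], 10.0)
    cleaned, report = preprocess.clean_path(path)
    assert report["duplicate_timestamp"] == 1
    assert len(cleaned) == 3
    assert cleaned.fixes["lat"].iloc[1] == 0  # first occurrence survives


def test_no_mask_means_no_land_removals():
    path = make_path(np.arange(10), np.zeros(10), 1e-4 * np.arange(10), 10.0)
    _, report = preprocess.clean_path(path)
    assert report["on_land"] == 0


def test_land_mask_removes_inside_points():
    lon = 1e-4 * np.arange(100)
    path = make_path(np.arange(100), np.zeros(100), lon, 10.0)
    # square covering exactly the 5 fixes at indices 10..14
    mask = shapely.box(lon[10] - 1e-6, -1e-3, lon[14] + 1e-6, 1e-3)
    cleaned, report = preprocess.clean_path(path, land_mask=mask)
    assert report["on_land"] == 5
    assert len(cleaned) == 95


def test_all_points_removed_is_hard_error():
    path = make_path([0, 1], [0, 0], [0, 1e-5], 10.0)
    mask = shapely.box(-1, -1, 1, 1)
    with pytest.raises(ValueError, match="empty after cleaning"):
        preprocess.clean_path(path, land_mask=mask)


# --- gap interpolation ------------------------------------------------------

def test_two_second_gap_filled_at_midpoint():
    path = make_path([0, 1, 3], [0.0, 0.0, 0.0], [0.0, 1e-4, 3e-4],
                     [10.0, 10.0, 12.0])
    filled, report = preprocess.interpolate_gaps(path)
    assert report["inserted"] == 1
    assert filled.fixes["t"].tolist() == [0, 1, 2, 3]
    assert filled.fixes["lon"].iloc[2] == pytest.approx(2e-4)
    assert filled.fixes["point_speed"].iloc[2] == pytest.approx(11.0)


def test_long_gap_left_as_break_marker():
    path = make_path([0, 300], [0, 0], [0, 1e-4], 10.0)
    filled, report = preprocess.interpolate_gaps(path)
    assert len(filled) == 2
    assert report["long_gaps"] == [(0.0, 300.0)]


def test_seeded_gappy_path_restored_to_uniform_one_second():
    noise = sd.NoiseParams(jitter_sd_m=0.0, speed_err_sd_ms=0.0, gap_prob=0.10)
    path, truth = sd.gen_track(
        sd.straight_preset(duration=2000.0, seed=42, noise=noise)
    )
    assert len(path) < len(truth)  # fixes actually dropped
    filled, _ = preprocess.interpolate_gaps(path)
    span = truth["t"].iloc[-1] - truth["t"].iloc[0]
    assert len(filled) == span + 1
    assert np.allclose(np.diff(filled.fixes["t"]), 1.0)


def test_two_second_deployment_skips_interpolation():
    path = make_path([0, 2, 4], [0, 0, 0], [0, 1e-4, 2e-4], 10.0)
    path.nominal_interval = 2.0
    filled, report = preprocess.interpolate_gaps(path)
    assert report["inserted"] == 0 and len(filled) == 3


# --- flight segmentation ----------------------------------------------------

def _speed_profile_path(speeds_ms):
    n = len(speeds_ms)
    return make_path(np.arange(n), np.zeros(n), 1e-4 * np.arange(n), speeds_ms)


def test_constant_fast_path_is_one_flight():
    path = _speed_profile_path(np.full(7200, 15 * KMH))
    flights = preprocess.segment_flights(path)
    assert len(flights) == 1
    assert flights[0].duration == 7199


def test_long_slow_period_splits_into_two_flights():
    speeds = np.concatenate(
        [np.full(600, 15 * KMH), np.full(120, 5 * KMH), np.full(600, 15 * KMH)]
    )
    flights = preprocess.segment_flights(_speed_profile_path(speeds))
    assert len(flights) == 2


def test_brief_slow_dip_does_not_split():
    speeds = np.concatenate(
        [np.full(600, 15 * KMH), np.full(30, 5 * KMH), np.full(600, 15 * KMH)]
    )
    flights = preprocess.segment_flights(_speed_profile_path(speeds))
    assert len(flights) == 1


def test_segmentation_idempotent():
    speeds = np.concatenate(
        [np.full(600, 15 * KMH), np.full(120, 5 * KMH), np.full(700, 15 * KMH)]
    )
    first = preprocess.segment_flights(_speed_profile_path(speeds))
    for flight in first:
        again = preprocess.segment_flights(
            make_path(flight.fixes["t"], flight.fixes["lat"],
                      flight.fixes["lon"], flight.fixes["point_speed"])
        )
        assert len(again) == 1
        assert again[0].fixes["t"].tolist() == flight.fixes["t"].tolist()


def test_durations_partition_the_path_span():
    speeds = np.concatenate(
        [np.full(600, 15 * KMH), np.full(120, 5 * KMH), np.full(700, 15 * KMH)]
    )
    path = _speed_profile_path(speeds)
    flights = preprocess.segment_flights(path)
    span = path.fixes["t"].iloc[-1] - path.fixes["t"].iloc[0]
    covered = sum(f.duration for f in flights)
    removed = span - covered
    # removed mass is the slow run plus at most 2 s per boundary
    assert covered + removed == span
    assert 60 <= removed <= 130


def test_short_path_warns_and_returns_nothing():
    path = _speed_profile_path(np.full(5, 15 * KMH))
    with pytest.warns(UserWarning):
        assert preprocess.segment_flights(path) == []


def test_positional_speed_fallback():
    n = 1200
    lon = np.degrees(4.17 * np.arange(n) / EARTH_RADIUS_M)  # ~15 km/h eastward
    path = make_path(np.arange(n), np.zeros(n), lon, np.nan)
    flights = preprocess.segment_flights(path, speed_source="auto")
    assert len(flights) == 1
    assert flights[0].speed_source == "positional"


# --- straightness index -----------------------------------------------------

def test_straight_path_has_si_one(straight_flight):
    assert preprocess.straightness_index(straight_flight) == pytest.approx(
        1.0, abs=1e-5
    )


def test_out_and_back_path_has_si_zero():
    lon = np.concatenate([1e-4 * np.arange(101), 1e-4 * np.arange(99, -1, -1)])
    flight = make_flight(np.arange(201), np.zeros(201), lon, 10.0)
    assert preprocess.straightness_index(flight) == pytest.approx(0.0, abs=1e-9)


def test_half_circle_si_matches_chord_over_arc():
    # v = 10 m/s, r = 200 m: half circle takes pi*200/10 ~ 62.8 s
    path, _ = sd.gen_track(sd.circle_preset(duration=63.0, radius_m=200.0))
    flight = preprocess.as_flight(path)
    si = preprocess.straightness_index(flight)
    # polygon closed form: n chords of turn delta on circumradius r'
    n, delta = 63, 10.0 / 200.0
    r_prime = (10.0 / 2) / math.sin(delta / 2)
    expected = 2 * r_prime * math.sin(n * delta / 2) / (n * 10.0)
    assert si == pytest.approx(expected, abs=1e-4)
    assert si == pytest.approx(2 / math.pi, abs=0.01)  # small-arc planar limit


def test_zero_distance_si_is_error():
    flight = make_flight([0, 1], [0, 0], [0, 0], 0.0)
    with pytest.raises(ValueError, match="undefined"):
        preprocess.straightness_index(flight)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.floats(min_value=-180, max_value=180))
def test_si_invariant_under_rotation_about_the_pole(lon_shift):
    path, _ = sd.gen_track(sd.soar_preset(duration=300.0, noise=sd.NOISE_FREE))
    flight = preprocess.as_flight(path)
    base = preprocess.straightness_index(flight)
    shifted = make_flight(
        flight.fixes["t"],
        flight.fixes["lat"],
        (flight.fixes["lon"] + lon_shift + 180) % 360 - 180,
        flight.fixes["point_speed"],
    )
    assert preprocess.straightness_index(shifted) == pytest.approx(base,
                                                                   abs=1e-9)


# --- SI threshold selection -------------------------------------------------

def _stub_flights(si_values):
    flights = []
    for i, si in enumerate(si_values):
        f = make_flight([0, 1], [0, 0], [0, 1e-4], 10.0, flight_id=f"s{i}")
        f.si = si
        flights.append(f)
    return flights


def test_bimodal_si_knee_falls_between_modes():
    flights = _stub_flights([0.2] * 50 + [0.9] * 50)
    curve = preprocess.select_si_threshold(flights)
    assert 0.2 < curve.threshold < 0.9
    preprocess.classify_flights(flights, curve.threshold)
    classes = [f.flight_class for f in flights]
    assert classes.count("sinuous") == 50 and classes.count("straight") == 50


def test_degenerate_si_population_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        curve = preprocess.select_si_threshold(_stub_flights([0.5] * 10))
    assert curve.degenerate and curve.threshold == 0.5


def test_percent_below_curve_is_monotone():
    rng = np.random.default_rng(1)
    curve = preprocess.select_si_threshold(_stub_flights(rng.random(200)))
    assert (np.diff(curve.percent_below) >= 0).all()
    assert curve.threshold in curve.grid


# --- stationary loggers -----------------------------------------------------

def test_noise_free_stationary_trips_the_log_guard():
    paths = [
        make_path(np.arange(100), np.zeros(100), np.zeros(100), 0.0,
                  bird_id=f"S{i}")
        for i in range(2)
    ]
    with pytest.raises(ValueError, match=r"S\d"):
        preprocess.stationary_error_summary(paths)


def test_identical_error_arms_give_t_zero():
    # alternate between two points 10 m apart with point speed 10 m/s:
    # displacement and point-speed totals are both exactly 100 m
    lon_step = math.degrees(10.0 / EARTH_RADIUS_M)
    lon = np.where(np.arange(11) % 2 == 0, 0.0, lon_step)
    paths = [
        make_path(np.arange(11), np.zeros(11), lon, 10.0, bird_id=f"S{i}")
        for i in range(2)
    ]
    summary = preprocess.stationary_error_summary(paths)
    assert summary.t_total == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(summary.per_logger["displacement_error_m"], 100.0)


def test_jittered_stationary_displacement_error_dominates():
    paths = sd.gen_stationary(n_loggers=10, duration=600.0, seed=7)
    summary = preprocess.stationary_error_summary(paths)
    disp = summary.per_logger["displacement_error_m"].to_numpy()
    spd = summary.per_logger["point_speed_error_m"].to_numpy()
    assert (disp > 50 * spd).all()
    assert summary.t_total > 0

    # independent Welch oracle on the log-transformed totals
    a, b = np.log(disp), np.log(spd)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t_oracle = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df_oracle = (va + vb) ** 2 / (
        va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
    )
    assert summary.t_total == pytest.approx(t_oracle, rel=1e-12)
    assert summary.df_welch == pytest.approx(df_oracle, rel=1e-12)
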