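"""Shared fixtures: small synthetic tracks with known geometry."""

import numpy as np
import pandas as pd
import pytest

from trackbias import preprocess, synthetic_data as sd
from trackbias.io_gps import RawPath
from trackbias.preprocess import Flight


def make_flight(t, lat, lon, speed, flight_id="f0", nominal_interval=1.0):
    df = pd.DataFrame(
        {
            "t": np.asarray(t, float),
            "lat": np.asarray(lat, float),
            "lon": np.asarray(lon, float),
            "point_speed": np.broadcast_to(
                np.asarray(speed, float), np.shape(t)
            ).copy(),
        }
    )
    return Flight(flight_id=flight_id, bird_id="test", fixes=df,
                  nominal_interval=nominal_interval)


def make_path(t, lat, lon, speed, bird_id="b0"):
    df = pd.DataFrame(
        {
            "t": np.asarray(t, float),
            "lat": np.asarray(lat, float),
            "lon": np.asarray(lon, float),
            "point_speed": np.broadcast_to(
                np.asarray(speed, float), np.shape(t)
            ).copy(),
        }
    )
    return RawPath(bird_id=bird_id, fixes=df)


@pytest.fixture(scope="session")
def circle_flight():
    """Noise-free circling track: r = 100 m, v = 10 m/s, 600 s."""
    path, _ = sd.gen_track(sd.circle_preset(duration=600.0))
    return preprocess.as_flight(path, "circle")


@pytest.fixture(scope="session")
def straight_flight():
    """Noise-free constant-heading track: v = 15 m/s, 2 h."""
    path, _ = sd.gen_track(
        sd.straight_preset(duration=7200.0, noise=sd.NOISE_FREE)
    )
    return preprocess.as_flight(path, "straight")


@pytest.fixture(scope="session")
def soar_flight():
    """Noise-free soaring track: A = 60 deg, T = 10 s, v = 15 m/s, 2 h."""
    path, _ = sd.gen_track(sd.soar_preset(duration=7200.0, noise=sd.NOISE_FREE))
    return preprocess.as_flight(path, "soar")


@pytest.fixture(scope="session")
def jittered_straight_flights():
    """Ten straight tracks with 5 m positional jitter, no gaps, 2 h each."""
    noise = sd.NoiseParams(jitter_sd_m=5.0, speed_err_sd_ms=0.006, gap_prob=0.0)
    flights = []
    for i in range(10):
        path, _ = sd.gen_track(
            sd.straight_preset(duration=7200.0, seed=100 + i, noise=noise,
                               bird_id=f"jit{i}")
        )
        flights.append(preprocess.as_flight(path, f"jit{i}"))
    return flights


@pytest.fixture(scope="session")
def trip():
    """Labelled 24 h foraging-trip fixture, cleaned and gap-interpolated."""
    path, truth, centers = sd.gen_trip(seed=3)
    cleaned, _ = preprocess.clean_path(path)
    filled, _ = preprocess.interpolate_gaps(cleaned)
    return preprocess.as_flight(filled), truth, centers
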