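"""Synthetic GPS tracks with the statistical structure of 1 Hz seabird data.

The generator integrates a speed/heading process on the sphere at 1 Hz and
then degrades it the way the loggers do: isotropic Gaussian positional
jitter (~5 m), near-unbiased Doppler point speeds (~0.006 m/s error scale)
and occasional fixes dropped so that ~2% of intervals stretch to 2 s.
Because the true path is a polyline whose chord lengths equal speed x dt,
the point-speed reference distance downstream recovers the true path
length exactly in the noise-free case.

Regimes
-------
straight   constant heading, constant speed (commuting flight)
soar       heading(t) = base + A sin(2 pi t / T): the continuous fine-scale
           heading oscillation of dynamic soaring
circle     constant turn rate set by radius (closed-form test geometry)
meander    area-restricted search: soaring legs flown out from and straight
           back to the bout's locale, so foraging stays in a compact patch
rest       near-zero speed with a drifting random heading (on the water)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodesy import EARTH_RADIUS_M
from .io_gps import RawPath

DEG = math.pi / 180.0


@dataclass
class NoiseParams:
    """Logger error model; defaults match low-cost 1 Hz GPS units."""

    jitter_sd_m: float = 5.0        # horizontal positional accuracy
    speed_err_sd_ms: float = 0.006  # Doppler point-speed error scale
    gap_prob: float = 0.02          # chance a fix is dropped (2-s gap)


@dataclass
class RegimeSpec:
    name: str  # straight | soar | circle | meander | rest
    duration: float  # seconds
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("regime duration must be positive")


@dataclass
class SimConfig:
    seed: int = 0
    start_lat: float = -46.9
    start_lon: float = 37.75
    start_heading: float = 45.0
    base_speed: float = 15.0
    regimes: list = field(default_factory=list)
    noise: NoiseParams = field(default_factory=NoiseParams)
    bird_id: str = "sim"
    species: str = "synthetic"


def _regime_headings_speeds(spec: RegimeSpec, base_speed, heading0, rng):
    """Per-second heading and speed arrays for one regime."""
    n = int(round(spec.duration))
    t = np.arange(n, dtype=float)
    p = spec.params
    speed = np.full(n, p.get("speed", base_speed))
    if spec.name == "straight":
        heading = np.full(n, p.get("heading", heading0))
    elif spec.name == "soar":
        amp = p.get("amplitude_deg", 60.0)
        period = p.get("period_s", 10.0)
        heading = p.get("heading", heading0) + amp * np.sin(2 * np.pi * t / period)
    elif spec.name == "circle":
        radius = p.get("radius_m", 100.0)
        sense = p.get("direction", 1.0)
        omega = sense * speed / radius / DEG  # deg per second
        heading = p.get("heading", heading0) + np.cumsum(omega) - omega
    elif spec.name == "meander":
        # area-restricted search: soaring legs flown out and straight back
        # along a freshly drawn heading, so the bout stays in a compact patch
        leg = int(round(p.get("leg_duration_s", 600.0)))
        amp = p.get("amplitude_deg", 40.0)
        period = p.get("period_s", 10.0)
        base = np.empty(n)
        out_heading = 0.0
        for j in range(int(np.ceil(n / leg))):
            if j % 2 == 0:
                out_heading = rng.uniform(0.0, 360.0)
            base[j * leg:(j + 1) * leg] = out_heading + 180.0 * (j % 2)
        heading = base + amp * np.sin(2 * np.pi * t / period)
    elif spec.name == "rest":
        base = p.get("speed", 0.3)
        speed = np.abs(base + rng.normal(0.0, 0.1 * base, n))
        heading = rng.uniform(0.0, 360.0, n)
    else:
        raise ValueError(f"unknown regime {spec.name!r}")
    return heading, speed


def _integrate_sphere(lat0, lon0, headings, speeds, dt=1.0):
    """Sequential direct great-circle stepping at interval dt."""
    n = len(headings)
    lat = np.empty(n + 1)
    lon = np.empty(n + 1)
    lat[0], lon[0] = lat0, lon0
    phi, lam = lat0 * DEG, lon0 * DEG
    for i in range(n):
        delta = speeds[i] * dt / EARTH_RADIUS_M
        theta = headings[i] * DEG
        sin_phi2 = math.sin(phi) * math.cos(delta) + math.cos(phi) * math.sin(
            delta
        ) * math.cos(theta)
        phi2 = math.asin(max(-1.0, min(1.0, sin_phi2)))
        lam2 = lam + math.atan2(
            math.sin(theta) * math.sin(delta) * math.cos(phi),
            math.cos(delta) - math.sin(phi) * sin_phi2,
        )
        phi, lam = phi2, lam2
        lat[i + 1] = phi / DEG
        lon[i + 1] = (lam / DEG + 540.0) % 360.0 - 180.0
    return lat, lon


def _apply_noise(truth: pd.DataFrame, noise: NoiseParams, rng) -> pd.DataFrame:
    """Jitter positions, perturb point speeds, drop fixes into 2-s gaps."""
    n = len(truth)
    lat = truth["lat"].to_numpy().copy()
    lon = truth["lon"].to_numpy().copy()
    if noise.jitter_sd_m > 0:
        dy = rng.normal(0.0, noise.jitter_sd_m, n)
        dx = rng.normal(0.0, noise.jitter_sd_m, n)
        lat = lat + dy / EARTH_RADIUS_M / DEG
        lon = lon + dx / (EARTH_RADIUS_M * np.cos(lat * DEG)) / DEG
    speed = truth["speed"].to_numpy()
    if noise.speed_err_sd_ms > 0:
        speed = np.clip(speed + rng.normal(0.0, noise.speed_err_sd_ms, n), 0.0, None)
    obs = pd.DataFrame(
        {"t": truth["t"].to_numpy(), "lat": lat, "lon": lon, "point_speed": speed}
    )
    if noise.gap_prob > 0 and n > 2:
        drop = rng.random(n) < noise.gap_prob
        drop[0] = drop[-1] = False
        # forbid adjacent drops so every gap is exactly 2 s
        prev = -2
        for i in np.flatnonzero(drop):
            if i - prev == 1:
                drop[i] = False
            else:
                prev = i
        obs = obs[~drop].reset_index(drop=True)
    return obs


def gen_track(config: SimConfig):
    """Generate one track from a regime schedule.

    Returns (RawPath of observed fixes, truth DataFrame with columns
    t, lat, lon, speed, heading, regime).  Pure function of (config, seed).
    """
    if not config.regimes:
        raise ValueError("config.regimes is empty")
    rng = np.random.default_rng(config.seed)
    headings, speeds, regimes = [], [], []
    heading0 = config.start_heading
    for spec in config.regimes:
        h, s = _regime_headings_speeds(spec, config.base_speed, heading0, rng)
        headings.append(h)
        speeds.append(s)
        regimes.extend([spec.name] * len(h))
        if spec.name != "rest":
            heading0 = float(h[-1]) % 360.0
    headings = np.concatenate(headings)
    speeds = np.concatenate(speeds)
    lat, lon = _integrate_sphere(config.start_lat, config.start_lon, headings, speeds)
    n = len(headings)
    truth = pd.DataFrame(
        {
            "t": np.arange(n + 1, dtype=float),
            "lat": lat,
            "lon": lon,
            # speed/heading of the step *leaving* each fix; last repeats
            "speed": np.append(speeds, speeds[-1]),
            "heading": np.append(headings, headings[-1]),
            "regime": regimes + [regimes[-1]],
        }
    )
    obs = _apply_noise(truth, config.noise, rng)
    path = RawPath(
        bird_id=config.bird_id, fixes=obs, species=config.species,
        nominal_interval=1.0,
    )
    return path, truth


# ---------------------------------------------------------------------------
# presets

NOISE_FREE = NoiseParams(jitter_sd_m=0.0, speed_err_sd_ms=0.0, gap_prob=0.0)


def straight_preset(duration=7200.0, speed=15.0, seed=0, noise=None, **kw):
    """Constant-heading commuting flight."""
    return SimConfig(
        seed=seed,
        base_speed=speed,
        regimes=[RegimeSpec("straight", duration)],
        noise=noise if noise is not None else NoiseParams(),
        bird_id=kw.pop("bird_id", "straight"),
        **kw,
    )


def circle_preset(duration=600.0, speed=10.0, radius_m=100.0, seed=0, noise=None,
                  **kw):
    """Constant-turn-rate circling; closed-form chord/arc test geometry."""
    return SimConfig(
        seed=seed,
        base_speed=speed,
        regimes=[RegimeSpec("circle", duration, {"radius_m": radius_m})],
        noise=noise if noise is not None else NOISE_FREE,
        bird_id=kw.pop("bird_id", "circle"),
        **kw,
    )


def soar_preset(duration=7200.0, speed=15.0, amplitude_deg=60.0, period_s=10.0,
                seed=0, noise=None, **kw):
    """Dynamic-soaring flight: sinusoidally oscillating heading."""
    return SimConfig(
        seed=seed,
        base_speed=speed,
        regimes=[
            RegimeSpec(
                "soar",
                duration,
                {"amplitude_deg": amplitude_deg, "period_s": period_s},
            )
        ],
        noise=noise if noise is not None else NoiseParams(),
        bird_id=kw.pop("bird_id", "soar"),
        **kw,
    )


def gen_stationary(n_loggers=10, duration=43200.0, noise=None, seed=0,
                   lat=-46.9, lon=37.75):
    """Stationary-logger trial: fixed true position, observed noise only.

    Emulates leaving loggers outside for ~12 h; per-logger truth is zero
    displacement, so everything downstream measures pure error.
    """
    if n_loggers < 2:
        raise ValueError("need at least two loggers")
    noise = noise if noise is not None else NoiseParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration)) + 1
    paths = []
    for i in range(n_loggers):
        truth = pd.DataFrame(
            {
                "t": np.arange(n, dtype=float),
                "lat": np.full(n, lat),
                "lon": np.full(n, lon),
                "speed": np.zeros(n),
            }
        )
        sub_rng = np.random.default_rng(rng.integers(2**31))
        obs = _apply_noise(truth, noise, sub_rng)
        # stationary point speed error is a magnitude: fold negatives
        obs["point_speed"] = np.abs(
            sub_rng.normal(0.0, noise.speed_err_sd_ms, len(obs))
        )
        paths.append(
            RawPath(bird_id=f"S{i + 1}", fixes=obs, species="stationary")
        )
    return paths


REGIME_TO_STATE = {
    "straight": "commute",
    "soar": "forage",
    "meander": "forage",
    "circle": "forage",
    "rest": "rest",
}


def trip_schedule(commute_h=4.0, patch_forage_h=6.0, patch_rest_h=1.0,
                  speed_commute=15.0, speed_forage=8.0):
    """Central-place foraging trip: out, two foraging patches, back.

    Foraging bouts are out-and-back soaring legs (area-restricted search)
    that keep the bird within a few km of where the bout starts; patches
    are therefore geographically fixed by the commute legs between them.
    """
    half_forage = patch_forage_h * 1800.0  # half a bout, seconds
    return [
        RegimeSpec("rest", 1800.0),
        RegimeSpec("straight", commute_h * 3600.0, {"heading": 45.0,
                                                    "speed": speed_commute}),
        RegimeSpec("meander", half_forage, {"speed": speed_forage}),
        RegimeSpec("rest", patch_rest_h * 3600.0),
        RegimeSpec("meander", half_forage, {"speed": speed_forage}),
        RegimeSpec("straight", 3600.0, {"heading": 135.0,
                                        "speed": speed_commute}),
        RegimeSpec("meander", half_forage, {"speed": speed_forage}),
        RegimeSpec("rest", patch_rest_h * 3600.0),
        RegimeSpec("meander", half_forage, {"speed": speed_forage}),
        RegimeSpec("straight", commute_h * 3600.0, {"heading": 260.0,
                                                    "speed": speed_commute}),
        RegimeSpec("rest", 1800.0),
    ]


def gen_trip(seed=0, noise=None, schedule=None, **config_kw):
    """Labelled full foraging trip (>= 24 h at 1 Hz) for state inference.

    Returns (RawPath, truth DataFrame with a ``state`` column, patch
    centres).  Patch centres are the true mid-bout positions of each
    foraging patch, giving kernel tests a known geography.
    """
    cfg = SimConfig(
        seed=seed,
        regimes=schedule if schedule is not None else trip_schedule(),
        noise=noise if noise is not None else NoiseParams(),
        bird_id=config_kw.pop("bird_id", "trip"),
        **config_kw,
    )
    path, truth = gen_track(cfg)
    truth["state"] = truth["regime"].map(REGIME_TO_STATE)
    # a patch = maximal run of forage/rest between commute legs
    is_patch = (truth["state"] != "commute").to_numpy()
    forage = (truth["state"] == "forage").to_numpy()
    edges = np.flatnonzero(np.diff(np.concatenate([[0], is_patch.astype(int), [0]])))
    centers = []
    for a, b in zip(edges[::2], edges[1::2]):
        idx = np.flatnonzero(forage[a:b])
        if len(idx) == 0:
            continue  # rest-only bouts (trip endpoints) are not patches
        mid = a + idx[len(idx) // 2]
        centers.append((float(truth["lat"].iloc[mid]), float(truth["lon"].iloc[mid])))
    return path, truth, centers


def gen_state_series(n=2000, seed=0, means=None, sds=None, self_prob=0.95):
    """Draw (speed, |turn angle|) observations from a 3-state Markov chain.

    Defaults: rest 0.5 m/s / 5 deg, forage 8 m/s / 60 deg, commute
    15 m/s / 8 deg, with sticky (0.95 self-probability) transitions --
    a separable regime mixture for testing state-inference recovery.
    Emissions are the raw Gaussians (occasionally negative at these SDs),
    matching the fitted observation model exactly so recovered means are
    comparable to the generating ones.  Returns (obs array (n, 2), true
    state indices).
    """
    means = np.asarray(
        means if means is not None else [[0.5, 5.0], [8.0, 60.0], [15.0, 8.0]]
    )
    sds = np.asarray(
        sds if sds is not None else [[0.3, 5.0], [2.0, 20.0], [2.0, 5.0]]
    )
    n_states = len(means)
    rng = np.random.default_rng(seed)
    off = (1.0 - self_prob) / (n_states - 1)
    transmat = np.full((n_states, n_states), off)
    np.fill_diagonal(transmat, self_prob)
    states = np.empty(n, dtype=int)
    states[0] = rng.integers(n_states)
    for i in range(1, n):
        states[i] = rng.choice(n_states, p=transmat[states[i - 1]])
    obs = rng.normal(means[states], sds[states])
    return obs, states
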