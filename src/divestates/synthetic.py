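"""Synthetic dive sequences, depth traces and Argos-like tracks with known truth.

The generator emulates the data a transmitting time-depth recorder on a
pelagic sea turtle produces: a first-order Markov chain over four behavioural
states, per-state right-skewed (lognormal) distributions of maximum depth,
bottom time, dive time and post-dive surface interval, rendering to
continuous depth traces with trapezoidal descent/bottom/ascent geometry,
linear sensor drift, point resampling to a coarse interval, and satellite
location fixes salted with near-duplicates, invalid (class Z) records and
speed-spike outliers.  Ground-truth labels are retained throughout so every
downstream stage can be scored against what was generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError
from .tdr import DepthSeries

__all__ = [
    "SimConfig",
    "LabeledDive",
    "default_sim_config",
    "simulate_dive_sequence",
    "render_depth_series",
    "add_sensor_drift",
    "resample_series",
    "simulate_argos_track",
    "dives_to_truth_frame",
]

FEATURE_NAMES = ("max_depth", "bottom_fraction", "dive_time", "surface_interval")


@dataclass
class SimConfig:
    """Generative configuration for labelled dive sequences.

    ``state_params[k]`` maps each of max_depth (m), bottom_fraction (of dive
    time), dive_time (s) and surface_interval (s) to a (log-mean, log-sd)
    pair; draws are lognormal, with bottom_fraction clipped below 0.95 so a
    dive always has some descent/ascent.  ``season_amplitude`` multiplies the
    transition-probability column of each state by
    ``1 + a_k * cos(2*pi*(month - peak_month_k)/12)`` (rows renormalised),
    modulating monthly occupancy; zero amplitudes give a homogeneous chain.
    """

    n_states: int = 4
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    A: np.ndarray = field(default_factory=lambda: np.full((4, 4), 0.25))
    state_params: list[dict[str, tuple[float, float]]] = field(default_factory=list)
    season_amplitude: np.ndarray = field(default_factory=lambda: np.zeros(4))
    season_peak_month: np.ndarray = field(default_factory=lambda: np.array([1.0, 10.0, 7.0, 4.0]))
    drift_m_per_day: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.pi.shape != (self.n_states,):
            raise ConfigurationError("pi must have length n_states")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ConfigurationError("pi must sum to 1 within 1e-12")
        if self.A.shape != (self.n_states, self.n_states):
            raise ConfigurationError("A must be n_states x n_states")
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigurationError("every row of A must sum to 1 within 1e-12")
        if len(self.state_params) != self.n_states:
            raise ConfigurationError("state_params must have one entry per state")
        for k, params in enumerate(self.state_params):
            for name in FEATURE_NAMES:
                if name not in params:
                    raise ConfigurationError(f"state {k + 1} missing parameter {name}")
                mu, sd = params[name]
                if sd <= 0:
                    raise ConfigurationError(f"state {k + 1} {name}: sd must be > 0")
            fmu = math.exp(params["bottom_fraction"][0])
            if not 0.0 <= fmu < 1.0:
                raise ConfigurationError(
                    f"state {k + 1}: bottom fraction median must be in [0, 1)"
                )

    # -- YAML round trip (CLI configs) ------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_states": self.n_states,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "state_params": [
                {k: list(v) for k, v in p.items()} for p in self.state_params
            ],
            "season_amplitude": np.asarray(self.season_amplitude).tolist(),
            "season_peak_month": np.asarray(self.season_peak_month).tolist(),
            "drift_m_per_day": self.drift_m_per_day,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["pi"] = np.asarray(doc["pi"], dtype=float)
        doc["A"] = np.asarray(doc["A"], dtype=float)
        doc["season_amplitude"] = np.asarray(doc["season_amplitude"], dtype=float)
        doc["season_peak_month"] = np.asarray(doc["season_peak_month"], dtype=float)
        doc["state_params"] = [
            {k: tuple(v) for k, v in p.items()} for p in doc["state_params"]
        ]
        cfg = cls(**doc)
        cfg.validate()
        return cfg


@dataclass
class LabeledDive:
    """Ground-truth twin of a dive feature vector."""

    state: int  # 1..n_states
    start_time: float  # s since epoch
    max_depth: float  # m
    dive_time: float  # s
    bottom_time: float  # s
    surface_interval: float  # s (post-dive)

    def __post_init__(self) -> None:
        if self.bottom_time > self.dive_time:
            raise ConfigurationError("bottom_time must not exceed dive_time")
        if self.max_depth <= 0:
            raise ConfigurationError("max_depth must be positive")
        if self.surface_interval < 0:
            raise ConfigurationError("surface_interval must be non-negative")

    @property
    def end_time(self) -> float:
        return self.start_time + self.dive_time


def _ln(x: float) -> float:
    return math.log(x)


def default_sim_config(seed: int = 0) -> SimConfig:
    """Four states mimicking the qualitative descriptors of loggerhead dive modes.

    State 1: intermediate depth, longest bottom and dive time, short surface
    interval (resting).  State 2: deepest, intermediate bottom time, long
    surface interval (deep exploratory).  State 3: intermediate depth, least
    bottom time, shortest dive, longest surface interval (mid-water
    foraging).  State 4: shallowest, shortest surface interval.  The
    transition matrix is strongly diagonal (states are persistent) and the
    initial distribution favours state 3.
    """
    A = np.array(
        [
            [0.833, 0.042, 0.052, 0.072],
            [0.025, 0.804, 0.104, 0.068],
            [0.023, 0.108, 0.781, 0.088],
            [0.072, 0.112, 0.163, 0.652],
        ]
    )
    A /= A.sum(axis=1, keepdims=True)
    pi = np.array([0.048, 0.081, 0.601, 0.270])
    pi /= pi.sum()
    state_params = [
        {  # state 1: resting
            "max_depth": (_ln(30.0), 0.35),
            "bottom_fraction": (_ln(0.65), 0.15),
            "dive_time": (_ln(4200.0), 0.35),
            "surface_interval": (_ln(150.0), 0.40),
        },
        {  # state 2: deep exploratory
            "max_depth": (_ln(90.0), 0.35),
            "bottom_fraction": (_ln(0.30), 0.25),
            "dive_time": (_ln(2100.0), 0.30),
            "surface_interval": (_ln(1200.0), 0.50),
        },
        {  # state 3: mid-water foraging
            "max_depth": (_ln(35.0), 0.30),
            "bottom_fraction": (_ln(0.12), 0.30),
            "dive_time": (_ln(1000.0), 0.30),
            "surface_interval": (_ln(2400.0), 0.50),
        },
        {  # state 4: shallow
            "max_depth": (_ln(16.0), 0.25),
            "bottom_fraction": (_ln(0.40), 0.25),
            "dive_time": (_ln(1500.0), 0.30),
            "surface_interval": (_ln(70.0), 0.35),
        },
    ]
    cfg = SimConfig(pi=pi, A=A, state_params=state_params, seed=seed)
    cfg.validate()
    return cfg


def _month_of(t: float) -> int:
    return datetime.fromtimestamp(t, tz=timezone.utc).month


def _seasonal_weights(cfg: SimConfig, month: int) -> np.ndarray:
    amp = np.asarray(cfg.season_amplitude, dtype=float)
    peak = np.asarray(cfg.season_peak_month, dtype=float)
    w = 1.0 + amp * np.cos(2.0 * np.pi * (month - peak) / 12.0)
    return np.clip(w, 1e-3, None)


def simulate_dive_sequence(
    cfg: SimConfig, n_dives: int, start_time: float = 0.0
) -> list[LabeledDive]:
    """Draw a labelled dive sequence from the configured Markov chain.

    States follow (pi, A) — seasonally reweighted when amplitudes are nonzero
    — metrics are lognormal per state, and start times accumulate dive time
    plus surface interval.  Deterministic under ``cfg.seed``.
    """
    if n_dives < 1:
        raise ConfigurationError("n_dives must be >= 1")
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = float(start_time)
    dives: list[LabeledDive] = []
    state = -1
    for i in range(n_dives):
        month = _month_of(t)
        if i == 0:
            p = cfg.pi
        else:
            p = cfg.A[state]
        if np.any(np.asarray(cfg.season_amplitude) != 0.0):
            p = p * _seasonal_weights(cfg, month)
            p = p / p.sum()
        state = int(rng.choice(cfg.n_states, p=p))
        params = cfg.state_params[state]
        depth = float(rng.lognormal(*params["max_depth"]))
        frac = min(float(rng.lognormal(*params["bottom_fraction"])), 0.95)
        dive_time = float(rng.lognormal(*params["dive_time"]))
        surf = float(rng.lognormal(*params["surface_interval"]))
        dives.append(
            LabeledDive(
                state=state + 1,
                start_time=t,
                max_depth=depth,
                dive_time=dive_time,
                bottom_time=frac * dive_time,
                surface_interval=surf,
            )
        )
        t += dive_time + surf
    return dives


def render_depth_series(
    dives: list[LabeledDive],
    dt: float,
    t_start: float | None = None,
    t_end: float | None = None,
    individual_id: str = "sim",
) -> DepthSeries:
    """Render dives as a continuous trapezoidal depth trace sampled every ``dt``.

    Each dive descends linearly to its maximum depth, holds it, and ascends
    linearly back to the surface; the hold is sized so that the time spent
    deeper than 80 % of the maximum depth equals the dive's bottom time (a
    pure vee when the bottom time is shorter than the descent/ascent
    contribution).  Depth is zero during surface intervals.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if t_start is None:
        if not dives:
            raise InputError("empty dive list needs an explicit t_start/t_end span")
        t_start = dives[0].start_time - dt
    if t_end is None:
        if not dives:
            raise InputError("empty dive list needs an explicit t_start/t_end span")
        last = dives[-1]
        t_end = last.end_time + max(last.surface_interval, dt)
    n = int(np.floor((t_end - t_start) / dt)) + 1
    times = t_start + np.arange(n) * dt
    depths = np.zeros(n)
    prev_end = -np.inf
    for dv in dives:
        if dv.start_time < prev_end - 1e-9:
            raise InputError(
                f"dives overlap in time at t={dv.start_time:.1f}"
            )
        prev_end = dv.end_time
        # hold H sized so hold + 0.2 * (descent + ascent) = bottom_time
        hold = max(0.0, (dv.bottom_time - 0.2 * dv.dive_time) / 0.8)
        ramp = (dv.dive_time - hold) / 2.0
        xs = np.array(
            [dv.start_time, dv.start_time + ramp, dv.start_time + ramp + hold, dv.end_time]
        )
        ys = np.array([0.0, dv.max_depth, dv.max_depth, 0.0])
        lo = int(np.searchsorted(times, dv.start_time, side="left"))
        hi = int(np.searchsorted(times, dv.end_time, side="right"))
        if hi > lo:
            depths[lo:hi] = np.interp(times[lo:hi], xs, ys)
    return DepthSeries(times, depths, dt, individual_id=individual_id)


def add_sensor_drift(series: DepthSeries, rate_m_per_day: float) -> DepthSeries:
    """Add linear sensor drift: depth(t) += rate * (t - t0) / 86400."""
    if len(series) == 0:
        raise InputError("series must be non-empty")
    drift = rate_m_per_day * (series.times - series.times[0]) / 86400.0
    return replace(series, depths=series.depths + drift)


def resample_series(series: DepthSeries, interval: float) -> DepthSeries:
    """Point-sample the series every ``interval`` seconds (no averaging).

    Each grid time t0, t0+interval, ... takes the nearest native reading at
    or before it, emulating a tag that reports instantaneous depth per
    transmission slot.
    """
    if interval < series.nominal_dt:
        raise InputError("resampling interval is smaller than the native step")
    t0, t1 = series.times[0], series.times[-1]
    grid = t0 + np.arange(int(np.floor((t1 - t0) / interval)) + 1) * interval
    idx = np.searchsorted(series.times, grid + 1e-9, side="right") - 1
    return DepthSeries(
        grid, series.depths[idx], interval, individual_id=series.individual_id
    )


# ---------------------------------------------------------------------------
# Argos track simulation

_LC_CLEAN = np.array(["3", "2", "1", "0", "A", "B"])
_KM_PER_DEG = 111.32


def simulate_argos_track(
    seed: int,
    n_fixes: int,
    duplicate_rate: float = 0.0,
    z_rate: float = 0.0,
    outlier_rate: float = 0.0,
    fix_interval_s: float = 7200.0,
    speed_kmh: float = 2.0,
    start_lon: float = 3.0,
    start_lat: float = 39.0,
    start_time: float = 0.0,
    individual_id: str = "sim",
) -> pd.DataFrame:
    """Simulate a smooth surface track plus labelled contaminants.

    The base trajectory is a correlated-heading random walk at ``speed_kmh``.
    Near-duplicate fixes (within 2 min of a base fix), class-Z records and
    spike outliers (displaced far enough to imply > 5 km/h both ways) are
    injected at the given per-fix rates; the ``injected`` column records the
    ground-truth label ('' for base fixes).
    """
    if n_fixes < 2:
        raise ConfigurationError("n_fixes must be >= 2")
    rng = np.random.default_rng(seed)
    heading = rng.uniform(0, 2 * np.pi)
    lon = np.empty(n_fixes)
    lat = np.empty(n_fixes)
    lon[0], lat[0] = start_lon, start_lat
    step_km = speed_kmh * fix_interval_s / 3600.0
    for i in range(1, n_fixes):
        heading += rng.normal(0.0, np.deg2rad(8.0))
        lat[i] = lat[i - 1] + step_km * np.cos(heading) / _KM_PER_DEG
        lon[i] = lon[i - 1] + step_km * np.sin(heading) / (
            _KM_PER_DEG * np.cos(np.deg2rad(lat[i - 1]))
        )
    times = start_time + np.arange(n_fixes) * fix_interval_s
    base = pd.DataFrame(
        {
            "id": individual_id,
            "time": times,
            "lon": lon,
            "lat": lat,
            "lc": rng.choice(_LC_CLEAN, size=n_fixes),
            "injected": "",
        }
    )
    extras = []
    n_dup = int(round(duplicate_rate * n_fixes))
    if n_dup:
        picks = rng.choice(n_fixes, size=n_dup, replace=False)
        for p in picks:
            extras.append(
                {
                    "id": individual_id,
                    "time": times[p] + rng.uniform(10.0, 118.0),
                    "lon": lon[p] + rng.normal(0, 1e-3),
                    "lat": lat[p] + rng.normal(0, 1e-3),
                    "lc": str(rng.choice(_LC_CLEAN)),
                    "injected": "duplicate",
                }
            )
    n_z = int(round(z_rate * n_fixes))
    if n_z:
        picks = rng.choice(n_fixes - 1, size=n_z, replace=False)
        for p in picks:
            extras.append(
                {
                    "id": individual_id,
                    "time": times[p] + fix_interval_s * rng.uniform(0.3, 0.7),
                    "lon": lon[p] + rng.normal(0, 0.05),
                    "lat": lat[p] + rng.normal(0, 0.05),
                    "lc": "Z",
                    "injected": "z",
                }
            )
    n_out = int(round(outlier_rate * n_fixes))
    if n_out:
        picks = rng.choice(np.arange(1, n_fixes - 1), size=n_out, replace=False)
        # displacement implying well over 5 km/h to both neighbours
        d_km = 4.0 * 5.0 * fix_interval_s / 3600.0 + 20.0
        for p in picks:
            ang = rng.uniform(0, 2 * np.pi)
            extras.append(
                {
                    "id": individual_id,
                    "time": times[p] + fix_interval_s * 0.5,
                    "lon": lon[p]
                    + d_km * np.sin(ang) / (_KM_PER_DEG * np.cos(np.deg2rad(lat[p]))),
                    "lat": lat[p] + d_km * np.cos(ang) / _KM_PER_DEG,
                    "lc": str(rng.choice(_LC_CLEAN)),
                    "injected": "spike",
                }
            )
    track = pd.concat([base, pd.DataFrame(extras)], ignore_index=True) if extras else base
    track = track.sort_values("time", kind="stable").reset_index(drop=True)
    return track


def dives_to_truth_frame(dives: list[LabeledDive]) -> pd.DataFrame:
    """Ground-truth sidecar: one row per generated dive."""
    return pd.DataFrame(
        {
            "state": [d.state for d in dives],
            "start_time": [d.start_time for d in dives],
            "end_time": [d.end_time for d in dives],
            "max_depth": [d.max_depth for d in dives],
            "dive_time": [d.dive_time for d in dives],
            "bottom_time": [d.bottom_time for d in dives],
            "surface_interval": [d.surface_interval for d in dives],
        }
    )
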