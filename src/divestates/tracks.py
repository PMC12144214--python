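"""Argos surface-track cleaning and joining of track attributes to dives.

The cleaning pipeline mirrors standard telemetry practice for Argos data:
near-duplicate removal (fixes within 2 min of the previously retained fix),
a speed/distance/angle filter (class Z dropped outright, then implausible
speeds > 5 km/h and sharp spike vertices removed iteratively), splitting
tracks into independent trips at gaps exceeding 7 days, and a per-individual
median split of an externally supplied move-persistence index g in [0, 1]
into localised (g < median) versus transiting (g >= median) movement.
Distances are haversine on a spherical Earth (R = 6371 km).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "FilterConfig",
    "Trip",
    "haversine_km",
    "remove_near_duplicates",
    "sda_filter",
    "split_trips",
    "classify_move_persistence",
    "link_dives_to_track",
    "read_argos_csv",
]

_EARTH_RADIUS_KM = 6371.0


@dataclass
class FilterConfig:
    duplicate_window: float = 120.0  # s
    vmax: float = 5.0  # km/h
    spike_angles: tuple[float, float] = (15.0, 25.0)  # degrees
    spike_lengths: tuple[float, float] = (2.5, 5.0)  # km
    max_gap_days: float = 7.0

    def __post_init__(self) -> None:
        if self.vmax <= 0:
            raise ConfigurationError("vmax must be positive")
        if not self.spike_angles[0] < self.spike_angles[1]:
            raise ConfigurationError("spike_angles must be ascending")
        if not self.spike_lengths[0] < self.spike_lengths[1]:
            raise ConfigurationError("spike_lengths must be ascending")


@dataclass
class Trip:
    """A contiguous track segment with no internal gap over ``max_gap_days``."""

    individual_id: str
    fixes: pd.DataFrame  # time-ordered; columns time, lon, lat, lc [, g, mp_class]


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _check_sorted(df: pd.DataFrame) -> None:
    for _, grp in df.groupby("id", sort=False):
        if np.any(np.diff(grp["time"].to_numpy()) < 0):
            raise InputError("fixes must be time-sorted within each individual")


def remove_near_duplicates(fixes: pd.DataFrame, window: float = 120.0) -> pd.DataFrame:
    """Drop fixes within ``window`` seconds of the previously retained fix.

    Applied per individual; the first fix is always kept.
    """
    _check_sorted(fixes)
    keep_idx = []
    for _, grp in fixes.groupby("id", sort=False):
        t = grp["time"].to_numpy()
        last = -np.inf
        for row_i, ti in zip(grp.index, t):
            if ti - last > window:
                keep_idx.append(row_i)
                last = ti
    return fixes.loc[keep_idx].reset_index(drop=True)


def _speeds_kmh(t, lon, lat):
    d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dt_h = np.diff(t) / 3600.0
    with np.errstate(divide="ignore"):
        return np.where(dt_h > 0, d / dt_h, np.inf)


def _internal_angle_deg(lon, lat, i):
    """Internal angle at vertex i of the polyline (180 = straight, 0 = doubling back)."""
    d1 = haversine_km(lon[i - 1], lat[i - 1], lon[i], lat[i])
    d2 = haversine_km(lon[i], lat[i], lon[i + 1], lat[i + 1])
    d3 = haversine_km(lon[i - 1], lat[i - 1], lon[i + 1], lat[i + 1])
    if d1 == 0 or d2 == 0:
        return 180.0, d1, d2
    c = (d1**2 + d2**2 - d3**2) / (2.0 * d1 * d2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))), d1, d2


def _sda_one(grp: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    nz = grp[grp["lc"].astype(str) != "Z"]
    if len(nz) < 3:
        warnings.warn(
            f"fewer than 3 fixes after class-Z removal for {grp['id'].iloc[0]}; "
            "returned unfiltered",
            stacklevel=3,
        )
        return nz
    t = nz["time"].to_numpy(float)
    lon = nz["lon"].to_numpy(float)
    lat = nz["lat"].to_numpy(float)
    alive = np.ones(len(nz), dtype=bool)
    a_lo, a_hi = cfg.spike_angles
    l_lo, l_hi = cfg.spike_lengths
    changed = True
    while changed:
        changed = False
        # speed pass: remove the interior fix with the worst implied speed
        while True:
            idx = np.flatnonzero(alive)
            if idx.size < 3:
                break
            v = _speeds_kmh(t[idx], lon[idx], lat[idx])
            worst, worst_rank = -1, -1.0
            for j in range(1, idx.size - 1):
                vin, vout = v[j - 1], v[j]
                if max(vin, vout) <= cfg.vmax:
                    continue
                # rank by the mean of in/out speeds so a true spike (fast both
                # ways) outranks its innocent neighbours (fast one way only)
                rank = 0.5 * (vin + vout)
                if rank >= worst_rank:  # >= removes the later fix on ties
                    worst, worst_rank = j, rank
            if worst < 0:
                break
            alive[idx[worst]] = False
            changed = True
        # angle pass: remove the sharpest qualifying spike vertex
        while True:
            idx = np.flatnonzero(alive)
            if idx.size < 3:
                break
            worst, worst_a = -1, 360.0
            for j in range(1, idx.size - 1):
                ang, d1, d2 = _internal_angle_deg(lon[idx], lat[idx], j)
                if (ang < a_lo and d1 > l_lo and d2 > l_lo) or (
                    ang < a_hi and d1 > l_hi and d2 > l_hi
                ):
                    if ang <= worst_a:  # <= keeps the later fix on ties
                        worst, worst_a = j, ang
            if worst < 0:
                break
            alive[idx[worst]] = False
            changed = True
    return nz[alive]


def sda_filter(fixes: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Speed/distance/angle filter on deduplicated, sorted fixes.

    Class-Z fixes are removed first.  Then, iteratively to a fixed point:
    interior fixes implying a great-circle speed above ``vmax`` to a retained
    neighbour are removed (worst first); spike vertices with an internal
    turning angle below 15 deg whose adjacent segments both exceed 2.5 km, or
    below 25 deg with both segments over 5 km, are removed.  The first and
    last fix are never removed except as class Z, and the output is a
    subsequence of the input.
    """
    cfg = cfg or FilterConfig()
    _check_sorted(fixes)
    parts = [_sda_one(grp, cfg) for _, grp in fixes.groupby("id", sort=False)]
    return pd.concat(parts, ignore_index=True) if parts else fixes.iloc[0:0]


def split_trips(fixes: pd.DataFrame, max_gap_days: float = 7.0) -> list[Trip]:
    """Cut tracks into trips between fixes separated by strictly more than the gap."""
    _check_sorted(fixes)
    trips: list[Trip] = []
    gap_s = max_gap_days * 86400.0
    for ind, grp in fixes.groupby("id", sort=False):
        t = grp["time"].to_numpy(float)
        cuts = np.flatnonzero(np.diff(t) > gap_s) + 1
        for n, part in enumerate(np.split(np.arange(len(grp)), cuts)):
            trips.append(
                Trip(
                    individual_id=f"{ind}" if n == 0 and cuts.size == 0 else f"{ind}#{n}",
                    fixes=grp.iloc[part].reset_index(drop=True),
                )
            )
    return trips


def classify_move_persistence(fixes: pd.DataFrame) -> pd.DataFrame:
    """Label each fix localised/transiting by the individual's median g.

    Per individual, the median g is the threshold: g below it is localised
    movement, g at or above it transiting.
    """
    if "g" not in fixes.columns or fixes["g"].isna().any():
        raise InputError("move-persistence g must be present on every fix")
    out = fixes.copy()
    med = out.groupby("id")["g"].transform("median")
    out["mp_class"] = np.where(out["g"] < med, "localised", "transiting")
    return out


def link_dives_to_track(
    dives: pd.DataFrame,
    track: pd.DataFrame,
    tolerance_s: float = 3600.0,
) -> pd.DataFrame:
    """Join each dive to its nearest-in-time fix within a tolerance.

    The default tolerance (1 h) is half the 2 h regularisation interval of
    the location series; dives with no fix in tolerance get null attributes.
    """
    cols = [c for c in ("lon", "lat", "g", "mp_class") if c in track.columns]
    dv = dives.sort_values("start_time", kind="stable").reset_index(drop=True)
    tr = track.sort_values("time", kind="stable").reset_index(drop=True)
    joined = pd.merge_asof(
        dv,
        tr[["time"] + cols],
        left_on="start_time",
        right_on="time",
        direction="nearest",
        tolerance=tolerance_s,
    )
    return joined.drop(columns=["time"])


def read_argos_csv(path) -> pd.DataFrame:
    """Read a location CSV (id, timestamp, lc, lon, lat [, g])."""
    df = pd.read_csv(path)
    df["time"] = (
        pd.to_datetime(df["timestamp"], utc=True, format="ISO8601").astype("int64") / 1e9
    )
    keep = ["id", "time", "lon", "lat", "lc"] + (["g"] if "g" in df.columns else [])
    return df[keep]
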