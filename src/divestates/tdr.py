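"""Time-depth-recorder preprocessing: drift correction, dive detection, phase labelling.

Depth is metres, positive down; times are seconds since the Unix epoch (UTC).
A *dive* is a maximal run of readings deeper than the dive threshold (3 m by
default).  Dive start/end times are refined by linear interpolation of the
threshold crossing on a 10 s grid anchored at the bracketing surface reading,
so that a dive's duration does not quantise to whole sampling intervals even
on 5-minute data.  The bottom phase is the span of the dive deeper than 80 %
of its maximum depth; readings before it are descent, after it ascent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "DepthSeries",
    "DiveConfig",
    "DiveRecord",
    "zero_offset_correct",
    "detect_dives",
    "label_phases",
    "read_depth_csv",
    "write_depth_csv",
    "dives_to_frame",
]


@dataclass
class DepthSeries:
    """A timestamped depth trace for one deployment."""

    times: np.ndarray  # s since epoch, strictly increasing
    depths: np.ndarray  # m, positive down
    nominal_dt: float  # nominal sampling interval, s
    individual_id: str = "tag"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.times.shape != self.depths.shape:
            raise InputError("times and depths must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if not np.all(np.isfinite(self.depths)):
            raise InputError("depths must be finite")
        if self.nominal_dt <= 0:
            raise ConfigurationError("nominal_dt must be positive")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class DiveConfig:
    """Parameters of dive detection and phase labelling.

    threshold      dive threshold depth (m); readings deeper count as diving
    interp_step    grid step (s) for interpolated boundary times
    bottom_fraction  bottom phase is deeper than this fraction of max depth
    min_depth_keep dives with max depth <= this (m) are excluded downstream
    peak_prominence  minimum within-dive peak prominence (m) for splitting
    settle_exclusion_h  dives starting within this many hours of deployment
                   start are excluded (handling effect)
    gap_factor     an inter-reading gap > gap_factor * nominal_dt inside a
                   dive marks the dive as containing missing readings
    """

    threshold: float = 3.0
    interp_step: float = 10.0
    bottom_fraction: float = 0.8
    min_depth_keep: float = 10.0
    peak_prominence: float = 1.0
    settle_exclusion_h: float = 24.0
    gap_factor: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.bottom_fraction < 1.0:
            raise ConfigurationError("bottom_fraction must be in (0, 1)")
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be positive")
        if self.interp_step <= 0:
            raise ConfigurationError("interp_step must be positive")


@dataclass
class DiveRecord:
    """One reconstructed dive with interpolated boundaries and phase labels."""

    dive_id: str
    individual_id: str
    start_time: float  # interpolated threshold crossing, s
    end_time: float
    times: np.ndarray  # in-dive recorded samples
    depths: np.ndarray
    max_depth: float
    grid_times: Optional[np.ndarray] = None  # interpolation grid
    grid_depths: Optional[np.ndarray] = None
    phases: Optional[np.ndarray] = None  # per grid point: descent/bottom/ascent
    bottom_enter: Optional[float] = None
    bottom_exit: Optional[float] = None
    bottom_time: Optional[float] = None
    excluded_reason: Optional[str] = None  # internal_gap / shallow / first_day
    was_split: bool = False
    parent_dive_id: Optional[str] = None
    split_rule: Optional[str] = None

    @property
    def dive_time(self) -> float:
        return self.end_time - self.start_time


def zero_offset_correct(
    series: DepthSeries,
    window_s: float = 3 * 3600.0,
    quantile: float = 0.05,
    envelope_factor: float = 4.0,
) -> DepthSeries:
    """Remove slowly varying surface-depth bias so surface readings read 0 m.

    The offset is estimated as a centred running low quantile of depth
    (default: 5th percentile over 3 h windows), reduced to its lower envelope
    by a running minimum over ``envelope_factor`` windows, smoothed by a
    running median, then subtracted; corrected depths are clamped at 0.  The
    quantile alone overshoots during bouts of long resting dives, when a
    window may contain almost no surface readings; the animal must breathe
    within the wider envelope window, which anchors the estimate back to the
    (drifting) sensor zero while still tracking drift that is slow relative
    to half a day.
    """
    if len(series) == 0:
        raise InputError("cannot zero-offset-correct an empty series")
    t, d = series.times, series.depths
    span = t[-1] - t[0]
    if span < window_s:
        warnings.warn(
            "deployment shorter than the correction window; "
            "using a single global offset",
            stacklevel=2,
        )
        offset = np.quantile(d, quantile)
        corrected = np.clip(d - offset, 0.0, None)
        return replace(series, depths=corrected)
    idx = pd.to_datetime(t, unit="s", utc=True)
    s = pd.Series(d, index=idx)
    win = f"{int(window_s)}s"
    env = f"{int(envelope_factor * window_s)}s"
    off = s.rolling(win, center=True, min_periods=1).quantile(quantile)
    off = off.rolling(env, center=True, min_periods=1).min()
    off = off.rolling(win, center=True, min_periods=1).median()
    corrected = np.clip(d - off.to_numpy(), 0.0, None)
    return replace(series, depths=corrected)


def _crossing_time_on_grid(
    t_surf: float,
    d_surf: float,
    t_dive: float,
    d_dive: float,
    threshold: float,
    step: float,
    entering: bool,
) -> float:
    """Interpolated threshold-crossing time on a grid anchored at the surface reading.

    For a dive entry the grid runs forward from the bracketing surface reading
    and the earliest grid time with interpolated depth >= threshold is
    returned; for an exit the grid runs backward from the bracketing surface
    reading and the latest such time is returned.
    """
    if d_dive <= d_surf:  # degenerate; fall back to the in-dive reading
        return t_dive
    # exact crossing time by linear interpolation
    frac = (threshold - d_surf) / (d_dive - d_surf)
    frac = min(max(frac, 0.0), 1.0)
    t_exact = t_surf + frac * (t_dive - t_surf)
    if entering:
        # earliest grid time t_surf + k*step with t >= t_exact
        k = int(np.ceil((t_exact - t_surf) / step - 1e-9))
        return min(t_surf + k * step, t_dive)
    # exit: grid runs backward from the surface reading; latest t_surf - k*step
    # with t <= t_exact
    k = int(np.ceil((t_surf - t_exact) / step - 1e-9))
    return max(t_surf - k * step, t_dive)


def detect_dives(series: DepthSeries, cfg: DiveConfig | None = None) -> list[DiveRecord]:
    """Detect dives as maximal runs of readings deeper than the threshold.

    Boundary times are interpolated threshold crossings on the ``interp_step``
    grid; dives whose interior spans a missing expected reading (gap greater
    than ``gap_factor * nominal_dt``) are flagged ``internal_gap``.  Phases are
    labelled on every returned dive.
    """
    cfg = cfg or DiveConfig()
    if len(series) < 2:
        return []
    t, d = series.times, series.depths
    wet = d > cfg.threshold
    # run boundaries
    edges = np.flatnonzero(np.diff(wet.astype(np.int8)))
    starts = edges[wet[edges + 1]] + 1
    ends = edges[~wet[edges + 1]]  # inclusive index of last wet reading
    if wet[0]:
        starts = np.insert(starts, 0, 0)
    if wet[-1]:
        ends = np.append(ends, len(wet) - 1)
    dives: list[DiveRecord] = []
    for n, (i, j) in enumerate(zip(starts, ends)):
        if i > 0:
            start = _crossing_time_on_grid(
                t[i - 1], d[i - 1], t[i], d[i], cfg.threshold, cfg.interp_step, True
            )
        else:
            start = t[i]
        if j < len(t) - 1:
            end = _crossing_time_on_grid(
                t[j + 1], d[j + 1], t[j], d[j], cfg.threshold, cfg.interp_step, False
            )
        else:
            end = t[j]
        gaps = np.diff(t[i : j + 1])
        reason = None
        if gaps.size and np.max(gaps) > cfg.gap_factor * series.nominal_dt:
            reason = "internal_gap"
        rec = DiveRecord(
            dive_id=f"{series.individual_id}-{n:05d}",
            individual_id=series.individual_id,
            start_time=start,
            end_time=end,
            times=t[i : j + 1].copy(),
            depths=d[i : j + 1].copy(),
            max_depth=float(np.max(d[i : j + 1])),
            excluded_reason=reason,
        )
        dives.append(label_phases(rec, cfg))
    return dives


def label_phases(dive: DiveRecord, cfg: DiveConfig | None = None) -> DiveRecord:
    """Assign descent/bottom/ascent on the interpolation grid.

    The bottom phase is the contiguous span between the first and last grid
    point strictly deeper than ``bottom_fraction * max_depth``; grid points
    before it are descent, after it ascent.  ``bottom_time`` is the span
    length.
    """
    cfg = cfg or DiveConfig()
    step = cfg.interp_step
    grid = np.arange(dive.start_time, dive.end_time + step * 1e-9, step)
    if grid.size == 0 or grid[-1] < dive.end_time - 1e-9:
        grid = np.append(grid, dive.end_time)
    # interpolation anchors: threshold depth at the boundaries, plus the
    # recorded in-dive samples strictly inside them
    inside = (dive.times > dive.start_time + 1e-9) & (dive.times < dive.end_time - 1e-9)
    xp = np.concatenate(([dive.start_time], dive.times[inside], [dive.end_time]))
    fp = np.concatenate(([cfg.threshold], dive.depths[inside], [cfg.threshold]))
    order = np.argsort(xp, kind="stable")
    xp, fp = xp[order], fp[order]
    gd = np.interp(grid, xp, fp)
    bthr = cfg.bottom_fraction * dive.max_depth
    deep = gd > bthr
    if not np.any(deep):
        # grid too coarse to see the peak: degenerate single-point bottom
        k = int(np.argmax(gd))
        enter = exit_ = grid[k]
    else:
        idx = np.flatnonzero(deep)
        enter, exit_ = grid[idx[0]], grid[idx[-1]]
    phases = np.where(grid < enter, "descent", np.where(grid > exit_, "ascent", "bottom"))
    return replace(
        dive,
        grid_times=grid,
        grid_depths=gd,
        phases=phases,
        bottom_enter=float(enter),
        bottom_exit=float(exit_),
        bottom_time=float(exit_ - enter),
    )


# ---------------------------------------------------------------------------
# CSV I/O

def read_depth_csv(path, nominal_dt: float | None = None) -> list[DepthSeries]:
    """Read a depth CSV (id, timestamp, depth) into one DepthSeries per id."""
    df = pd.read_csv(path)
    times = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601").astype("int64") / 1e9
    df = df.assign(_t=times)
    out = []
    for ind, grp in df.groupby("id", sort=False):
        t = grp["_t"].to_numpy()
        dt = nominal_dt or float(np.median(np.diff(t))) if len(grp) > 1 else 300.0
        out.append(
            DepthSeries(t, grp["depth"].to_numpy(float), dt, individual_id=str(ind))
        )
    return out


def write_depth_csv(series: DepthSeries, path) -> None:
    pd.DataFrame(
        {
            "id": series.individual_id,
            "timestamp": pd.to_datetime(series.times, unit="s", utc=True).strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "depth": series.depths,
        }
    ).to_csv(path, index=False)


def dives_to_frame(dives: list[DiveRecord]) -> pd.DataFrame:
    """One row per dive: ids, boundaries, metrics and flags."""
    return pd.DataFrame(
        {
            "dive_id": [d.dive_id for d in dives],
            "id": [d.individual_id for d in dives],
            "start_time": [d.start_time for d in dives],
            "end_time": [d.end_time for d in dives],
            "max_depth": [d.max_depth for d in dives],
            "bottom_time": [d.bottom_time for d in dives],
            "dive_time": [d.dive_time for d in dives],
            "excluded_reason": [d.excluded_reason for d in dives],
            "was_split": [d.was_split for d in dives],
            "parent_dive_id": [d.parent_dive_id for d in dives],
            "split_rule": [d.split_rule for d in dives],
        }
    )
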