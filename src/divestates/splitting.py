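"""Splitting merged low-resolution dive records at within-dive peaks.

On 5-minute data, two fast successive dives whose surfacing falls between
samples appear as a single long dive containing a 'peak' — a shallow local
excursion bounded by deeper readings.  If the ascent rate into the peak, or
the descent rate out of it, would have carried the animal past the dive
threshold within one sampling interval, the surfacing is considered
kinematically possible and the record is split into two consecutive dives at
the implied crossing times.  A peak where the animal ascends, holds a depth,
and descends again (a plateau) is split unconditionally.  Splitting never
alters recorded samples; it only introduces boundaries, and it recurses into
the halves (bounded depth) so chains of merged dives are fully separated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import InputError
from .tdr import DiveConfig, DiveRecord, label_phases

__all__ = [
    "PeakEvent",
    "SplitDecision",
    "find_dive_peaks",
    "decide_split",
    "split_dive",
    "split_merged_dives",
]

MAX_RECURSION = 4


@dataclass
class PeakEvent:
    """A shallow within-dive excursion bounded by deeper readings."""

    dive_id: str
    index: int  # position of the peak (or plateau-start) reading
    run_end_index: int  # == index for a single-point peak
    peak_time: float
    peak_depth: float
    run_end_time: float
    prev_reading: tuple[float, float]  # (time, depth) adjacent before
    next_reading: tuple[float, float]  # (time, depth) adjacent after
    prominence: float
    is_plateau: bool


@dataclass
class SplitDecision:
    peak: PeakEvent
    v_up: float  # m/s ascent rate into the peak
    v_down: float  # m/s descent rate out of the peak
    t_surface_up: float  # s to cover peak_depth - threshold at v_up
    t_surface_down: float
    split: bool
    rule: str  # speed_up / speed_down / plateau / none


def find_dive_peaks(
    dive: DiveRecord, prominence_min: float = 1.0
) -> list[PeakEvent]:
    """Local depth minima strictly inside the dive with prominence over the floor.

    Prominence is min(adjacent depths) - peak depth.  A run of equal minimal
    depths bounded by deeper readings on both sides is reported once, at the
    run's first reading, flagged as a plateau.
    """
    t, d = dive.times, dive.depths
    n = len(t)
    peaks: list[PeakEvent] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and d[j + 1] == d[i]:
            j += 1
        if j < n - 1 and d[i - 1] > d[i] and d[j + 1] > d[i]:
            prom = min(d[i - 1], d[j + 1]) - d[i]
            if prom > prominence_min:
                peaks.append(
                    PeakEvent(
                        dive_id=dive.dive_id,
                        index=i,
                        run_end_index=j,
                        peak_time=float(t[i]),
                        peak_depth=float(d[i]),
                        run_end_time=float(t[j]),
                        prev_reading=(float(t[i - 1]), float(d[i - 1])),
                        next_reading=(float(t[j + 1]), float(d[j + 1])),
                        prominence=float(prom),
                        is_plateau=j > i,
                    )
                )
        i = j + 1
    return peaks


def decide_split(
    peak: PeakEvent, threshold: float = 3.0, nominal_dt: float = 300.0
) -> SplitDecision:
    """Apply the kinematic surfacing test to a peak.

    The ascent rate into the peak and the descent rate out of it each imply a
    time to cover the remaining depth to the threshold; if either fits inside
    one sampling interval the record is split.  Plateaus split regardless of
    the speed test, and a peak already at or above the threshold is a
    mis-merged boundary and always splits.
    """
    pt, pd_ = peak.prev_reading
    nt, nd = peak.next_reading
    if peak.peak_time <= pt or nt <= peak.run_end_time:
        raise InputError("zero or negative time spacing around peak")
    v_up = (pd_ - peak.peak_depth) / (peak.peak_time - pt)
    v_down = (nd - peak.peak_depth) / (nt - peak.run_end_time)
    remaining = peak.peak_depth - threshold
    t_up = remaining / v_up if v_up > 0 else math.inf
    t_down = remaining / v_down if v_down > 0 else math.inf
    if remaining <= 0:
        split, rule = True, "speed_up"  # boundary itself was mis-merged
    elif min(t_up, t_down) <= nominal_dt:
        split = True
        rule = "speed_up" if t_up <= t_down else "speed_down"
    elif peak.is_plateau:
        split, rule = True, "plateau"
    else:
        split, rule = False, "none"
    return SplitDecision(
        peak=peak,
        v_up=v_up,
        v_down=v_down,
        t_surface_up=max(t_up, 0.0),
        t_surface_down=max(t_down, 0.0),
        split=split,
        rule=rule,
    )


def split_dive(
    dive: DiveRecord,
    decision: SplitDecision,
    cfg: DiveConfig | None = None,
) -> Optional[tuple[DiveRecord, DiveRecord]]:
    """Partition a dive's readings at the decided peak into two dives.

    The first half's end and second half's start are the kinematically
    implied threshold crossings (ascent-based time preferred when both speed
    rules qualify); plateau splits cut between the first two plateau
    readings.  Both halves are re-labelled.  Returns None — the split is
    abandoned — if a half would have no in-dive reading.
    """
    if not decision.split:
        raise InputError("decision does not call for a split")
    cfg = cfg or DiveConfig()
    peak = decision.peak
    t, d = dive.times, dive.depths
    k = peak.index
    if peak.is_plateau:
        first_sl, second_sl = slice(0, k + 1), slice(k + 1, len(t))
        end1 = float(t[k])
        start2 = float(t[k + 1]) if k + 1 < len(t) else end1
    else:
        first_sl, second_sl = slice(0, k + 1), slice(k + 1, len(t))
        nt, nd = peak.next_reading
        t_cross_up = peak.peak_time + max(peak.peak_depth - cfg.threshold, 0.0) / max(
            decision.v_up, 1e-12
        )
        t_cross_down = nt - max(nd - cfg.threshold, 0.0) / max(decision.v_down, 1e-12)
        end1 = min(t_cross_up, nt - 1e-6)
        start2 = min(max(t_cross_down, end1), nt)
    t1, d1 = t[first_sl], d[first_sl]
    t2, d2 = t[second_sl], d[second_sl]
    if t1.size < 1 or t2.size < 1:
        return None
    half1 = DiveRecord(
        dive_id=f"{dive.dive_id}.1",
        individual_id=dive.individual_id,
        start_time=dive.start_time,
        end_time=end1,
        times=t1,
        depths=d1,
        max_depth=float(np.max(d1)),
        excluded_reason=dive.excluded_reason,
        was_split=True,
        parent_dive_id=dive.parent_dive_id or dive.dive_id,
        split_rule=decision.rule,
    )
    half2 = DiveRecord(
        dive_id=f"{dive.dive_id}.2",
        individual_id=dive.individual_id,
        start_time=start2,
        end_time=dive.end_time,
        times=t2,
        depths=d2,
        max_depth=float(np.max(d2)),
        excluded_reason=dive.excluded_reason,
        was_split=True,
        parent_dive_id=dive.parent_dive_id or dive.dive_id,
        split_rule=decision.rule,
    )
    return label_phases(half1, cfg), label_phases(half2, cfg)


def _split_recursive(
    dive: DiveRecord, cfg: DiveConfig, nominal_dt: float, depth: int
) -> list[DiveRecord]:
    if depth >= MAX_RECURSION:
        return [dive]
    for peak in find_dive_peaks(dive, cfg.peak_prominence):
        decision = decide_split(peak, cfg.threshold, nominal_dt)
        if decision.split:
            halves = split_dive(dive, decision, cfg)
            if halves is None:
                continue
            return _split_recursive(halves[0], cfg, nominal_dt, depth + 1) + _split_recursive(
                halves[1], cfg, nominal_dt, depth + 1
            )
    return [dive]


def split_merged_dives(
    dives: list[DiveRecord],
    cfg: DiveConfig | None = None,
    nominal_dt: float = 300.0,
) -> list[DiveRecord]:
    """Apply peak detection and kinematic splitting to every dive, recursively."""
    cfg = cfg or DiveConfig()
    out: list[DiveRecord] = []
    for dv in dives:
        out.extend(_split_recursive(dv, cfg, nominal_dt, 0))
    return out
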