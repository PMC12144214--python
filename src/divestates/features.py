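"""Per-dive feature extraction, exclusion rules and the transformed HMM inputs.

Four features per dive: maximum depth (m), bottom time (s, time deeper than
80 % of max depth), dive time (s) and post-dive surface interval (s, end of
ascent to start of the next dive).  The skewed features — surface interval,
maximum depth and dive time — are natural-log transformed (with a 1 s floor
guarding zero intervals), then all four are min-max scaled to [0, 1] over the
pooled dataset, one scaling shared across individuals so a single model fits
all deployments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .tdr import DiveConfig, DiveRecord

__all__ = [
    "FEATURES",
    "LOG_FEATURES",
    "TransformSpec",
    "extract_features",
    "apply_exclusions",
    "fit_transform",
]

FEATURES = ("max_depth", "bottom_time", "dive_time", "surface_interval")
LOG_FEATURES = ("max_depth", "dive_time", "surface_interval")


def extract_features(dives: list[DiveRecord]) -> pd.DataFrame:
    """Build the per-dive feature table from dives in trip order.

    The surface interval is the gap to the next dive's start; the final dive
    of a deployment, lacking a following dive, is dropped.
    """
    rows = []
    for cur, nxt in zip(dives, dives[1:]):
        surf = nxt.start_time - cur.end_time
        if surf < 0:
            raise DataError(
                f"dives {cur.dive_id} and {nxt.dive_id} overlap "
                f"(interval {surf:.1f} s)"
            )
        rows.append(
            {
                "dive_id": cur.dive_id,
                "id": cur.individual_id,
                "start_time": cur.start_time,
                "month": pd.Timestamp(cur.start_time, unit="s", tz="UTC").month,
                "max_depth": cur.max_depth,
                "bottom_time": cur.bottom_time,
                "dive_time": cur.dive_time,
                "surface_interval": surf,
                "excluded_reason": cur.excluded_reason,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    features: pd.DataFrame,
    deployment_start: float,
    cfg: DiveConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop first-day dives, shallow dives and dives with missing readings.

    Exclusions (in priority order when several apply): ``internal_gap`` — the
    dive spans a transmission gap; ``first_day`` — it starts within 24 h of
    deployment; ``shallow`` — maximum depth at or below 10 m.  Returns the
    retained table and per-reason counts (counts + retained = input rows).
    """
    cfg = cfg or DiveConfig()
    if features.empty:
        return features, {"internal_gap": 0, "first_day": 0, "shallow": 0, "retained": 0}
    gap = features["excluded_reason"].eq("internal_gap").fillna(False).to_numpy()
    first_day = (
        features["start_time"].to_numpy()
        < deployment_start + cfg.settle_exclusion_h * 3600.0
    )
    shallow = features["max_depth"].to_numpy() <= cfg.min_depth_keep
    reason = np.where(gap, "internal_gap", np.where(first_day, "first_day", np.where(shallow, "shallow", "")))
    keep = reason == ""
    counts = {
        "internal_gap": int((reason == "internal_gap").sum()),
        "first_day": int((reason == "first_day").sum()),
        "shallow": int((reason == "shallow").sum()),
        "retained": int(keep.sum()),
    }
    return features[keep].reset_index(drop=True), counts


@dataclass
class TransformSpec:
    """Log + range transform fitted on the pooled dataset.

    Persisting the fitted ranges lets held-out data be transformed
    identically to the training pool.
    """

    log_features: tuple[str, ...] = LOG_FEATURES
    epsilon: float = 1.0  # s; floor before the log, guards zero intervals
    mins: dict[str, float] = field(default_factory=dict)
    maxs: dict[str, float] = field(default_factory=dict)

    def _pre(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for f in FEATURES:
            x = df[f].to_numpy(float)
            if f in self.log_features:
                x = np.log(np.maximum(x, self.epsilon))
            cols.append(x)
        return np.column_stack(cols)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        """Feature matrix scaled to [0, 1] (values outside the fitted range clip)."""
        x = self._pre(df)
        lo = np.array([self.mins[f] for f in FEATURES])
        hi = np.array([self.maxs[f] for f in FEATURES])
        return np.clip((x - lo) / (hi - lo), 0.0, 1.0)

    def inverse_transform(self, matrix: np.ndarray) -> pd.DataFrame:
        lo = np.array([self.mins[f] for f in FEATURES])
        hi = np.array([self.maxs[f] for f in FEATURES])
        x = np.asarray(matrix) * (hi - lo) + lo
        out = {}
        for j, f in enumerate(FEATURES):
            col = x[:, j]
            out[f] = np.exp(col) if f in self.log_features else col
        return pd.DataFrame(out)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "log_features": list(self.log_features),
                    "epsilon": self.epsilon,
                    "mins": {k: float(v) for k, v in self.mins.items()},
                    "maxs": {k: float(v) for k, v in self.maxs.items()},
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "TransformSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            log_features=tuple(doc["log_features"]),
            epsilon=doc["epsilon"],
            mins=doc["mins"],
            maxs=doc["maxs"],
        )


def fit_transform(
    features: pd.DataFrame, epsilon: float = 1.0
) -> tuple[TransformSpec, np.ndarray]:
    """Fit the log + range transform on the pooled dives and apply it.

    Raises ConfigurationError when a feature is constant (range scaling
    undefined) or fewer than 2 dives are supplied.
    """
    if len(features) < 2:
        raise ConfigurationError("need at least 2 dives to fit the transform")
    spec = TransformSpec(epsilon=epsilon)
    pre = spec._pre(features)
    for j, f in enumerate(FEATURES):
        lo, hi = float(np.min(pre[:, j])), float(np.max(pre[:, j]))
        if hi <= lo:
            raise ConfigurationError(f"feature {f} is constant; cannot range-scale")
        spec.mins[f] = lo
        spec.maxs[f] = hi
    return spec, spec.transform(features)
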