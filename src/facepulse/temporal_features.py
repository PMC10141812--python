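"""Rolling-variance and event-count features over the per-frame feature series.

Conventions (pinned here and echoed in the feature-table metadata):

* rolling variance uses a centered window of ``2 * half_width * fps + 1``
  frames, truncated at the edges, population (ddof=0) variance, missing
  values excluded; windows with fewer than two present values are missing;
* closure thresholds are the first quartile (linear-interpolation quantile
  convention) of the area series over the WHOLE session, mirroring the
  source protocol's global statistic — this leaks session-level statistics
  into every frame and is intentional;
* closure counting counts episodes (maximal below-threshold runs), not
  closed frames, intersected with a trailing window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd

from .facial_geometry import EyeModelMap, extract_frame_features
from .io_formats import SessionRecording

__all__ = [
    "FeatureConfig",
    "FeatureTable",
    "rolling_variance",
    "closure_threshold",
    "count_closure_episodes",
    "count_episodes_from_mask",
    "build_feature_table",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing and convention knobs for feature-table assembly."""

    facial_var_half_width_s: float = 3.0
    pulse_var_half_width_s: float = 10.0
    event_window_s: float = 3.0
    bridge_convention: str = "midpoint"
    eye_map: EyeModelMap = field(default_factory=EyeModelMap)
    #: None = rolling variance of every facial (non-pulse) feature.
    variance_features: tuple[str, ...] | None = None

    def conventions(self) -> dict[str, object]:
        return {
            "variance": "population (ddof=0), centered window, edge-truncated",
            "quantile": "linear interpolation",
            "facial_var_half_width_s": self.facial_var_half_width_s,
            "pulse_var_half_width_s": self.pulse_var_half_width_s,
            "event_window_s": self.event_window_s,
            "bridge_convention": self.bridge_convention,
        }


@dataclass
class FeatureTable:
    """Rectangular per-frame feature matrix plus the conventions that built it."""

    data: pd.DataFrame
    fps: float
    conventions: dict[str, object] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the table as CSV (empty cells = missing) with a JSON sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False, lineterminator="\n")
        if sidecar:
            meta = {"fps": self.fps, "conventions": self.conventions}
            path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1) + "\n")


def rolling_variance(
    series: Sequence[float] | np.ndarray, half_width_s: float, fps: float
) -> np.ndarray:
    """Centered rolling population variance over ±``half_width_s`` seconds.

    Edges truncate; NaNs are excluded from each window; windows with fewer
    than 2 present values yield NaN.
    """
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("rolling_variance requires a non-empty series")
    if half_width_s <= 0:
        raise ValueError("half_width_s must be positive")
    half = int(round(half_width_s * fps))
    window = 2 * half + 1
    s = pd.Series(arr)
    return s.rolling(window, center=True, min_periods=2).var(ddof=0).to_numpy()


def closure_threshold(series: Sequence[float] | np.ndarray) -> float:
    """First quartile (linear convention) of the present values of an area series."""
    arr = np.asarray(series, dtype=float)
    present = arr[~np.isnan(arr)]
    if present.size < 4:
        raise ValueError("closure_threshold requires at least 4 present values")
    return float(np.quantile(present, 0.25, method="linear"))


def count_episodes_from_mask(mask: np.ndarray, window_s: float, fps: float) -> np.ndarray:
    """Per-frame count of True-run episodes intersecting the trailing window.

    An episode is a maximal run of consecutive True frames; it is counted at
    frame ``t`` iff it intersects the half-open frame window
    ``(t - window_s * fps, t]`` (an episode straddling the window edge counts
    once).
    """
    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    w = int(round(window_s * fps))
    counts = np.zeros(n + 1, dtype=np.int64)
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    diffs = np.diff(padded)
    starts = np.flatnonzero(diffs == 1)  # first frame of each run
    ends = np.flatnonzero(diffs == -1) - 1  # last frame of each run
    # run [s, e] intersects (t - w, t]  <=>  t in [s, e + w - 1]
    for s, e in zip(starts, ends):
        lo = s
        hi = min(e + w - 1, n - 1)
        if hi >= lo:
            counts[lo] += 1
            counts[hi + 1] -= 1
    return np.cumsum(counts[:-1])


def count_closure_episodes(
    series: Sequence[float] | np.ndarray,
    threshold: float,
    window_s: float = 3.0,
    fps: float = 30.0,
) -> np.ndarray:
    """Per-frame number of below-threshold episodes in the trailing window.

    Missing frames never count as below-threshold (they split runs).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    arr = np.asarray(series, dtype=float)
    with np.errstate(invalid="ignore"):
        below = arr < threshold
    return count_episodes_from_mask(below, window_s, fps)


def build_feature_table(
    session: SessionRecording, config: FeatureConfig | None = None
) -> FeatureTable:
    """Assemble the full per-frame feature table for one session.

    Columns, in deterministic order: the static frame features, a
    ``var_<name>`` rolling variance for every facial feature (±3 s default),
    ``pulse_var`` (±10 s default), per-eye and merged blink counts, and the
    mouth-closure count (trailing 3 s windows). Missing values propagate as
    NaN; nothing is imputed.
    """
    config = config or FeatureConfig()
    fps = session.fps
    rows = [
        extract_frame_features(
            frame,
            session.pulse_per_frame[k],
            bridge_convention=config.bridge_convention,
            eye_map=config.eye_map,
        )
        for k, frame in enumerate(session.frames)
    ]
    static = pd.DataFrame(rows)
    static.insert(0, "frame", [f.frame_index for f in session.frames])

    out = static.copy()
    facial_cols = [c for c in static.columns if c not in ("frame", "pulse")]
    var_cols = (
        facial_cols if config.variance_features is None else list(config.variance_features)
    )
    for col in var_cols:
        out[f"var_{col}"] = rolling_variance(
            static[col].to_numpy(), config.facial_var_half_width_s, fps
        )
    out["pulse_var"] = rolling_variance(
        static["pulse"].to_numpy(), config.pulse_var_half_width_s, fps
    )

    thr_r = closure_threshold(static["eye_area_r"].to_numpy())
    thr_l = closure_threshold(static["eye_area_l"].to_numpy())
    thr_m = closure_threshold(static["mouth_area_in"].to_numpy())
    out["blink_count_r"] = count_closure_episodes(
        static["eye_area_r"].to_numpy(), thr_r, config.event_window_s, fps
    )
    out["blink_count_l"] = count_closure_episodes(
        static["eye_area_l"].to_numpy(), thr_l, config.event_window_s, fps
    )
    with np.errstate(invalid="ignore"):
        either_closed = (static["eye_area_r"].to_numpy() < thr_r) | (
            static["eye_area_l"].to_numpy() < thr_l
        )
    out["blink_count"] = count_episodes_from_mask(either_closed, config.event_window_s, fps)
    out["mouth_closed_count"] = count_closure_episodes(
        static["mouth_area_in"].to_numpy(), thr_m, config.event_window_s, fps
    )

    conventions = dict(config.conventions())
    conventions["closure_thresholds"] = {
        "eye_area_r": thr_r,
        "eye_area_l": thr_l,
        "mouth_area_in": thr_m,
    }
    return FeatureTable(data=out, fps=fps, conventions=conventions)
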