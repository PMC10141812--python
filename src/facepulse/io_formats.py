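"""Readers/writers for the three session input formats and pulse-to-frame alignment.

Three file kinds make up one recorded session:

* a per-frame facial landmark table in the OpenFace 2.0 output CSV dialect
  (68 face points, 56 eye-model points, gaze angles, head rotation,
  per-frame confidence/success),
* a 1 Hz pulse-rate CSV (``timestamp,bpm``; empty bpm cells mark dropouts),
* a JSON utterance annotation file
  (``[{"onset_s": ..., "end_s": ..., "deceptive": ...}, ...]``).

The landmark dialect is configurable through a column-name mapping so tables
produced by other tools can be ingested without rewriting headers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, CoverageError, FormatError, ParseError

__all__ = [
    "N_FACE_POINTS",
    "N_EYE_POINTS",
    "DEFAULT_DIALECT",
    "LandmarkFrame",
    "PulseSeries",
    "UtteranceAnnotation",
    "SessionRecording",
    "read_openface_csv",
    "write_openface_csv",
    "read_pulse_csv",
    "write_pulse_csv",
    "read_annotations",
    "write_annotations",
    "align_pulse_to_frames",
    "load_session",
]

N_FACE_POINTS = 68
N_EYE_POINTS = 56

#: Column-name templates of the OpenFace 2.0 CSV dialect. ``{i}`` is the
#: landmark index. Override entries via the ``dialect_map`` argument of
#: :func:`read_openface_csv` for other dialects.
DEFAULT_DIALECT: dict[str, object] = {
    "frame": "frame",
    "timestamp": "timestamp",
    "confidence": "confidence",
    "success": "success",
    "face_x": "x_{i}",
    "face_y": "y_{i}",
    "eye_x": "eye_lmk_x_{i}",
    "eye_y": "eye_lmk_y_{i}",
    "gaze": ("gaze_angle_x", "gaze_angle_y"),
    "pose": ("pose_Rx", "pose_Ry", "pose_Rz"),
}


@dataclass
class LandmarkFrame:
    """One video frame's landmarks, gaze, head pose and tracking status.

    ``face_points`` holds the 68 face-model points (pixels) in landmark
    order P0..P67; ``eye_points`` the 56 eye-model points E0..E55. The two
    models use independent index spaces.
    """

    frame_index: int
    timestamp: float
    confidence: float
    success: bool
    face_points: np.ndarray  # (68, 2) float
    eye_points: np.ndarray  # (56, 2) float
    gaze: np.ndarray  # (2,) radians: horizontal, vertical
    head_rotation: np.ndarray  # (3,) radians: pitch, yaw, roll

    def __post_init__(self) -> None:
        self.face_points = np.asarray(self.face_points, dtype=float)
        self.eye_points = np.asarray(self.eye_points, dtype=float)
        self.gaze = np.asarray(self.gaze, dtype=float)
        self.head_rotation = np.asarray(self.head_rotation, dtype=float)
        if self.face_points.shape != (N_FACE_POINTS, 2):
            raise ValueError(f"face_points must be (68, 2), got {self.face_points.shape}")
        if self.eye_points.shape != (N_EYE_POINTS, 2):
            raise ValueError(f"eye_points must be (56, 2), got {self.eye_points.shape}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkFrame):
            return NotImplemented
        return (
            self.frame_index == other.frame_index
            and self.timestamp == other.timestamp
            and self.confidence == other.confidence
            and self.success == other.success
            and np.array_equal(self.face_points, other.face_points)
            and np.array_equal(self.eye_points, other.eye_points)
            and np.array_equal(self.gaze, other.gaze)
            and np.array_equal(self.head_rotation, other.head_rotation)
        )


@dataclass
class PulseSeries:
    """A 1 Hz (or otherwise sampled) pulse-rate series; NaN marks missing bpm."""

    timestamps: np.ndarray  # seconds, strictly increasing
    bpm: np.ndarray  # beats/minute, NaN where missing

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.timestamps.shape != self.bpm.shape:
            raise ValueError("timestamps and bpm must have the same length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise FormatError("pulse timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.bpm).sum())


@dataclass(frozen=True)
class UtteranceAnnotation:
    """One utterance interval; onset is the moment the subject opened their mouth."""

    onset_s: float
    end_s: float
    deceptive: bool

    def __post_init__(self) -> None:
        if not self.onset_s < self.end_s:
            raise AnnotationError(
                f"annotation onset ({self.onset_s}) must precede end ({self.end_s})"
            )


@dataclass
class SessionRecording:
    """A frame sequence aligned with a per-frame pulse value and its annotations."""

    frames: list[LandmarkFrame]
    pulse_per_frame: np.ndarray
    annotations: list[UtteranceAnnotation]
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.pulse_per_frame = np.asarray(self.pulse_per_frame, dtype=float)
        if len(self.pulse_per_frame) != len(self.frames):
            raise ValueError("pulse_per_frame must have one value per frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def _expand_dialect(dialect_map: dict[str, object] | None) -> dict[str, object]:
    d = dict(DEFAULT_DIALECT)
    if dialect_map:
        d.update(dialect_map)
    return d


def _required_columns(d: dict[str, object]) -> list[str]:
    cols = [str(d["frame"]), str(d["timestamp"]), str(d["confidence"]), str(d["success"])]
    for i in range(N_FACE_POINTS):
        cols.append(str(d["face_x"]).format(i=i))
    for i in range(N_FACE_POINTS):
        cols.append(str(d["face_y"]).format(i=i))
    for i in range(N_EYE_POINTS):
        cols.append(str(d["eye_x"]).format(i=i))
    for i in range(N_EYE_POINTS):
        cols.append(str(d["eye_y"]).format(i=i))
    cols.extend(d["gaze"])  # type: ignore[arg-type]
    cols.extend(d["pose"])  # type: ignore[arg-type]
    return cols


def read_openface_csv(
    path: str | Path, dialect_map: dict[str, object] | None = None
) -> list[LandmarkFrame]:
    """Read a per-frame landmark table into a list of :class:`LandmarkFrame`.

    Rows with ``success == 0`` are retained but flagged; downstream feature
    extraction marks them missing. Raises :class:`FormatError` naming the
    first missing mapped column, :class:`ParseError` with the (0-based data)
    row number of the first non-numeric cell.
    """
    path = Path(path)
    d = _expand_dialect(dialect_map)
    # OpenFace pads header/cell values with spaces.
    raw = pd.read_csv(path, skipinitialspace=True, float_precision="round_trip")
    raw.columns = [c.strip() for c in raw.columns]
    required = _required_columns(d)
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")

    table = raw[required].apply(pd.to_numeric, errors="coerce")
    bad = table.isna() & raw[required].notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0])
        col = bad.columns[int(np.argwhere(bad.to_numpy()[row])[0][0])]
        raise ParseError(f"non-numeric cell in column {col!r} at data row {row} of {path.name}")
    if table.isna().to_numpy().any():
        row = int(np.argwhere(table.isna().to_numpy().any(axis=1))[0][0])
        raise ParseError(f"empty cell at data row {row} of {path.name}")

    fx = table[[str(d["face_x"]).format(i=i) for i in range(N_FACE_POINTS)]].to_numpy()
    fy = table[[str(d["face_y"]).format(i=i) for i in range(N_FACE_POINTS)]].to_numpy()
    ex = table[[str(d["eye_x"]).format(i=i) for i in range(N_EYE_POINTS)]].to_numpy()
    ey = table[[str(d["eye_y"]).format(i=i) for i in range(N_EYE_POINTS)]].to_numpy()
    gaze = table[list(d["gaze"])].to_numpy()  # type: ignore[call-overload]
    pose = table[list(d["pose"])].to_numpy()  # type: ignore[call-overload]

    frames: list[LandmarkFrame] = []
    prev_index = None
    for r in range(len(table)):
        idx = int(table[str(d["frame"])].iloc[r])
        if prev_index is not None and idx <= prev_index:
            raise FormatError(
                f"frame indices must be strictly increasing (row {r} of {path.name})"
            )
        prev_index = idx
        frames.append(
            LandmarkFrame(
                frame_index=idx,
                timestamp=float(table[str(d["timestamp"])].iloc[r]),
                confidence=float(table[str(d["confidence"])].iloc[r]),
                success=bool(int(table[str(d["success"])].iloc[r])),
                face_points=np.stack([fx[r], fy[r]], axis=1),
                eye_points=np.stack([ex[r], ey[r]], axis=1),
                gaze=gaze[r],
                head_rotation=pose[r],
            )
        )
    return frames


def write_openface_csv(frames: Sequence[LandmarkFrame], path: str | Path) -> None:
    """Write frames in the canonical (default) dialect; inverse of the reader."""
    d = DEFAULT_DIALECT
    cols: dict[str, list] = {
        str(d["frame"]): [f.frame_index for f in frames],
        str(d["timestamp"]): [f.timestamp for f in frames],
        str(d["confidence"]): [f.confidence for f in frames],
        str(d["success"]): [int(f.success) for f in frames],
    }
    for i in range(N_FACE_POINTS):
        cols[str(d["face_x"]).format(i=i)] = [f.face_points[i, 0] for f in frames]
    for i in range(N_FACE_POINTS):
        cols[str(d["face_y"]).format(i=i)] = [f.face_points[i, 1] for f in frames]
    for i in range(N_EYE_POINTS):
        cols[str(d["eye_x"]).format(i=i)] = [f.eye_points[i, 0] for f in frames]
    for i in range(N_EYE_POINTS):
        cols[str(d["eye_y"]).format(i=i)] = [f.eye_points[i, 1] for f in frames]
    for j, name in enumerate(d["gaze"]):  # type: ignore[arg-type]
        cols[name] = [f.gaze[j] for f in frames]
    for j, name in enumerate(d["pose"]):  # type: ignore[arg-type]
        cols[name] = [f.head_rotation[j] for f in frames]
    # %.17g guarantees exact float round-trip through text
    pd.DataFrame(cols).to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_pulse_csv(path: str | Path) -> PulseSeries:
    """Read a ``timestamp,bpm`` CSV; empty bpm cells become NaN missing-markers."""
    path = Path(path)
    raw = pd.read_csv(path, skipinitialspace=True, float_precision="round_trip")
    raw.columns = [c.strip() for c in raw.columns]
    for col in ("timestamp", "bpm"):
        if col not in raw.columns:
            raise FormatError(f"missing required column {col!r} in {path.name}")
    ts = pd.to_numeric(raw["timestamp"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(ts).any():
        row = int(np.argwhere(np.isnan(ts))[0][0])
        raise ParseError(f"non-numeric timestamp at data row {row} of {path.name}")
    bpm = pd.to_numeric(raw["bpm"], errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(bpm) & raw["bpm"].notna().to_numpy()
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ParseError(f"non-numeric bpm at data row {row} of {path.name}")
    present = bpm[~np.isnan(bpm)]
    if present.size and (present.min() <= 20 or present.max() >= 250):
        raise FormatError(f"bpm values outside the plausible (20, 250) range in {path.name}")
    return PulseSeries(timestamps=ts, bpm=bpm)


def write_pulse_csv(pulse: PulseSeries, path: str | Path) -> None:
    df = pd.DataFrame({"timestamp": pulse.timestamps, "bpm": pulse.bpm})
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_annotations(path: str | Path) -> list[UtteranceAnnotation]:
    """Read the utterance annotation JSON (list of onset/end/deceptive records)."""
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise FormatError(f"{Path(path).name}: annotation file must contain a JSON list")
    out = []
    for k, rec in enumerate(records):
        try:
            out.append(
                UtteranceAnnotation(
                    onset_s=float(rec["onset_s"]),
                    end_s=float(rec["end_s"]),
                    deceptive=bool(rec["deceptive"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{Path(path).name}: malformed annotation record {k}: {exc}")
    return out


def write_annotations(annotations: Sequence[UtteranceAnnotation], path: str | Path) -> None:
    records = [
        {"onset_s": a.onset_s, "end_s": a.end_s, "deceptive": a.deceptive} for a in annotations
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)
        fh.write("\n")


def align_pulse_to_frames(
    pulse: PulseSeries, n_frames: int, fps: float, mode: str = "step"
) -> np.ndarray:
    """Resample a pulse series to one bpm value per video frame.

    ``step`` (default) assigns each frame the pulse sample with the greatest
    timestamp not exceeding the frame time; ``linear`` interpolates between
    consecutive samples at the frame timestamp ``frame_index / fps``. Frames
    whose covering sample(s) are missing carry NaN.
    """
    if mode not in ("step", "linear"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if len(pulse) == 0:
        raise CoverageError("empty pulse series")
    duration = n_frames / fps
    interval = float(np.median(np.diff(pulse.timestamps))) if len(pulse) > 1 else 1.0
    if pulse.timestamps[-1] < duration - interval - 1e-9:
        raise CoverageError(
            f"pulse series ends at {pulse.timestamps[-1]:.3f}s but the session "
            f"lasts {duration:.3f}s"
        )
    t = np.arange(n_frames, dtype=float) / fps
    idx = np.searchsorted(pulse.timestamps, t + 1e-12, side="right") - 1
    if mode == "step":
        return pulse.bpm[np.clip(idx, 0, len(pulse) - 1)]
    lo = np.clip(idx, 0, len(pulse) - 1)
    hi = np.clip(idx + 1, 0, len(pulse) - 1)
    t0, t1 = pulse.timestamps[lo], pulse.timestamps[hi]
    b0, b1 = pulse.bpm[lo], pulse.bpm[hi]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(t1 > t0, (t - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0)
    w = np.clip(w, 0.0, 1.0)
    return b0 + w * (b1 - b0)


def load_session(
    landmarks_path: str | Path,
    pulse_path: str | Path,
    annotations_path: str | Path,
    fps: float = 30.0,
    align_mode: str = "step",
    dialect_map: dict[str, object] | None = None,
) -> SessionRecording:
    """Read the three session files and assemble an aligned :class:`SessionRecording`."""
    frames = read_openface_csv(landmarks_path, dialect_map=dialect_map)
    pulse = read_pulse_csv(pulse_path)
    annotations = read_annotations(annotations_path)
    pulse_per_frame = align_pulse_to_frames(pulse, len(frames), fps, mode=align_mode)
    return SessionRecording(
        frames=frames, pulse_per_frame=pulse_per_frame, annotations=annotations, fps=fps
    )
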