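"""Synthetic session generator: landmark CSV, pulse CSV and annotation JSON.

Stands in for unavailable human-subject recordings. A neutral 68-point face
template (plus a 56-point eye model) is animated with seeded jitter; blinks
are a Poisson process whose rate is multiplied inside deception windows;
the mouth opens during utterances and its area is shifted inside deception
windows; gaze and head pose follow small AR(1) walks with extra gaze shifts
in deception windows; pulse is an AR(1) series at 1 Hz whose innovation
variance is multiplied in deception windows.

"Deception window" always means the label window ``[onset - 3 s, onset + 5 s)``
of a deceptive utterance, so the generator and the labeler agree by
construction. Every emitted file round-trips through the io readers.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError
from .io_formats import (
    LandmarkFrame,
    PulseSeries,
    SessionRecording,
    UtteranceAnnotation,
    align_pulse_to_frames,
    write_annotations,
    write_openface_csv,
    write_pulse_csv,
)
from .labeling import POST_ONSET_S, PRE_ONSET_S, make_labels

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_session",
    "make_role_play_set",
    "null_config",
    "write_session_files",
]

# --- face template geometry (pixels, 1280x720 image, y grows downward) -------------
_EYE_CENTER_R = np.array([570.0, 320.0])
_EYE_CENTER_L = np.array([710.0, 320.0])
_EYE_RX, _EYE_RY = 28.0, 11.0
_IRIS_R, _PUPIL_R = 6.0, 2.5
_GAZE_TO_PX = 18.0  # iris displacement per radian of gaze
_MOUTH_CENTER = np.array([640.0, 412.0])
_MOUTH_RX_OUT, _MOUTH_RX_IN = 40.0, 30.0
_BROW_R_X = np.array([535.0, 551.0, 567.0, 583.0, 600.0])
_BROW_R_Y = np.array([302.0, 297.0, 295.0, 296.0, 298.0])
_BROW_L_X = np.array([680.0, 697.0, 713.0, 729.0, 745.0])
_BROW_L_Y = np.array([298.0, 296.0, 295.0, 297.0, 302.0])


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; effect sizes act only inside deception windows."""

    duration_s: float = 180.0
    fps: float = 30.0
    n_utterances: int = 10
    fraction_deceptive: float = 0.5
    utterance_length_s: tuple[float, float] = (6.0, 9.0)
    seed: int = 0
    # effect sizes
    blink_rate_base: float = 24.0  # blinks/minute outside deception windows
    blink_rate_deception_multiplier: float = 5.0
    mouth_area_shift: float = 0.2  # fractional inner/outer area change
    gaze_shift_sd: float = 0.03  # radians, per-window offset (~1.3x baseline sd)
    pulse_base: float = 72.0
    pulse_noise_sd: float = 1.0
    pulse_ar_coeff: float = 0.2
    pulse_variance_deception_multiplier: float = 8.0
    landmark_jitter_sd: float = 0.4  # pixels
    pulse_missing_rate: float = 0.0
    # label-independent eyelid nuisance motion (variance pollution for lid
    # features); zero both to make blink counts exactly recover scripted blinks
    droop_rate_per_min: float = 15.0
    eyelid_wander_sd: float = 0.003

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ConfigError("duration and fps must be positive")
        if not 0.0 <= self.fraction_deceptive <= 1.0:
            raise ConfigError("fraction_deceptive must be in [0, 1]")
        lo, hi = self.utterance_length_s
        if not 0 < lo <= hi:
            raise ConfigError("utterance_length_s must be an increasing positive range")
        for name in (
            "blink_rate_base",
            "blink_rate_deception_multiplier",
            "mouth_area_shift",
            "gaze_shift_sd",
            "pulse_noise_sd",
            "pulse_variance_deception_multiplier",
            "landmark_jitter_sd",
            "pulse_missing_rate",
            "droop_rate_per_min",
            "eyelid_wander_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually injected, for oracle-style assertions."""

    labels: np.ndarray  # per-frame deception label
    annotations: list[UtteranceAnnotation]
    blink_start_frames: list[int]
    effects: dict[str, bool] = field(default_factory=dict)
    config: SynthConfig | None = None

    @property
    def n_blinks(self) -> int:
        return len(self.blink_start_frames)

    def blink_counts_by_label(self) -> tuple[int, int]:
        """(blinks starting in negative frames, blinks starting in positive frames)."""
        pos = sum(1 for f in self.blink_start_frames if self.labels[f] == 1)
        return self.n_blinks - pos, pos

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": self.labels.astype(int).tolist(),
            "annotations": [asdict(a) for a in self.annotations],
            "blink_start_frames": list(map(int, self.blink_start_frames)),
            "effects": self.effects,
            "config": asdict(self.config) if self.config else None,
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def _place_utterances(config: SynthConfig, rng: np.random.Generator) -> list[UtteranceAnnotation]:
    """One utterance per equal time slot, label windows guaranteed disjoint."""
    n = config.n_utterances
    if n == 0:
        return []
    slot = config.duration_s / n
    lo_len, hi_len = config.utterance_length_s
    needed = PRE_ONSET_S + max(hi_len, POST_ONSET_S) + 1.0
    if slot < needed:
        raise ConfigError(
            f"cannot pack {n} utterances of up to {hi_len}s into {config.duration_s}s "
            f"(each needs a {needed:.1f}s slot, have {slot:.1f}s)"
        )
    n_deceptive = int(round(config.fraction_deceptive * n))
    deceptive = np.zeros(n, dtype=bool)
    deceptive[rng.permutation(n)[:n_deceptive]] = True
    annotations = []
    for i in range(n):
        length = float(rng.uniform(lo_len, hi_len))
        start_lo = i * slot + PRE_ONSET_S + 0.5
        start_hi = i * slot + slot - max(hi_len, POST_ONSET_S) - 0.5
        onset = float(rng.uniform(start_lo, start_hi))
        annotations.append(
            UtteranceAnnotation(onset_s=onset, end_s=onset + length, deceptive=bool(deceptive[i]))
        )
    return annotations


def _in_intervals(n_frames: int, fps: float, intervals: list[tuple[float, float]]) -> np.ndarray:
    t = np.arange(n_frames) / fps
    mask = np.zeros(n_frames, dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t < b)
    return mask


def _ar1(
    n: int, coeff: float, sd: np.ndarray | float, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.standard_normal(n) * sd
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = coeff * acc + noise[i]
        out[i] = acc
    return out


def _eye_model_points(
    center: np.ndarray, open_frac: float, iris_offset: np.ndarray
) -> np.ndarray:
    """28 points of one eye: pupil ring (0-7), lid ellipse (8-19), iris ring (20-27)."""
    pts = np.empty((28, 2))
    iris_center = center + iris_offset
    ang_pupil = np.deg2rad(180.0 - 45.0 * np.arange(8))
    pts[0:8, 0] = iris_center[0] + _PUPIL_R * np.cos(ang_pupil)
    pts[0:8, 1] = iris_center[1] - _PUPIL_R * np.sin(ang_pupil)
    ang_lid = np.deg2rad(180.0 - 30.0 * np.arange(12))
    pts[8:20, 0] = center[0] + _EYE_RX * np.cos(ang_lid)
    pts[8:20, 1] = center[1] - _EYE_RY * open_frac * np.sin(ang_lid)
    ang_iris = np.deg2rad(180.0 - 45.0 * np.arange(8))
    pts[20:28, 0] = iris_center[0] + _IRIS_R * np.cos(ang_iris)
    pts[20:28, 1] = iris_center[1] - _IRIS_R * np.sin(ang_iris)
    return pts


def _ellipse_ring(center: np.ndarray, rx: float, ry: float, angles_deg: np.ndarray) -> np.ndarray:
    ang = np.deg2rad(angles_deg)
    return np.stack([center[0] + rx * np.cos(ang), center[1] - ry * np.sin(ang)], axis=1)


def _face_points(
    eye_open: float, mouth_inner_ry: float, mouth_scale: float
) -> np.ndarray:
    pts = np.empty((68, 2))
    # jaw P0..P16: lower half-ellipse
    ang = np.deg2rad(180.0 + 180.0 * np.arange(17) / 16.0)
    pts[0:17, 0] = 640.0 + 120.0 * np.cos(ang)
    pts[0:17, 1] = 330.0 - 140.0 * np.sin(ang)
    # brows P17..P26
    pts[17:22, 0], pts[17:22, 1] = _BROW_R_X, _BROW_R_Y
    pts[22:27, 0], pts[22:27, 1] = _BROW_L_X, _BROW_L_Y
    # nose P27..P35
    pts[27:31] = [[640.0, 310.0], [640.0, 325.0], [640.0, 340.0], [640.0, 352.0]]
    pts[31:36, 0] = [620.0, 630.0, 640.0, 650.0, 660.0]
    pts[31:36, 1] = 358.0
    # eye hexagons P36..P47
    hexa = np.array([180.0, 120.0, 60.0, 0.0, -60.0, -120.0])
    pts[36:42] = _ellipse_ring(_EYE_CENTER_R, _EYE_RX, _EYE_RY * eye_open, hexa)
    pts[42:48] = _ellipse_ring(_EYE_CENTER_L, _EYE_RX, _EYE_RY * eye_open, hexa)
    # mouth rings P48..P59 (outer dodecagon) and P60..P67 (inner octagon)
    ry_out = 10.0 + 0.8 * mouth_inner_ry
    outer_ang = 180.0 - 30.0 * np.arange(12)
    inner_ang = 180.0 - 45.0 * np.arange(8)
    pts[48:60] = _ellipse_ring(
        _MOUTH_CENTER, _MOUTH_RX_OUT * mouth_scale, ry_out * mouth_scale, outer_ang
    )
    pts[60:68] = _ellipse_ring(
        _MOUTH_CENTER, _MOUTH_RX_IN * mouth_scale, mouth_inner_ry * mouth_scale, inner_ang
    )
    return pts


_BLINK_PROFILE = np.array([0.05, 0.25])  # eye-opening factor over 2 frames


def simulate_session(
    config: SynthConfig, outdir: str | Path | None = None
) -> tuple[SessionRecording, GroundTruth]:
    """Generate one complete synthetic session (optionally writing its files).

    Returns the in-memory :class:`SessionRecording` (pulse step-aligned to
    frames) and the :class:`GroundTruth` log. With ``outdir`` set, also
    writes ``landmarks.csv``, ``pulse.csv``, ``annotations.json`` and
    ``ground_truth.json`` there.
    """
    rng = np.random.default_rng(config.seed)
    fps = config.fps
    n_frames = int(round(config.duration_s * fps))
    annotations = _place_utterances(config, rng)
    labels, _ = make_labels(annotations, n_frames, fps)
    in_utterance = _in_intervals(
        n_frames, fps, [(a.onset_s, a.end_s) for a in annotations]
    )
    deception = labels.astype(bool)

    # --- blinks: Poisson process, rate multiplied inside deception windows
    hazard = np.where(
        deception,
        config.blink_rate_base * config.blink_rate_deception_multiplier,
        config.blink_rate_base,
    ) / (60.0 * fps)
    # Eyelid openness: a tight baseline plus slow, smooth "droop" events
    # (label-independent partial closures). Droops make blink-free lid motion
    # non-degenerate — they pollute the 6 s lid-feature variance windows and
    # contribute at most one below-threshold episode each — while deep blinks
    # stay an unambiguous episode count.
    eye_open = 1.0 + _ar1(n_frames, 0.99, config.eyelid_wander_sd, rng)
    droop_hazard = config.droop_rate_per_min / (60.0 * fps)
    droop_draws = rng.random(n_frames)
    k = 0
    while k < n_frames:
        if droop_draws[k] < droop_hazard:
            dur = int(rng.uniform(1.0, 3.0) * fps)
            depth = rng.uniform(0.3, 0.7)
            span = min(dur, n_frames - k)
            profile = depth * np.sin(math.pi * np.linspace(0.0, 1.0, span))
            eye_open[k : k + span] -= profile
            k += span + 1
        else:
            k += 1
    draws = rng.random(n_frames)
    blink_starts: list[int] = []
    k = 0
    while k < n_frames:
        if draws[k] < hazard[k]:
            blink_starts.append(k)
            span = min(len(_BLINK_PROFILE), n_frames - k)
            depth = rng.uniform(0.5, 0.75)  # closure fraction of this blink
            eye_open[k : k + span] *= 1.0 - depth * (1.0 - _BLINK_PROFILE[:span])
            k += span + 2  # refractory gap so episodes stay separate
        else:
            k += 1
    eye_open = np.clip(eye_open, 0.02, 1.5)

    # --- mouth: opens while speaking (slow per-utterance cadence), area shifted
    # inside deception windows
    t = np.arange(n_frames) / fps
    mouth_ry = 1.2 + np.abs(rng.normal(0.0, 0.25, n_frames))
    for ann in annotations:
        window = (t >= ann.onset_s) & (t < ann.end_s)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        cadence = 0.5 + 0.5 * np.sin(2.0 * math.pi * 0.4 * t[window] + phase)
        mouth_ry[window] += 3.3 * cadence
    mouth_scale = np.where(deception, math.sqrt(1.0 + config.mouth_area_shift), 1.0)

    # --- gaze and head pose: AR(1) walks; extra per-window gaze offsets
    gaze = np.stack(
        [_ar1(n_frames, 0.9, 0.01, rng), _ar1(n_frames, 0.9, 0.01, rng)], axis=1
    )
    for idx, ann in enumerate(annotations):
        if not ann.deceptive:
            continue
        offset = rng.normal(0.0, config.gaze_shift_sd, size=2)
        window = _in_intervals(
            n_frames, fps, [(ann.onset_s - PRE_ONSET_S, ann.onset_s + POST_ONSET_S)]
        )
        gaze[window] += offset
    head = np.stack([_ar1(n_frames, 0.9, 0.005, rng) for _ in range(3)], axis=1)

    # --- pulse at 1 Hz: AR(1), innovation variance multiplied in deception windows
    n_seconds = int(math.ceil(config.duration_s)) + 1
    sec_frames = np.minimum((np.arange(n_seconds) * fps).astype(int), n_frames - 1)
    sec_deceptive = deception[sec_frames]
    sd_per_sec = np.where(
        sec_deceptive,
        config.pulse_noise_sd * math.sqrt(config.pulse_variance_deception_multiplier),
        config.pulse_noise_sd,
    )
    bpm = config.pulse_base + _ar1(n_seconds, config.pulse_ar_coeff, sd_per_sec, rng)
    bpm = np.clip(bpm, 40.0, 200.0)
    if config.pulse_missing_rate > 0:
        bpm[rng.random(n_seconds) < config.pulse_missing_rate] = np.nan
    pulse = PulseSeries(timestamps=np.arange(n_seconds, dtype=float), bpm=bpm)

    # --- assemble frames; landmark jitter is AR(1)-smooth over time (real
    # tracker noise is strongly autocorrelated), marginal sd = landmark_jitter_sd
    jitter_coeff = 0.97
    innovations = rng.normal(
        0.0,
        config.landmark_jitter_sd * math.sqrt(1.0 - jitter_coeff**2),
        size=(n_frames, 68 + 56, 2),
    )
    jitter = lfilter([1.0], [1.0, -jitter_coeff], innovations, axis=0)
    frames: list[LandmarkFrame] = []
    for i in range(n_frames):
        face = _face_points(eye_open[i], mouth_ry[i], mouth_scale[i]) + jitter[i, :68]
        iris_off = np.clip(gaze[i] * _GAZE_TO_PX, -10.0, 10.0)
        eye = np.vstack(
            [
                _eye_model_points(_EYE_CENTER_R, eye_open[i], iris_off),
                _eye_model_points(_EYE_CENTER_L, eye_open[i], iris_off),
            ]
        ) + jitter[i, 68:]
        frames.append(
            LandmarkFrame(
                frame_index=i,
                timestamp=i / fps,
                confidence=0.98,
                success=True,
                face_points=face,
                eye_points=eye,
                gaze=gaze[i].copy(),
                head_rotation=head[i].copy(),
            )
        )

    session = SessionRecording(
        frames=frames,
        pulse_per_frame=align_pulse_to_frames(pulse, n_frames, fps, mode="step"),
        annotations=annotations,
        fps=fps,
    )
    truth = GroundTruth(
        labels=labels,
        annotations=annotations,
        blink_start_frames=blink_starts,
        effects={
            "blink_rate": config.blink_rate_deception_multiplier != 1.0,
            "mouth_area": config.mouth_area_shift != 0.0,
            "gaze": config.gaze_shift_sd != 0.0,
            "pulse_variance": config.pulse_variance_deception_multiplier != 1.0,
        },
        config=config,
    )
    if outdir is not None:
        write_session_files(session, truth, pulse, outdir)
    return session, truth


def write_session_files(
    session: SessionRecording,
    truth: GroundTruth,
    pulse: PulseSeries,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three io-format files plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "landmarks": outdir / "landmarks.csv",
        "pulse": outdir / "pulse.csv",
        "annotations": outdir / "annotations.json",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_openface_csv(session.frames, paths["landmarks"])
    write_pulse_csv(pulse, paths["pulse"])
    write_annotations(session.annotations, paths["annotations"])
    truth.to_json(paths["ground_truth"])
    return paths


def null_config(config: SynthConfig) -> SynthConfig:
    """The same generator with every deception effect switched off."""
    return replace(
        config,
        blink_rate_deception_multiplier=1.0,
        mouth_area_shift=0.0,
        gaze_shift_sd=0.0,
        pulse_variance_deception_multiplier=1.0,
    )


def make_role_play_set(
    config: SynthConfig, shift: float = 0.0, seed_offset: int = 7919
) -> tuple[SessionRecording, GroundTruth]:
    """A second session with effect sizes perturbed by a relative ``shift``.

    ``shift=0`` re-draws the same distribution under a different seed
    (statistically exchangeable with the training set); ``shift=-1`` zeroes
    every deception effect.
    """
    scale = 1.0 + shift
    if scale < 0:
        raise ConfigError("shift below -1 would produce negative effect sizes")
    perturbed = replace(
        config,
        blink_rate_deception_multiplier=1.0
        + (config.blink_rate_deception_multiplier - 1.0) * scale,
        mouth_area_shift=config.mouth_area_shift * scale,
        gaze_shift_sd=config.gaze_shift_sd * scale,
        pulse_variance_deception_multiplier=1.0
        + (config.pulse_variance_deception_multiplier - 1.0) * scale,
        seed=config.seed + seed_offset,
    )
    return simulate_session(perturbed)
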