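"""Per-frame geometric facial features from 2-D landmark coordinates.

All distances are normalized by the nasal-bridge length ``L`` and all areas
by ``L**2`` so features are invariant to image scale; every feature is also
translation invariant by construction. Coordinates follow the image
convention (y grows downward), so the sign of slope-like features is flipped
versus visual intuition — documented, not corrected.

Missing sub-features (closed-eye degeneracies, vertical brows, zero-length
segments) are marked NaN rather than raising, except for a fully degenerate
face (``L == 0``) which invalidates the whole frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFaceError
from .io_formats import LandmarkFrame

__all__ = [
    "FEATURE_COLUMNS",
    "EyeModelMap",
    "NormalizationContext",
    "ExtentPair",
    "polygon_area",
    "nasal_bridge_length",
    "eyebrow_tilt",
    "brow_eye_distance",
    "inter_brow_area",
    "eye_area",
    "eye_aspect_ratio",
    "iris_offsets",
    "mouth_area",
    "mouth_aspect",
    "mouth_corner_raise",
    "mouth_angle",
    "extract_frame_features",
]

# --- 68-point face-model index sets -------------------------------------------------
BROW_RIGHT = (17, 18, 19, 20, 21)
BROW_LEFT = (22, 23, 24, 25, 26)
BROW_EYE_PAIRS_RIGHT = ((18, 36), (19, 37), (20, 38), (21, 39))
BROW_EYE_PAIRS_LEFT = ((22, 42), (23, 43), (24, 44), (25, 45))
NASAL_BRIDGE = (21, 22, 39, 42)
INTER_BROW_RING = (21, 22, 42, 39)  # convex traversal, not the listed order
EYE_RIGHT = (36, 37, 38, 39, 40, 41)
EYE_LEFT = (42, 43, 44, 45, 46, 47)
MOUTH_OUTER = tuple(range(48, 60))
MOUTH_INNER = tuple(range(60, 68))
MOUTH_ASPECT_INNER = {"v": (62, 66), "h": (60, 64)}
MOUTH_ASPECT_OUTER = {"v": (51, 57), "h": (48, 54)}
MOUTH_CORNER_TOP_BOTTOM = (51, 57)
MOUTH_CORNER_SIDES = (48, 54)
MOUTH_ANGLE_RIGHT = (48, 49, 59)  # vertex first
MOUTH_ANGLE_LEFT = (54, 53, 55)


@dataclass(frozen=True)
class EyeModelMap:
    """Binding of semantic eye-landmark roles to 56-point eye-model indices.

    The eye model uses its own index space (E0..E55); which indices play the
    corner/top/iris roles is configuration, with defaults matching the
    right-eye-first layout (right eye E0..E27, left eye E28..E55).
    """

    right_h: tuple[int, int] = (8, 14)  # leftmost, rightmost lid points
    right_v: tuple[int, int] = (11, 17)  # top, bottom lid points
    right_inner_corner: int = 14
    right_top: int = 11
    right_iris: tuple[int, int] = (23, 27)
    left_h: tuple[int, int] = (36, 42)
    left_v: tuple[int, int] = (39, 45)
    left_inner_corner: int = 36
    left_top: int = 39
    left_iris: tuple[int, int] = (51, 55)


DEFAULT_EYE_MAP = EyeModelMap()


@dataclass(frozen=True)
class NormalizationContext:
    """Nasal-bridge scale: distances are divided by L, areas by L**2."""

    L: float

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise DegenerateFaceError(f"normalization length must be positive, got {self.L}")


@dataclass(frozen=True)
class ExtentPair:
    """Vertical / horizontal extents of an eye or mouth opening (pixels)."""

    l_v: float
    l_h: float


def polygon_area(points: np.ndarray) -> float:
    """Absolute shoelace area of a closed polygon in stored vertex order.

    The vertex list wraps cyclically; collinear input yields 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("polygon_area needs at least 3 two-dimensional points")
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * abs(float(np.sum((x - xn) * (y + yn))))


def nasal_bridge_length(face_points: np.ndarray, convention: str = "midpoint") -> float:
    """Scale reference L from the inner brow ends (P21, P22) and inner eye tops (P39, P42).

    ``midpoint`` (default): distance between midpoint(P21, P22) and
    midpoint(P39, P42). ``pair_mean``: mean of |P21-P39| and |P22-P42|.
    Both conventions agree on axis-aligned rectangles.
    """
    p21, p22, p39, p42 = (np.asarray(face_points[i], dtype=float) for i in NASAL_BRIDGE)
    if convention == "midpoint":
        L = float(np.linalg.norm((p21 + p22) / 2 - (p39 + p42) / 2))
    elif convention == "pair_mean":
        L = float((np.linalg.norm(p21 - p39) + np.linalg.norm(p22 - p42)) / 2)
    else:
        raise ValueError(f"unknown nasal-bridge convention {convention!r}")
    if L <= 0:
        raise DegenerateFaceError("nasal-bridge length is zero")
    return L


def eyebrow_tilt(brow_points: np.ndarray) -> float:
    """Ordinary least-squares slope of y on x over the 5 brow points.

    NaN when all x coincide (vertical brow). Image y grows downward, so the
    sign is flipped versus visual intuition.
    """
    pts = np.asarray(brow_points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        return math.nan
    return float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)


def brow_eye_distance(
    face_points: np.ndarray,
    pairs: tuple[tuple[int, int], ...],
    ctx: NormalizationContext,
) -> float:
    """Mean Euclidean length of the listed brow-to-eyelid segments, ÷ L."""
    pts = np.asarray(face_points, dtype=float)
    dists = [float(np.linalg.norm(pts[a] - pts[b])) for a, b in pairs]
    return float(np.mean(dists)) / ctx.L


def inter_brow_area(face_points: np.ndarray, ctx: NormalizationContext) -> float:
    """Area of the quadrilateral P21-P22-P42-P39 (convex traversal), ÷ L²."""
    pts = np.asarray(face_points, dtype=float)[list(INTER_BROW_RING)]
    return polygon_area(pts) / ctx.L**2


def eye_area(face_points: np.ndarray, side: str, ctx: NormalizationContext) -> float:
    """Shoelace area of the 6-point eye ring, ÷ L²."""
    ring = EYE_RIGHT if side == "right" else EYE_LEFT
    return polygon_area(np.asarray(face_points, dtype=float)[list(ring)]) / ctx.L**2


def eye_aspect_ratio(extents: ExtentPair) -> float:
    """Vertical over horizontal extent; NaN when the horizontal extent is zero."""
    if extents.l_h == 0:
        return math.nan
    return extents.l_v / extents.l_h


def _extents(points: np.ndarray, v_pair: tuple[int, int], h_pair: tuple[int, int]) -> ExtentPair:
    pts = np.asarray(points, dtype=float)
    return ExtentPair(
        l_v=float(np.linalg.norm(pts[v_pair[0]] - pts[v_pair[1]])),
        l_h=float(np.linalg.norm(pts[h_pair[0]] - pts[h_pair[1]])),
    )


def iris_offsets(
    eye_points: np.ndarray,
    side: str,
    ctx: NormalizationContext,
    eye_map: EyeModelMap = DEFAULT_EYE_MAP,
) -> tuple[float, float]:
    """(horizontal, vertical) iris displacement, ÷ L.

    Horizontal: distance from the inner eye corner to the iris center (the
    midpoint of the two designated iris points). Vertical: distance from the
    top lid point to the iris center.
    """
    pts = np.asarray(eye_points, dtype=float)
    if side == "right":
        corner, top, iris = eye_map.right_inner_corner, eye_map.right_top, eye_map.right_iris
    else:
        corner, top, iris = eye_map.left_inner_corner, eye_map.left_top, eye_map.left_iris
    center = (pts[iris[0]] + pts[iris[1]]) / 2
    return (
        float(np.linalg.norm(pts[corner] - center)) / ctx.L,
        float(np.linalg.norm(pts[top] - center)) / ctx.L,
    )


def mouth_area(face_points: np.ndarray, ring: str, ctx: NormalizationContext) -> float:
    """Shoelace area of the inner octagon (P60..P67) or outer dodecagon (P48..P59), ÷ L²."""
    indices = MOUTH_INNER if ring == "inner" else MOUTH_OUTER
    return polygon_area(np.asarray(face_points, dtype=float)[list(indices)]) / ctx.L**2


def mouth_aspect(extents: ExtentPair) -> float:
    """Vertical over horizontal mouth extent; NaN when the horizontal extent is zero."""
    return eye_aspect_ratio(extents)


def mouth_corner_raise(face_points: np.ndarray) -> float:
    """(y_h - y_v) / y_v where y_v sums the top/bottom lip y's and y_h the corner y's.

    Positive means raised corners under the image-coordinate reading; NaN
    when y_v is zero.
    """
    pts = np.asarray(face_points, dtype=float)
    y_v = float(pts[MOUTH_CORNER_TOP_BOTTOM[0], 1] + pts[MOUTH_CORNER_TOP_BOTTOM[1], 1])
    y_h = float(pts[MOUTH_CORNER_SIDES[0], 1] + pts[MOUTH_CORNER_SIDES[1], 1])
    if y_v == 0:
        return math.nan
    return (y_h - y_v) / y_v


def _angle_at(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return math.nan
    cos = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cos))))


def mouth_angle(face_points: np.ndarray) -> float:
    """Mean of the two mouth-corner opening angles, in degrees within [0, 180]."""
    pts = np.asarray(face_points, dtype=float)
    r = _angle_at(pts[MOUTH_ANGLE_RIGHT[0]], pts[MOUTH_ANGLE_RIGHT[1]], pts[MOUTH_ANGLE_RIGHT[2]])
    l = _angle_at(pts[MOUTH_ANGLE_LEFT[0]], pts[MOUTH_ANGLE_LEFT[1]], pts[MOUTH_ANGLE_LEFT[2]])
    return (r + l) / 2


#: Stable output column order of :func:`extract_frame_features`.
FEATURE_COLUMNS = [
    "eyebrow_tilt_r",
    "eyebrow_tilt_l",
    "brow_eye_dist_r",
    "brow_eye_dist_l",
    "inter_brow_area",
    "eye_area_r",
    "eye_area_l",
    "ear_r",
    "ear_l",
    "iris_offset_h_r",
    "iris_offset_v_r",
    "iris_offset_h_l",
    "iris_offset_v_l",
    "mouth_area_in",
    "mouth_area_out",
    "mouth_aspect_in",
    "mouth_aspect_out",
    "mouth_corner_raise",
    "mouth_angle",
    "gaze_h",
    "gaze_v",
    "head_pitch",
    "head_yaw",
    "head_roll",
    "pulse",
]


def extract_frame_features(
    frame: LandmarkFrame,
    pulse_bpm: float,
    bridge_convention: str = "midpoint",
    eye_map: EyeModelMap = DEFAULT_EYE_MAP,
) -> dict[str, float]:
    """Compute the full static feature vector of one frame.

    Gaze, head rotation and pulse are passed through unchanged. Frames the
    landmark tool flagged unsuccessful, or with a degenerate face, yield an
    all-NaN vector (later removed by preprocessing).
    """
    if not frame.success:
        return {name: math.nan for name in FEATURE_COLUMNS}
    try:
        ctx = NormalizationContext(L=nasal_bridge_length(frame.face_points, bridge_convention))
    except DegenerateFaceError:
        return {name: math.nan for name in FEATURE_COLUMNS}

    fp, ep = frame.face_points, frame.eye_points
    off_r = iris_offsets(ep, "right", ctx, eye_map)
    off_l = iris_offsets(ep, "left", ctx, eye_map)
    values = {
        "eyebrow_tilt_r": eyebrow_tilt(fp[list(BROW_RIGHT)]),
        "eyebrow_tilt_l": eyebrow_tilt(fp[list(BROW_LEFT)]),
        "brow_eye_dist_r": brow_eye_distance(fp, BROW_EYE_PAIRS_RIGHT, ctx),
        "brow_eye_dist_l": brow_eye_distance(fp, BROW_EYE_PAIRS_LEFT, ctx),
        "inter_brow_area": inter_brow_area(fp, ctx),
        "eye_area_r": eye_area(fp, "right", ctx),
        "eye_area_l": eye_area(fp, "left", ctx),
        "ear_r": eye_aspect_ratio(_extents(ep, eye_map.right_v, eye_map.right_h)),
        "ear_l": eye_aspect_ratio(_extents(ep, eye_map.left_v, eye_map.left_h)),
        "iris_offset_h_r": off_r[0],
        "iris_offset_v_r": off_r[1],
        "iris_offset_h_l": off_l[0],
        "iris_offset_v_l": off_l[1],
        "mouth_area_in": mouth_area(fp, "inner", ctx),
        "mouth_area_out": mouth_area(fp, "outer", ctx),
        "mouth_aspect_in": mouth_aspect(
            _extents(fp, MOUTH_ASPECT_INNER["v"], MOUTH_ASPECT_INNER["h"])
        ),
        "mouth_aspect_out": mouth_aspect(
            _extents(fp, MOUTH_ASPECT_OUTER["v"], MOUTH_ASPECT_OUTER["h"])
        ),
        "mouth_corner_raise": mouth_corner_raise(fp),
        "mouth_angle": mouth_angle(fp),
        "gaze_h": float(frame.gaze[0]),
        "gaze_v": float(frame.gaze[1]),
        "head_pitch": float(frame.head_rotation[0]),
        "head_yaw": float(frame.head_rotation[1]),
        "head_roll": float(frame.head_rotation[2]),
        "pulse": float(pulse_bpm),
    }
    return {name: values[name] for name in FEATURE_COLUMNS}
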