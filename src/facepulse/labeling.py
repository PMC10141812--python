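"""Per-frame binary deception labels from utterance annotations.

A frame is positive iff its timestamp falls in ``[onset - 3 s, onset + 5 s)``
of any deceptive utterance (half-open at frame resolution, so an unclipped
window spans exactly ``8 * fps`` frames). Everything else — truthful
utterances, silence, and the tail of a deceptive utterance beyond +5 s — is
negative. Overlapping positive windows union; a positive window takes
precedence over any overlapping truthful utterance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnotationError
from .io_formats import UtteranceAnnotation
from .temporal_features import FeatureTable

__all__ = ["PRE_ONSET_S", "POST_ONSET_S", "LabeledDataset", "make_labels", "label_dataset"]

PRE_ONSET_S = 3.0
POST_ONSET_S = 5.0


@dataclass
class LabeledDataset:
    """A feature table joined with per-frame labels and their provenance.

    ``provenance[k]`` is the index of the deceptive annotation whose window
    covers frame ``k`` (the first one, for overlaps), or -1 for negatives.
    """

    features: pd.DataFrame
    labels: np.ndarray
    provenance: np.ndarray
    fps: float
    conventions: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.features):
            raise ValueError("labels must have one entry per feature row")
        if len(self.provenance) != len(self.features):
            raise ValueError("provenance must have one entry per feature row")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def make_labels(
    annotations: list[UtteranceAnnotation],
    n_frames: int,
    fps: float,
    pre_s: float = PRE_ONSET_S,
    post_s: float = POST_ONSET_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (labels, provenance) arrays of length ``n_frames``.

    Frame ``k`` (time ``k / fps``) is positive iff it lies in
    ``[onset - pre_s, onset + post_s)`` of a deceptive annotation, clipped to
    the session. Raises :class:`AnnotationError` for a deceptive onset
    outside the session bounds.
    """
    labels = np.zeros(n_frames, dtype=np.int8)
    provenance = np.full(n_frames, -1, dtype=np.int64)
    duration = n_frames / fps
    eps = 1e-9
    for idx, ann in enumerate(annotations):
        if not ann.deceptive:
            continue
        if ann.onset_s < 0 or ann.onset_s > duration:
            raise AnnotationError(
                f"deceptive onset {ann.onset_s}s outside session [0, {duration}]s"
            )
        start = max(0, math.ceil((ann.onset_s - pre_s) * fps - eps))
        stop = min(n_frames, math.ceil((ann.onset_s + post_s) * fps - eps))
        if stop <= start:
            continue
        labels[start:stop] = 1
        seg = provenance[start:stop]
        seg[seg == -1] = idx
    return labels, provenance


def label_dataset(
    table: FeatureTable,
    annotations: list[UtteranceAnnotation],
    pre_s: float = PRE_ONSET_S,
    post_s: float = POST_ONSET_S,
) -> LabeledDataset:
    """Join a feature table with window labels derived from its annotations."""
    labels, provenance = make_labels(annotations, table.n_frames, table.fps, pre_s, post_s)
    conventions = dict(table.conventions)
    conventions["label_window_s"] = [-pre_s, post_s]
    return LabeledDataset(
        features=table.data,
        labels=labels,
        provenance=provenance,
        fps=table.fps,
        conventions=conventions,
    )
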