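"""Core data structures for 25-point 2D pose skeletons.

The pipeline works on the BODY_25 keypoint layout emitted by markerless
pose trackers: 25 ordered joints per frame, each with an image-pixel
(x, y) position (x rightward, y downward) and a detection confidence in
[0, 1].  A confidence at or below :data:`DEFAULT_MISSING_CONFIDENCE` marks
the joint as missing for that frame (occlusion / tracking failure).

Recordings are cut into *snippets*: 5-second, 250-frame units at 50 fps
that are rated and classified independently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

#: BODY_25 joint order (index -> name), adopted verbatim from the OpenPose
#: convention.  The normalization anchor is MidHip (8); trunk length is the
#: Neck (1) <-> MidHip (8) distance.
BODY_25_JOINT_NAMES = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

N_JOINTS = 25
NECK = 1
MID_HIP = 8

#: Joints with confidence strictly below this are treated as missing.
DEFAULT_MISSING_CONFIDENCE = 0.05

#: A snippet is exactly 5 s at 50 fps.
SNIPPET_FPS = 50.0
SNIPPET_FRAMES = 250


class Label(str, enum.Enum):
    """Snippet-level rating: fidgety movements present / absent / unusable."""

    FM_PLUS = "FM_PLUS"
    FM_MINUS = "FM_MINUS"
    NOT_ASSESSABLE = "NOT_ASSESSABLE"
    UNLABELED = "UNLABELED"

    @classmethod
    def coerce(cls, value) -> "Label":
        """Parse a label from common spellings (``FM+``, ``fm-``, ...)."""
        if isinstance(value, cls):
            return value
        text = str(value).strip()
        aliases = {
            "FM+": cls.FM_PLUS, "FM_PLUS": cls.FM_PLUS, "FMPLUS": cls.FM_PLUS, "1": cls.FM_PLUS,
            "FM-": cls.FM_MINUS, "FM−": cls.FM_MINUS, "FM_MINUS": cls.FM_MINUS,
            "FMMINUS": cls.FM_MINUS, "0": cls.FM_MINUS,
            "NOT_ASSESSABLE": cls.NOT_ASSESSABLE, "NOT ASSESSABLE": cls.NOT_ASSESSABLE,
            "NA": cls.NOT_ASSESSABLE,
            "UNLABELED": cls.UNLABELED,
        }
        key = text.upper().replace("−", "-")
        if key in aliases:
            return aliases[key]
        raise ValueError(f"unknown label {value!r}")


@dataclass(frozen=True)
class KeypointFrame:
    """One video frame: 25 ordered 2D points with confidences."""

    points: np.ndarray      # (25, 2) float, image pixels
    confidence: np.ndarray  # (25,) float in [0, 1]
    frame_index: int

    def __post_init__(self):
        points = np.asarray(self.points, dtype=float)
        confidence = np.asarray(self.confidence, dtype=float)
        if points.shape != (N_JOINTS, 2):
            raise ValueError(f"expected (25, 2) points, got {points.shape}")
        if confidence.shape != (N_JOINTS,):
            raise ValueError(f"expected 25 confidences, got {confidence.shape}")
        if np.any((confidence < 0) | (confidence > 1)):
            raise ValueError("confidences must lie in [0, 1]")
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "confidence", confidence)

    def missing_mask(self, threshold: float = DEFAULT_MISSING_CONFIDENCE) -> np.ndarray:
        return self.confidence < threshold


class SkeletonSequence:
    """An ordered, gapless run of keypoint frames at a known frame rate.

    Coordinates and confidences are stored as dense arrays (``xy`` with
    shape ``(T, 25, 2)``, ``confidence`` with shape ``(T, 25)``); the
    ``frames`` property materialises :class:`KeypointFrame` views on demand.
    """

    def __init__(self, xy: np.ndarray, confidence: np.ndarray, fps: float,
                 participant_id: str = "", source_id: str = ""):
        xy = np.asarray(xy, dtype=float)
        confidence = np.asarray(confidence, dtype=float)
        if xy.ndim != 3 or xy.shape[1:] != (N_JOINTS, 2):
            raise ValueError(f"xy must have shape (T, 25, 2), got {xy.shape}")
        if confidence.shape != xy.shape[:2]:
            raise ValueError("confidence shape must match xy frames x joints")
        if np.any((confidence < 0) | (confidence > 1)):
            raise ValueError("confidences must lie in [0, 1]")
        if not fps > 0:
            raise ValueError("fps must be positive")
        self.xy = xy
        self.confidence = confidence
        self.fps = float(fps)
        self.participant_id = participant_id
        self.source_id = source_id

    def __len__(self) -> int:
        return self.xy.shape[0]

    @property
    def frames(self) -> list[KeypointFrame]:
        return [KeypointFrame(self.xy[t], self.confidence[t], t) for t in range(len(self))]

    @classmethod
    def from_frames(cls, frames, fps: float, participant_id: str = "",
                    source_id: str = "") -> "SkeletonSequence":
        indices = [f.frame_index for f in frames]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise ValueError("frame indices must be strictly increasing")
        if indices and indices != list(range(indices[0], indices[0] + len(indices))):
            raise ValueError("frame indices must be gapless")
        xy = np.stack([f.points for f in frames]) if frames else np.empty((0, N_JOINTS, 2))
        conf = np.stack([f.confidence for f in frames]) if frames else np.empty((0, N_JOINTS))
        return cls(xy, conf, fps, participant_id, source_id)

    def copy(self) -> "SkeletonSequence":
        return SkeletonSequence(self.xy.copy(), self.confidence.copy(), self.fps,
                                self.participant_id, self.source_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SkeletonSequence):
            return NotImplemented
        return (self.fps == other.fps
                and self.participant_id == other.participant_id
                and np.array_equal(self.xy, other.xy)
                and np.array_equal(self.confidence, other.confidence))


@dataclass
class SkeletonSnippet:
    """A labelled 250-frame (5 s at 50 fps) unit tied to one participant."""

    sequence: SkeletonSequence
    snippet_id: str
    label: Label = Label.UNLABELED

    def __post_init__(self):
        if len(self.sequence) != SNIPPET_FRAMES:
            raise ValueError(
                f"snippet must have exactly {SNIPPET_FRAMES} frames, got {len(self.sequence)}")
        if self.sequence.fps != SNIPPET_FPS:
            raise ValueError(f"snippet must be sampled at {SNIPPET_FPS} fps")
        self.label = Label.coerce(self.label)

    @property
    def participant_id(self) -> str:
        return self.sequence.participant_id

    @property
    def duration_s(self) -> float:
        return len(self.sequence) / self.sequence.fps


@dataclass(frozen=True)
class RatingPair:
    """Labels assigned to one snippet by two independent assessors."""

    snippet_id: str
    rater_a: Label
    rater_b: Label

    def __post_init__(self):
        for name in ("rater_a", "rater_b"):
            label = Label.coerce(getattr(self, name))
            if label is Label.UNLABELED:
                raise ValueError("rater labels must be FM+/FM-/not-assessable")
            object.__setattr__(self, name, label)
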