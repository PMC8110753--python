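"""Skeleton normalization and stacked sliding-window feature vectors.

A snippet's raw pixel skeleton depends on camera distance and framing.
To remove that, every frame is translated so the mid-hip joint sits at
the origin, and all coordinates are divided by the snippet-median trunk
length (neck ↔ mid-hip distance over frames where both are present) —
the skeleton is scaled to 1.  Joints the tracker missed are set to
exactly (0, 0) after the transform, so zero marks "missing".

Classification inputs are then built by a sliding window: the (x, y)
values of ``n_stack`` consecutive frames are concatenated into one
vector of ``50 * n_stack`` values, with consecutive windows offset by
``n_slide`` frames.  At the defaults (n_stack=52, n_slide=12) a
250-frame snippet yields 17 windows of 2600 values, each covering
1.04 s of video.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnusableSnippetError
from .skeleton import (
    DEFAULT_MISSING_CONFIDENCE, MID_HIP, N_JOINTS, NECK, SNIPPET_FRAMES,
    SkeletonSequence, SkeletonSnippet, Label,
)


@dataclass(frozen=True)
class FeatureConfig:
    """Sliding-window geometry: frames per input vector and window offset."""

    n_stack: int = 52
    n_slide: int = 12

    def __post_init__(self):
        if not 1 <= self.n_stack <= SNIPPET_FRAMES:
            raise ValueError(f"n_stack must lie in [1, {SNIPPET_FRAMES}]")
        if self.n_slide < 1:
            raise ValueError("n_slide must be >= 1")

    @property
    def vector_length(self) -> int:
        return 2 * N_JOINTS * self.n_stack

    @property
    def window_seconds(self) -> float:
        return self.n_stack / 50.0


@dataclass(frozen=True)
class FeatureWindow:
    """One stacked input vector for the classifier.

    Layout is frame-major, within a frame joint-major, within a joint
    (x, y): ``[x0_f, y0_f, x1_f, y1_f, ..., x24_f, y24_f]`` for each
    frame ``f`` of the window in order.  Missing joints contribute
    exactly 0.
    """

    vector: np.ndarray
    snippet_id: str
    window_index: int
    label: Label = Label.UNLABELED


def normalize_skeleton(snippet: SkeletonSnippet,
                       anchor_joint: int = MID_HIP,
                       trunk_joints: tuple[int, int] = (NECK, MID_HIP),
                       missing_threshold: float = DEFAULT_MISSING_CONFIDENCE) -> SkeletonSnippet:
    """Translate to the anchor joint, scale by median trunk length, zero-fill.

    Per frame the anchor (default mid-hip) is moved to the origin; when
    the anchor is missing in a frame, the snippet-median anchor position
    is used instead.  All coordinates are divided by the snippet-median
    trunk length so the output is unitless.  If the trunk joints are
    never jointly present the snippet-median bounding-box diagonal of
    the confident points is used as scale.  Missing joints end up at
    exactly (0, 0).

    Raises
    ------
    UnusableSnippetError
        No frame has at least two confident points.
    """
    seq = snippet.sequence
    present = seq.confidence >= missing_threshold
    if not (present.sum(axis=1) >= 2).any():
        raise UnusableSnippetError(f"{snippet.snippet_id}: no frame has >= 2 confident points")

    a, b = trunk_joints
    both = present[:, a] & present[:, b]
    if both.any():
        scale = float(np.median(np.linalg.norm(seq.xy[both, a] - seq.xy[both, b], axis=1)))
    else:
        diagonals = []
        for t in range(len(seq)):
            pts = seq.xy[t][present[t]]
            if len(pts) >= 2:
                diagonals.append(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
        scale = float(np.median(diagonals))
    if scale <= 0:
        raise UnusableSnippetError(f"{snippet.snippet_id}: degenerate (zero) trunk scale")

    anchor_present = present[:, anchor_joint]
    if anchor_present.any():
        fallback_anchor = np.median(seq.xy[anchor_present, anchor_joint], axis=0)
    else:
        fallback_anchor = np.array([0.0, 0.0])
    anchors = np.where(anchor_present[:, None], seq.xy[:, anchor_joint, :], fallback_anchor)

    xy = (seq.xy - anchors[:, None, :]) / scale
    xy[~present] = 0.0
    conf = np.where(present, seq.confidence, 0.0)
    norm_seq = SkeletonSequence(xy, conf, seq.fps, seq.participant_id, seq.source_id)
    return SkeletonSnippet(norm_seq, snippet.snippet_id, snippet.label)


def window_count(t_frames: int, n_stack: int, n_slide: int) -> int:
    """Number of complete sliding windows over ``t_frames`` frames.

    Windows start at 0, n_slide, 2*n_slide, ...; a trailing partial
    window is dropped.
    """
    if t_frames < 1 or n_stack < 1 or n_slide < 1:
        raise ValueError("t_frames, n_stack and n_slide must be positive")
    if t_frames < n_stack:
        return 0
    return (t_frames - n_stack) // n_slide + 1


def stack_windows(snippet: SkeletonSnippet,
                  cfg: FeatureConfig = FeatureConfig()) -> list[FeatureWindow]:
    """Cut a normalized snippet into stacked sliding-window vectors.

    Window ``k`` covers frames ``[k*n_slide, k*n_slide + n_stack)``;
    every window inherits the snippet label.
    """
    seq = snippet.sequence
    t_frames = len(seq)
    if cfg.n_stack > t_frames:
        raise ValueError(f"n_stack={cfg.n_stack} exceeds snippet length {t_frames}")
    flat = seq.xy.reshape(t_frames, 2 * N_JOINTS)  # per frame: x0,y0,x1,y1,...
    windows = []
    for k in range(window_count(t_frames, cfg.n_stack, cfg.n_slide)):
        start = k * cfg.n_slide
        vec = flat[start:start + cfg.n_stack].reshape(-1).copy()
        windows.append(FeatureWindow(vec, snippet.snippet_id, k, snippet.label))
    return windows


def windows_matrix(snippets, cfg: FeatureConfig = FeatureConfig(), normalize: bool = True):
    """Build the training matrix for a list of snippets.

    Returns ``(X, y, snippet_ids)`` where ``X`` is float32 of shape
    (n_windows, 50*n_stack), ``y`` holds 1 for FM+ / 0 for FM−, and
    ``snippet_ids`` maps each row back to its snippet.
    """
    vectors, labels, ids = [], [], []
    for snippet in snippets:
        if normalize:
            snippet = normalize_skeleton(snippet)
        for window in stack_windows(snippet, cfg):
            vectors.append(window.vector)
            labels.append(1.0 if window.label is Label.FM_PLUS else 0.0)
            ids.append(window.snippet_id)
    X = np.asarray(vectors, dtype=np.float32)
    return X, np.asarray(labels, dtype=np.float32), np.asarray(ids)


def save_feature_matrix(path, X, y, snippet_ids, cfg: FeatureConfig) -> None:
    """Persist a feature matrix as ``.npz`` with a JSON sidecar describing
    the window geometry and vector layout."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(path, X=X, y=y, snippet_ids=snippet_ids)
    sidecar = {"n_stack": cfg.n_stack, "n_slide": cfg.n_slide,
               "vector_length": cfg.vector_length,
               "layout": "frame-major, joint-major, (x, y)", "layout_version": 1}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_feature_matrix(path):
    """Load a feature matrix saved by :func:`save_feature_matrix`."""
    import json
    from pathlib import Path

    data = np.load(Path(path), allow_pickle=False)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    cfg = FeatureConfig(n_stack=sidecar["n_stack"], n_slide=sidecar["n_slide"])
    return data["X"], data["y"], data["snippet_ids"], cfg
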