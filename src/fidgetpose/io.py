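"""Read and write pose-keypoint sequences.

Two on-disk dialects are supported:

* **OpenPose BODY_25 JSON** — one JSON file per frame (ordered by
  filename) or a single JSON-lines stream, each record holding
  ``people[i].pose_keypoints_2d``: a flat ``[x1, y1, c1, ..., x25, y25,
  c25]`` array of 75 floats.
* **Long-format CSV** — columns ``frame, joint, x, y, confidence``, one
  row per (frame, joint).  Writing then reading reproduces a sequence
  exactly (coordinates are serialized at full precision).

Sequences are assembled into non-overlapping 250-frame snippets at
50 fps; inputs at other frame rates are resampled by per-coordinate
linear interpolation first (missing joints are never interpolated
across).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AmbiguousPersonError, FormatError, ParseError
from .skeleton import (
    N_JOINTS, SNIPPET_FPS, SNIPPET_FRAMES,
    Label, RatingPair, SkeletonSequence, SkeletonSnippet,
)

logger = logging.getLogger(__name__)

_FLAT_LEN = 3 * N_JOINTS  # 75 floats per person


def _frame_from_record(record: dict, source: str, person_index: int | None):
    people = record.get("people", [])
    if len(people) == 0:
        return np.zeros((N_JOINTS, 2)), np.zeros(N_JOINTS)
    if len(people) > 1 and person_index is None:
        raise AmbiguousPersonError(
            f"{source}: {len(people)} people detected; pass person_index to choose one")
    person = people[person_index if person_index is not None else 0]
    flat = person.get("pose_keypoints_2d")
    if flat is None or len(flat) != _FLAT_LEN:
        got = "absent" if flat is None else len(flat)
        raise FormatError(f"{source}: pose_keypoints_2d must hold {_FLAT_LEN} floats, got {got}")
    triplets = np.asarray(flat, dtype=float).reshape(N_JOINTS, 3)
    return triplets[:, :2], np.clip(triplets[:, 2], 0.0, 1.0)


def read_openpose_json(path, fps: float = SNIPPET_FPS, person_index: int | None = None,
                       participant_id: str = "", source_id: str | None = None) -> SkeletonSequence:
    """Read a BODY_25 JSON directory (one file per frame) or JSON-lines file.

    Frames are ordered by filename (directory input) or line order
    (stream input) and re-indexed 0..T-1.  A record with no detected
    people yields an all-missing frame (every confidence 0).

    Raises
    ------
    ParseError
        Malformed JSON; the message names the offending file.
    FormatError
        A person entry whose keypoint array is not 75 floats long.
    AmbiguousPersonError
        More than one person in a frame and ``person_index`` is None.
    """
    path = Path(path)
    records: list[tuple[dict, str]] = []
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise ParseError(f"{path}: no .json files found")
        for file in files:
            try:
                records.append((json.loads(file.read_text()), str(file)))
            except json.JSONDecodeError as exc:
                raise ParseError(f"{file}: malformed JSON ({exc})") from exc
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                records.append((json.loads(line), f"{path}:{lineno}"))
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: malformed JSON ({exc})") from exc
        if not records:
            raise ParseError(f"{path}: empty JSON stream")

    xy = np.empty((len(records), N_JOINTS, 2))
    conf = np.empty((len(records), N_JOINTS))
    for t, (record, source) in enumerate(records):
        xy[t], conf[t] = _frame_from_record(record, source, person_index)
    return SkeletonSequence(xy, conf, fps, participant_id,
                            source_id if source_id is not None else path.stem)


CSV_COLUMNS = ("frame", "joint", "x", "y", "confidence")


def write_sequence_csv(seq: SkeletonSequence, path) -> None:
    """Write one row per (frame, joint) with full-precision coordinates."""
    frames = np.repeat(np.arange(len(seq)), N_JOINTS)
    joints = np.tile(np.arange(N_JOINTS), len(seq))
    df = pd.DataFrame({
        "frame": frames,
        "joint": joints,
        "x": seq.xy[:, :, 0].ravel(),
        "y": seq.xy[:, :, 1].ravel(),
        "confidence": seq.confidence.ravel(),
    })
    df.to_csv(path, index=False)


def read_sequence_csv(path, fps: float = SNIPPET_FPS, participant_id: str = "",
                      source_id: str | None = None) -> SkeletonSequence:
    """Read a long-format keypoint CSV.

    Joints absent for a frame are filled in as confidence-0 (missing)
    points with a warning; duplicate (frame, joint) rows are an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    if df.empty:
        raise ParseError(f"{path}: no keypoint rows")
    if df.duplicated(subset=["frame", "joint"]).any():
        raise FormatError(f"{path}: duplicate (frame, joint) rows")
    if ((df["joint"] < 0) | (df["joint"] >= N_JOINTS)).any():
        raise FormatError(f"{path}: joint index outside 0..{N_JOINTS - 1}")

    frame_ids = np.sort(df["frame"].unique())
    n_frames = len(frame_ids)
    index_of = {f: t for t, f in enumerate(frame_ids)}
    xy = np.zeros((n_frames, N_JOINTS, 2))
    conf = np.zeros((n_frames, N_JOINTS))
    rows_t = df["frame"].map(index_of).to_numpy()
    rows_j = df["joint"].to_numpy(dtype=int)
    xy[rows_t, rows_j, 0] = df["x"].to_numpy()
    xy[rows_t, rows_j, 1] = df["y"].to_numpy()
    conf[rows_t, rows_j] = df["confidence"].to_numpy()
    n_filled = n_frames * N_JOINTS - len(df)
    if n_filled:
        logger.warning("%s: %d missing (frame, joint) entries filled as confidence-0",
                       path, n_filled)
    return SkeletonSequence(xy, conf, fps, participant_id,
                            source_id if source_id is not None else path.stem)


def resample_to_snippet_rate(seq: SkeletonSequence,
                             missing_threshold: float = 0.05) -> SkeletonSequence:
    """Resample a sequence to 50 fps by per-coordinate linear interpolation.

    At 50 fps this is the identity.  An output frame interpolated between
    two source frames keeps a joint only if that joint is present in both
    bracketing frames — missingness is never interpolated across.
    """
    if seq.fps == SNIPPET_FPS:
        return seq
    n_src = len(seq)
    if n_src == 0:
        return SkeletonSequence(seq.xy, seq.confidence, SNIPPET_FPS,
                                seq.participant_id, seq.source_id)
    duration = (n_src - 1) / seq.fps
    n_out = int(math.floor(duration * SNIPPET_FPS)) + 1
    t_out = np.arange(n_out) / SNIPPET_FPS * seq.fps  # in source-frame units
    lo = np.clip(np.floor(t_out).astype(int), 0, n_src - 1)
    hi = np.clip(lo + 1, 0, n_src - 1)
    w = (t_out - lo)[:, None, None]
    xy = (1 - w) * seq.xy[lo] + w * seq.xy[hi]
    conf = np.minimum(seq.confidence[lo], seq.confidence[hi])
    # joints missing in either bracket stay missing
    missing = (seq.confidence[lo] < missing_threshold) | (seq.confidence[hi] < missing_threshold)
    conf = np.where(missing, 0.0, conf)
    xy[missing] = 0.0
    return SkeletonSequence(xy, conf, SNIPPET_FPS, seq.participant_id, seq.source_id)


def assemble_snippets(seq: SkeletonSequence, label: Label = Label.UNLABELED) -> list[SkeletonSnippet]:
    """Cut a sequence into consecutive, non-overlapping 250-frame snippets.

    Sequences not at 50 fps are resampled first.  A trailing remainder
    shorter than 250 frames is dropped (logged); a sequence shorter than
    one snippet yields an empty list with a warning.
    """
    seq = resample_to_snippet_rate(seq)
    n = len(seq)
    n_snippets = n // SNIPPET_FRAMES
    if n_snippets == 0:
        logger.warning("%s: only %d frames after resampling; no snippet produced",
                       seq.source_id, n)
        return []
    remainder = n - n_snippets * SNIPPET_FRAMES
    if remainder:
        logger.info("%s: dropping trailing %d-frame remainder", seq.source_id, remainder)
    snippets = []
    for k in range(n_snippets):
        sl = slice(k * SNIPPET_FRAMES, (k + 1) * SNIPPET_FRAMES)
        sub = SkeletonSequence(seq.xy[sl].copy(), seq.confidence[sl].copy(), SNIPPET_FPS,
                               seq.participant_id, seq.source_id)
        snippets.append(SkeletonSnippet(sub, f"{seq.source_id}_{k:04d}", label))
    return snippets


def read_labels_csv(path) -> pd.DataFrame:
    """Read the labels table: ``snippet_id, participant_id, rater_a, rater_b``."""
    df = pd.read_csv(path, dtype={"snippet_id": str, "participant_id": str})
    required = {"snippet_id", "participant_id", "rater_a", "rater_b"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: labels table missing columns {sorted(missing)}")
    df["rater_a"] = df["rater_a"].map(lambda v: Label.coerce(v).value)
    df["rater_b"] = df["rater_b"].map(lambda v: Label.coerce(v).value)
    return df


def rating_pairs_from_labels(df: pd.DataFrame) -> list[RatingPair]:
    return [RatingPair(row.snippet_id, Label.coerce(row.rater_a), Label.coerce(row.rater_b))
            for row in df.itertuples(index=False)]
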