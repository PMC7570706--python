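"""Per-joint pose heatmaps: rendering, stacking, normalization, and I/O.

A movement video enters the pipeline as a :class:`PoseSequence` -- per-frame
2D keypoints with confidences for the first J=15 joints of the BODY-25
layout (head, neck, shoulders, elbows, wrists, mid-hip, hips, knees,
ankles).  Keypoints are converted to per-joint probability heatmaps by
placing an isotropic Gaussian (scaled by the detection confidence) at the
joint location, and the T heatmaps of one joint over a clip are stacked into
the ``W x H x T`` tensor consumed by the trajectory-descriptor stage.

Coordinates are 0-based, pixel-center convention, x rightward, y downward.
Heatmap arrays use numpy image layout ``(H, W)``; a "W x H map" of width W
and height H is an array of shape ``(H, W)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import (
    FormatError,
    InvalidArgumentError,
    InvalidDataError,
    OutOfRangeError,
)

N_JOINTS = 15
BODY25_TOTAL = 25
#: detections below this confidence are treated as missing (occluded) joints
CONF_THRESHOLD = 0.1
DEFAULT_SIGMA = 2.0
DEFAULT_MAP_SIZE = 56


@dataclass
class VideoMeta:
    """Identity and label of one recorded or simulated video."""

    video_id: str = ""
    subject: int = 0
    view: int = 0
    action: str = "synthetic-walk"
    score: int = 0


@dataclass
class PoseSequence:
    """Per-frame 2D joint coordinates + confidence for one video.

    ``joints`` has shape ``(n_frames, 15, 3)`` with columns (x, y,
    confidence); ``frame_size`` is (W, H) in pixels.
    """

    joints: np.ndarray
    frame_size: tuple[int, int]
    meta: VideoMeta = field(default_factory=VideoMeta)

    def __post_init__(self):
        self.joints = np.asarray(self.joints, dtype=np.float64)
        if self.joints.ndim != 3 or self.joints.shape[1] != N_JOINTS or self.joints.shape[2] != 3:
            raise InvalidArgumentError(
                f"joints must be (n_frames, {N_JOINTS}, 3), got {self.joints.shape}"
            )
        if self.joints.shape[0] < 1:
            raise InvalidArgumentError("a pose sequence needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.joints.shape[0])

    def copy(self) -> "PoseSequence":
        return PoseSequence(self.joints.copy(), tuple(self.frame_size),
                            VideoMeta(**vars(self.meta)))


@dataclass
class JointHeatmapClip:
    """Stacked heatmaps of one joint over a T-frame clip; shape (H, W, T)."""

    values: np.ndarray
    joint_id: int
    clip_index: int = 0

    @property
    def T(self) -> int:
        return int(self.values.shape[2])


def render_joint_heatmap(center, confidence: float, frame_size, sigma: float,
                         conf_threshold: float = CONF_THRESHOLD) -> np.ndarray:
    """Gaussian heatmap of one joint: ``confidence * exp(-d^2 / 2 sigma^2)``.

    ``d`` is the distance from each pixel center to ``center``; a detection
    below ``conf_threshold`` yields an all-zero map (missing joint).
    """
    w, h = int(frame_size[0]), int(frame_size[1])
    if sigma <= 0:
        raise InvalidArgumentError(f"sigma must be positive, got {sigma}")
    if w < 8 or h < 8:
        raise InvalidArgumentError(f"degenerate frame size {frame_size}")
    if confidence < conf_threshold:
        return np.zeros((h, w), dtype=np.float64)
    cx, cy = float(center[0]), float(center[1])
    xs = np.arange(w, dtype=np.float64)
    ys = np.arange(h, dtype=np.float64)
    d2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    return confidence * np.exp(-d2 / (2.0 * sigma * sigma))


def render_sequence_heatmaps(seq: PoseSequence, sigma: float = DEFAULT_SIGMA,
                             map_size: int | tuple[int, int] = DEFAULT_MAP_SIZE,
                             conf_threshold: float = CONF_THRESHOLD) -> np.ndarray:
    """Render all joints of all frames at once onto a (possibly smaller) map.

    Joint coordinates are rescaled from ``seq.frame_size`` to ``map_size``
    (W, H).  Returns an array of shape ``(n_frames, 15, H, W)``.  Vectorized
    equivalent of calling :func:`render_joint_heatmap` per joint per frame
    on the rescaled coordinates.
    """
    if isinstance(map_size, int):
        mw = mh = int(map_size)
    else:
        mw, mh = int(map_size[0]), int(map_size[1])
    if sigma <= 0:
        raise InvalidArgumentError(f"sigma must be positive, got {sigma}")
    if mw < 8 or mh < 8:
        raise InvalidArgumentError(f"degenerate map size {(mw, mh)}")
    sw, sh = seq.frame_size
    sx, sy = mw / sw, mh / sh
    cx = seq.joints[:, :, 0] * sx  # (F, J)
    cy = seq.joints[:, :, 1] * sy
    conf = seq.joints[:, :, 2].copy()
    conf[conf < conf_threshold] = 0.0
    xs = np.arange(mw, dtype=np.float64)
    ys = np.arange(mh, dtype=np.float64)
    dx2 = (xs[None, None, None, :] - cx[:, :, None, None]) ** 2
    dy2 = (ys[None, None, :, None] - cy[:, :, None, None]) ** 2
    maps = conf[:, :, None, None] * np.exp(-(dx2 + dy2) / (2.0 * sigma * sigma))
    return maps


def stack_clip(seq: PoseSequence, joint_id: int, frame_range, sigma: float = DEFAULT_SIGMA,
               conf_threshold: float = CONF_THRESHOLD) -> JointHeatmapClip:
    """Stack one joint's heatmaps over the frames of a clip into (H, W, T).

    ``joint_id`` is 1-based (1..15) following the field convention for
    numbering retained joints; ``frame_range`` is an iterable of frame
    indices (e.g. ``range(start, start + T)``).
    """
    if not 1 <= joint_id <= N_JOINTS:
        raise InvalidArgumentError(f"joint_id must be in 1..{N_JOINTS}, got {joint_id}")
    frames = list(frame_range)
    if not frames:
        raise InvalidArgumentError("empty frame range")
    if min(frames) < 0 or max(frames) >= seq.n_frames:
        raise OutOfRangeError(
            f"frame range [{min(frames)}, {max(frames)}] exceeds sequence of "
            f"{seq.n_frames} frames"
        )
    j = joint_id - 1
    slices = [
        render_joint_heatmap(seq.joints[t, j, :2], seq.joints[t, j, 2],
                             seq.frame_size, sigma, conf_threshold)
        for t in frames
    ]
    return JointHeatmapClip(np.stack(slices, axis=2), joint_id)


def normalize_to_image_range(m: np.ndarray) -> np.ndarray:
    """Affine rescale of a map to the 0..255 image intensity range.

    Min maps to 0 and max to 255; an all-constant map (no signal, e.g. a
    fully occluded joint) returns all zeros.
    """
    m = np.asarray(m, dtype=np.float64)
    if not np.all(np.isfinite(m)):
        raise InvalidDataError("map contains NaN or Inf")
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) * (255.0 / (hi - lo))


# ---------------------------------------------------------------------------
# keypoint parsing / serialization
# ---------------------------------------------------------------------------


def parse_keypoint_frames(records, frame_size, meta: VideoMeta | None = None) -> PoseSequence:
    """Build a :class:`PoseSequence` from per-frame keypoint-JSON records.

    Each record follows the BODY-25 keypoint-JSON layout: a dict with a
    ``"people"`` list whose entries hold a flat ``"pose_keypoints_2d"``
    list of (x, y, confidence) triples.  Only the first detected person is
    used; the first 15 of the 25 triples are retained.  A frame with no
    detected person yields 15 zero-confidence joints.
    """
    frames = []
    for idx, rec in enumerate(records):
        if not isinstance(rec, dict) or "people" not in rec:
            raise FormatError("record is not a keypoint dict with a 'people' list", idx)
        people = rec["people"]
        if not people:
            frames.append(np.zeros((N_JOINTS, 3)))
            continue
        kp = people[0].get("pose_keypoints_2d")
        if kp is None or len(kp) < N_JOINTS * 3:
            raise FormatError(
                f"expected >= {N_JOINTS * 3} keypoint values, got "
                f"{0 if kp is None else len(kp)}", idx)
        arr = np.asarray(kp, dtype=np.float64)
        if arr.size % 3 != 0:
            raise FormatError("keypoint list length is not a multiple of 3", idx)
        frames.append(arr.reshape(-1, 3)[:N_JOINTS])
    if not frames:
        raise FormatError("no frames in record list")
    return PoseSequence(np.stack(frames), tuple(frame_size), meta or VideoMeta())


def sequence_to_keypoint_records(seq: PoseSequence) -> list[dict]:
    """Inverse of :func:`parse_keypoint_frames` (15 triples per frame)."""
    out = []
    for t in range(seq.n_frames):
        out.append({
            "version": 1.3,
            "people": [{"pose_keypoints_2d": seq.joints[t].reshape(-1).tolist()}],
        })
    return out


def load_keypoint_dir(path, frame_size, meta: VideoMeta | None = None) -> PoseSequence:
    """Read one JSON file per frame (sorted by name) from a directory."""
    files = sorted(Path(path).glob("*.json"))
    if not files:
        raise FormatError(f"no keypoint JSON files under {path}")
    records = [json.loads(f.read_text()) for f in files]
    return parse_keypoint_frames(records, frame_size, meta)


def write_keypoint_dir(seq: PoseSequence, path) -> None:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    for t, rec in enumerate(sequence_to_keypoint_records(seq)):
        (p / f"frame_{t:06d}_keypoints.json").write_text(json.dumps(rec))


def write_sequence_csv(seq: PoseSequence, path) -> None:
    """Consolidated per-video table: frame, joint, x, y, confidence."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame", "joint", "x", "y", "confidence"])
        for t in range(seq.n_frames):
            for j in range(N_JOINTS):
                x, y, c = seq.joints[t, j]
                wr.writerow([t, j + 1, repr(float(x)), repr(float(y)), repr(float(c))])


def read_sequence_csv(path, frame_size, meta: VideoMeta | None = None) -> PoseSequence:
    rows = []
    with open(path) as fh:
        rd = csv.DictReader(fh)
        for row in rd:
            rows.append((int(row["frame"]), int(row["joint"]),
                         float(row["x"]), float(row["y"]), float(row["confidence"])))
    if not rows:
        raise FormatError(f"empty keypoint table {path}")
    n_frames = max(r[0] for r in rows) + 1
    joints = np.zeros((n_frames, N_JOINTS, 3))
    for t, j, x, y, c in rows:
        if not 1 <= j <= N_JOINTS:
            raise FormatError(f"joint index {j} out of 1..{N_JOINTS}", t)
        joints[t, j - 1] = (x, y, c)
    return PoseSequence(joints, tuple(frame_size), meta or VideoMeta())


# ---------------------------------------------------------------------------
# heatmap clip archive (HDF5)
# ---------------------------------------------------------------------------


def save_clips_hdf5(path, clips_by_video: dict[str, dict[int, np.ndarray]],
                    metas: dict[str, VideoMeta]) -> None:
    """Write clip tensors as ``/video_<id>/joint_<j>`` datasets (H, W, T)."""
    with h5py.File(path, "w") as f:
        for vid, joints in clips_by_video.items():
            grp = f.create_group(f"video_{vid}")
            m = metas[vid]
            grp.attrs.update({"subject": m.subject, "view": m.view,
                              "action": m.action, "score": m.score})
            for j, arr in joints.items():
                grp.create_dataset(f"joint_{j}", data=np.asarray(arr, dtype=np.float32))


def load_clips_hdf5(path):
    """Read back the archive written by :func:`save_clips_hdf5`."""
    clips: dict[str, dict[int, np.ndarray]] = {}
    metas: dict[str, VideoMeta] = {}
    with h5py.File(path, "r") as f:
        for name, grp in f.items():
            vid = name.removeprefix("video_")
            metas[vid] = VideoMeta(video_id=vid, subject=int(grp.attrs["subject"]),
                                   view=int(grp.attrs["view"]),
                                   action=str(grp.attrs["action"]),
                                   score=int(grp.attrs["score"]))
            clips[vid] = {int(k.removeprefix("joint_")): np.asarray(v)
                          for k, v in grp.items()}
    return clips, metas
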