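"""Reading, writing and cleaning per-trial skeletal keypoint streams.

A trial is a JSON file holding an ordered list of frames; each frame carries
17 keypoints ``[x, y, confidence]`` in the common 17-point skeleton where
index 15 is the left foot (ankle) and index 16 the right foot.  Coordinates
are pixels in image convention (origin top-left, y downward); the analysis
downstream is invariant to that choice.

The canonical dialect is

.. code-block:: json

    {"subject_id": "S001", "trial_id": "t2_1",
     "frames": [{"keypoints": [[x, y, c], "... 17 triples ..."]}]}

A tolerant reader also accepts a flat 51-float frame layout
(``[x0, y0, c0, x1, y1, c1, ...]``).  A JSON-Schema document of the dialect
ships in ``gaitvar/schema/keypoints.schema.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InsufficientFramesError, KeypointSchemaError

logger = logging.getLogger(__name__)

N_KEYPOINTS = 17
LEFT_FOOT = 15
RIGHT_FOOT = 16


@dataclass(frozen=True)
class KeypointFrame:
    """One frame: ordinal ``index`` and a (17, 3) array of ``x, y, confidence``."""

    index: int
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_KEYPOINTS, 3):
            raise KeypointSchemaError(
                f"frame {self.index}: expected {N_KEYPOINTS} keypoints, "
                f"got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)


@dataclass
class PoseSequence:
    """An ordered stack of keypoint frames for one walking trial.

    ``keypoints`` has shape ``(n_frames, 17, 3)``; frame ordinals are the
    leading axis (0-based, strictly increasing by construction).
    """

    subject_id: str
    trial_id: str
    keypoints: np.ndarray

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.ndim != 3 or kp.shape[1:] != (N_KEYPOINTS, 3):
            raise KeypointSchemaError(
                f"trial {self.trial_id!r}: keypoint array must have shape "
                f"(n, {N_KEYPOINTS}, 3), got {kp.shape}"
            )
        self.keypoints = kp

    @property
    def n_frames(self) -> int:
        return self.keypoints.shape[0]

    def frame(self, k: int) -> KeypointFrame:
        return KeypointFrame(index=k, points=self.keypoints[k])

    def frames(self) -> list[KeypointFrame]:
        return [self.frame(k) for k in range(self.n_frames)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PoseSequence):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.trial_id == other.trial_id
            and self.keypoints.shape == other.keypoints.shape
            and np.array_equal(self.keypoints, other.keypoints)
        )


@dataclass
class FootTrack:
    """Confidence-filtered coordinate track of one foot.

    ``coords`` is ``(m, 2)``; ``frame_indices`` records which source frames
    survived so gap-spanning displacements can be identified downstream.
    """

    foot_index: int
    coords: np.ndarray
    n_dropped: int
    frame_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.foot_index not in (LEFT_FOOT, RIGHT_FOOT):
            raise ValueError(f"foot_index must be {LEFT_FOOT} or {RIGHT_FOOT}")
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.frame_indices.size == 0 and len(self.coords):
            self.frame_indices = np.arange(len(self.coords))

    def __len__(self) -> int:
        return len(self.coords)


def _frame_to_points(frame_obj: object, k: int) -> np.ndarray:
    """Normalize one raw frame entry to a (17, 3) float array."""
    if isinstance(frame_obj, dict):
        if "keypoints" not in frame_obj:
            raise KeypointSchemaError(f"frame {k}: missing 'keypoints' field")
        raw = frame_obj["keypoints"]
    else:
        raw = frame_obj
    if not isinstance(raw, list):
        raise KeypointSchemaError(f"frame {k}: keypoints must be a JSON array")

    # flat 51-float layout
    if raw and all(isinstance(v, (int, float)) for v in raw):
        if len(raw) != 3 * N_KEYPOINTS:
            raise KeypointSchemaError(
                f"frame {k}: flat layout needs {3 * N_KEYPOINTS} numbers, got {len(raw)}"
            )
        return np.asarray(raw, dtype=float).reshape(N_KEYPOINTS, 3)

    # list-of-triples layout; null entries become confidence-0 placeholders
    pts = []
    for i, entry in enumerate(raw):
        if entry is None:
            pts.append((0.0, 0.0, 0.0))
            continue
        if not isinstance(entry, list) or len(entry) != 3:
            raise KeypointSchemaError(
                f"frame {k}: keypoint {i} must be [x, y, confidence]"
            )
        pts.append(tuple(float(v) for v in entry))
    if len(pts) != N_KEYPOINTS:
        raise KeypointSchemaError(
            f"frame {k}: expected {N_KEYPOINTS} keypoints, got {len(pts)}"
        )
    return np.asarray(pts, dtype=float)


def validate_trial_dict(obj: object) -> None:
    """Structurally validate a decoded trial against the canonical dialect.

    Raises :class:`KeypointSchemaError` on the first violation; the message
    names the offending frame.  This is the executable counterpart of the
    shipped JSON-Schema document.
    """
    if not isinstance(obj, dict):
        raise KeypointSchemaError("top level must be a JSON object")
    if "frames" not in obj or not isinstance(obj["frames"], list):
        raise KeypointSchemaError("top level must contain a 'frames' array")
    for key in ("subject_id", "trial_id"):
        if key in obj and not isinstance(obj[key], str):
            raise KeypointSchemaError(f"'{key}' must be a string")
    for k, frame_obj in enumerate(obj["frames"]):
        pts = _frame_to_points(frame_obj, k)
        conf = pts[:, 2]
        if np.any((conf < 0.0) | (conf > 1.0)):
            raise KeypointSchemaError(
                f"frame {k}: confidences must lie in [0, 1]"
            )


def read_keypoint_json(path: str | Path) -> PoseSequence:
    """Read one trial file into a :class:`PoseSequence`.

    Frames are kept in file order and never silently truncated.  Missing
    (``null``) keypoint entries become ``(0, 0, 0)`` placeholders so a frame
    count mismatch is always an explicit schema error.
    """
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise KeypointSchemaError(
            f"{path}: malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc

    validate_trial_dict(obj)
    frames = obj["frames"]
    if not frames:
        logger.warning("%s: trial contains no frames", path)
        kp = np.empty((0, N_KEYPOINTS, 3))
    else:
        kp = np.stack([_frame_to_points(f, k) for k, f in enumerate(frames)])
    return PoseSequence(
        subject_id=str(obj.get("subject_id", path.stem)),
        trial_id=str(obj.get("trial_id", path.stem)),
        keypoints=kp,
    )


def write_keypoint_json(seq: PoseSequence, path: str | Path) -> Path:
    """Write a trial in the canonical dialect.

    Output is byte-deterministic for a given sequence, and floats use
    shortest round-trip representation so ``read(write(s)) == s`` exactly.
    """
    path = Path(path)
    payload = {
        "subject_id": seq.subject_id,
        "trial_id": seq.trial_id,
        "frames": [
            {"keypoints": [[float(x), float(y), float(c)] for x, y, c in frame]}
            for frame in seq.keypoints
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, separators=(",", ":"))
        fh.write("\n")
    return path


def extract_foot_tracks(
    seq: PoseSequence, min_confidence: float = 0.3
) -> tuple[FootTrack, FootTrack]:
    """Extract confidence-filtered left/right foot tracks.

    A frame is dropped from *both* tracks whenever either foot's confidence
    falls below ``min_confidence``, keeping the two tracks time-aligned.
    ``min_confidence = 0`` is the degenerate no-filtering threshold.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must lie in [0, 1]")
    conf = seq.keypoints[:, (LEFT_FOOT, RIGHT_FOOT), 2]
    keep = (conf >= min_confidence).all(axis=1)
    kept = np.flatnonzero(keep)
    n_dropped = seq.n_frames - kept.size
    if kept.size < 2:
        raise InsufficientFramesError(
            f"trial {seq.trial_id!r}: only {kept.size} frame(s) survive "
            f"confidence filtering at {min_confidence}; need at least 2"
        )
    left = FootTrack(
        LEFT_FOOT, seq.keypoints[kept, LEFT_FOOT, :2], n_dropped, kept
    )
    right = FootTrack(
        RIGHT_FOOT, seq.keypoints[kept, RIGHT_FOOT, :2], n_dropped, kept
    )
    return left, right
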