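"""ByteTrack-style multi-target tracking over per-frame detections.

Tracking-by-detection with a two-stage Hungarian association:

* stage 1 pairs high-confidence detections (conf >= tau_high) with the
  Kalman-predicted boxes of all live tracks;
* stage 2 pairs the remaining low-confidence detections
  (tau_low <= conf < tau_high) with still-unmatched tracks — the rescue step
  that keeps identities alive through occlusions, when a partially hidden
  animal is still detected but scored low.

Matched tracks are Kalman-corrected; unmatched high-confidence detections
spawn tentative tracks; low-confidence detections never spawn tracks; tracks
unmatched for more than ``max_age`` frames die.  Tracks are reported once
they have accumulated ``min_hits`` matches (their full history, including
the tentative frames, is kept).

Everything is deterministic: identical inputs and configuration give
bit-identical output.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import kalman
from .errors import InvalidArgumentError
from .geometry import Box, Detection, iou

__all__ = [
    "TrackStatus",
    "TrackerConfig",
    "Track",
    "ByteTracker",
    "associate",
    "run_tracker",
    "tracks_to_frame",
    "detections_by_frame",
]


class TrackStatus(str, Enum):
    TENTATIVE = "tentative"
    ACTIVE = "active"
    LOST = "lost"
    DEAD = "dead"


@dataclass
class TrackerConfig:
    """Tracking parameters.  The association thresholds are IoU minima below
    which an assignment pair is rejected after the Hungarian step."""

    tau_high: float = 0.5
    tau_low: float = 0.1
    iou_stage1: float = 0.2
    iou_stage2: float = 0.3
    max_age: int = 30
    min_hits: int = 3
    #: enable the stage-2 low-confidence rescue (disable to ablate it)
    byte: bool = True
    #: linearly interpolate coasted frames inside reported track histories
    fill_gaps: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_low <= self.tau_high <= 1.0:
            raise InvalidArgumentError(
                f"need 0 <= tau_low <= tau_high <= 1, got {self.tau_low}, {self.tau_high}"
            )
        for name in ("iou_stage1", "iou_stage2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must lie in [0, 1], got {v}")
        if self.max_age < 1 or self.min_hits < 1:
            raise InvalidArgumentError("max_age and min_hits must be >= 1")


@dataclass
class Track:
    """Identity-labeled trajectory: Kalman state plus per-frame history."""

    id: int
    state: kalman.KalmanState
    history: list[tuple[int, Box, float]] = field(default_factory=list)
    status: TrackStatus = TrackStatus.TENTATIVE
    frames_since_update: int = 0
    hits: int = 0

    def predicted_box(self) -> Box:
        return self.state.box()

    @property
    def frames(self) -> list[int]:
        return [f for f, _, _ in self.history]


def associate(
    track_boxes: list[Box], det_boxes: list[Box], iou_threshold: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Globally optimal track-detection assignment at cost 1 - IoU.

    Pairs whose IoU falls below ``iou_threshold`` are rejected after the
    assignment and reported as unmatched.  Empty inputs yield all-unmatched.
    Matches are returned sorted by track index, which (together with the
    deterministic Hungarian solver) fixes tie-breaking.
    """
    if not track_boxes or not det_boxes:
        return [], list(range(len(track_boxes))), list(range(len(det_boxes)))
    iou_mat = np.array([[iou(t, d) for d in det_boxes] for t in track_boxes])
    rows, cols = linear_sum_assignment(1.0 - iou_mat)
    matches: list[tuple[int, int]] = []
    unmatched_t = set(range(len(track_boxes)))
    unmatched_d = set(range(len(det_boxes)))
    for r, c in zip(rows, cols):
        if iou_mat[r, c] >= iou_threshold and iou_mat[r, c] > 0.0:
            matches.append((int(r), int(c)))
            unmatched_t.discard(int(r))
            unmatched_d.discard(int(c))
    matches.sort()
    return matches, sorted(unmatched_t), sorted(unmatched_d)


class ByteTracker:
    """Stateful frame-by-frame tracker; see the module docstring for the
    association scheme.  Track ids are positive, unique per run and never
    reused."""

    def __init__(self, cfg: TrackerConfig | None = None) -> None:
        self.cfg = cfg if cfg is not None else TrackerConfig()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    # -- single frame -----------------------------------------------------

    def step(self, detections: list[Detection], frame: int) -> list[Track]:
        """Advance one frame: predict, associate in two stages, update
        lifecycles.  Returns the live track list (all statuses)."""
        cfg = self.cfg
        if self._last_frame is not None and frame <= self._last_frame:
            raise InvalidArgumentError(
                f"frames must be strictly increasing, got {frame} after {self._last_frame}"
            )
        self._last_frame = frame

        live = [t for t in self.tracks if t.status != TrackStatus.DEAD]
        for t in live:
            t.state = kalman.kalman_predict(t.state)

        high = [d for d in detections if d.confidence >= cfg.tau_high]
        low = [d for d in detections if cfg.tau_low <= d.confidence < cfg.tau_high]

        track_boxes = [t.predicted_box() for t in live]
        matches, u_tracks, u_high = associate(
            track_boxes, [d.box for d in high], cfg.iou_stage1
        )
        for ti, di in matches:
            self._apply_match(live[ti], high[di], frame)

        if cfg.byte and u_tracks and low:
            rest = [live[i] for i in u_tracks]
            m2, u2, _ = associate(
                [t.predicted_box() for t in rest], [d.box for d in low], cfg.iou_stage2
            )
            for ti, di in m2:
                self._apply_match(rest[ti], low[di], frame)
            u_tracks = [u_tracks[i] for i in u2]

        for i in u_tracks:
            t = live[i]
            t.frames_since_update += 1
            if t.frames_since_update > cfg.max_age:
                t.status = TrackStatus.DEAD
            elif t.status == TrackStatus.ACTIVE:
                t.status = TrackStatus.LOST

        for di in u_high:
            d = high[di]
            t = Track(
                id=self._next_id,
                state=kalman.initiate(d.box),
                history=[(frame, d.box, d.confidence)],
                status=TrackStatus.ACTIVE if cfg.min_hits <= 1 else TrackStatus.TENTATIVE,
                hits=1,
            )
            self._next_id += 1
            self.tracks.append(t)

        return [t for t in self.tracks if t.status != TrackStatus.DEAD]

    def _apply_match(self, track: Track, det: Detection, frame: int) -> None:
        track.state = kalman.kalman_update(track.state, det.box.to_xyah())
        track.history.append((frame, track.state.box(), det.confidence))
        track.hits += 1
        track.frames_since_update = 0
        if track.hits >= self.cfg.min_hits:
            track.status = TrackStatus.ACTIVE

    # -- results ----------------------------------------------------------

    def output(self) -> list[Track]:
        """Confirmed tracks (>= min_hits matches), tentative stragglers
        dropped; histories optionally gap-filled by linear interpolation."""
        out = [t for t in self.tracks if t.hits >= self.cfg.min_hits]
        if self.cfg.fill_gaps:
            out = [replace(t, history=_fill_gaps(t.history)) for t in out]
        return out


def _fill_gaps(history: list[tuple[int, Box, float]]) -> list[tuple[int, Box, float]]:
    """Linear interpolation of box corners (and confidence) across missed
    frames, strictly between observed frames — never extrapolated."""
    if len(history) < 2:
        return list(history)
    filled: list[tuple[int, Box, float]] = [history[0]]
    for (f0, b0, c0), (f1, b1, c1) in zip(history, history[1:]):
        span = f1 - f0
        for f in range(f0 + 1, f1):
            w = (f - f0) / span
            box = Box(
                b0.x1 + w * (b1.x1 - b0.x1),
                b0.y1 + w * (b1.y1 - b0.y1),
                b0.x2 + w * (b1.x2 - b0.x2),
                b0.y2 + w * (b1.y2 - b0.y2),
            )
            filled.append((f, box, min(c0, c1)))
        filled.append((f1, b1, c1))
    return filled


def run_tracker(detections, cfg: TrackerConfig | None = None) -> list[Track]:
    """Track a whole detection stream.

    ``detections`` is either a mapping {frame: [Detection, ...]} or a
    sequence of (frame, [Detection, ...]) pairs with strictly increasing
    frames (unsorted sequences are an error).  Every frame in the covered
    range is processed, so tracks age correctly through empty frames.
    """
    if isinstance(detections, Mapping):
        items = sorted(detections.items())
    else:
        items = list(detections)
        frames = [f for f, _ in items]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise InvalidArgumentError("detection stream frames must be strictly increasing")
    if not items:
        return []
    by_frame = {int(f): list(ds) for f, ds in items}
    tracker = ByteTracker(cfg)
    for f in range(min(by_frame), max(by_frame) + 1):
        tracker.step(by_frame.get(f, []), f)
    return tracker.output()


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to a tidy table (frame, id, x1, y1, x2, y2, conf)."""
    rows = [
        (f, t.id, b.x1, b.y1, b.x2, b.y2, c)
        for t in tracks
        for f, b, c in t.history
    ]
    df = pd.DataFrame(rows, columns=["frame", "id", "x1", "y1", "x2", "y2", "conf"])
    return df.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)


def detections_by_frame(df: pd.DataFrame) -> dict[int, list[Detection]]:
    """Group a detection table (frame, x1, y1, x2, y2, conf) by frame."""
    out: dict[int, list[Detection]] = {}
    for row in df.itertuples(index=False):
        det = Detection(
            frame=int(row.frame),
            box=Box(float(row.x1), float(row.y1), float(row.x2), float(row.y2)),
            confidence=float(row.conf),
        )
        out.setdefault(int(row.frame), []).append(det)
    return out
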