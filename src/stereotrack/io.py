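"""Readers and writers for the MOTChallenge CSV dialects and run artifacts.

MOT files are comma-separated lines

    frame,id,left,top,width,height,conf,<x>,<y>,<z>

with 1-based frames and (left, top, width, height) box geometry.  Internally
frames are 0-based and boxes corner-based; the conversion happens here and
nowhere else.  Ground-truth lines require id >= 1; detection lines carry
id = -1.  Columns 8-10 are written as -1 placeholders for det/track files
and as (class 1, visibility 1.0) for gt files.

All writes are atomic (temp file + rename), so a crashed run never leaves a
half-written table behind.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .amplitude import AmplitudeSeries
from .errors import InvalidArgumentError, ParseError

__all__ = [
    "read_mot",
    "write_mot",
    "read_amplitude_csv",
    "write_amplitude_csv",
    "write_episode_csvs",
    "read_summary_csv",
    "read_episodes_gt",
    "write_json",
    "atomic_write_text",
    "RunConfig",
]

logger = logging.getLogger(__name__)

_MOT_KINDS = ("gt", "det", "track")


def atomic_write_text(path, text: str) -> Path:
    """Write text to ``path`` atomically (temp file in the same directory,
    then rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def read_mot(path, kind: str = "det") -> pd.DataFrame:
    """Parse a MOT-dialect file into a tidy table
    (frame, id, x1, y1, x2, y2, conf) with 0-based frames.

    Malformed lines raise :class:`ParseError` naming the line number.
    Non-monotone frame order is legal but sorted on load with a warning.
    """
    if kind not in _MOT_KINDS:
        raise InvalidArgumentError(f"kind must be one of {_MOT_KINDS}, got {kind!r}")
    path = Path(path)
    rows = []
    last_frame = None
    unsorted = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise ParseError(f"{path}:{lineno}: expected >= 7 fields, got {len(parts)}")
            try:
                frame = int(float(parts[0]))
                tid = int(float(parts[1]))
                left, top, w, h = (float(v) for v in parts[2:6])
                conf = float(parts[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if frame < 1:
                raise ParseError(f"{path}:{lineno}: frames are 1-based, got {frame}")
            if kind == "gt" and tid < 1:
                raise ParseError(f"{path}:{lineno}: gt lines require id >= 1, got {tid}")
            if w < 0 or h < 0:
                raise ParseError(f"{path}:{lineno}: negative box size {w}x{h}")
            if last_frame is not None and frame < last_frame:
                unsorted = True
            last_frame = frame
            rows.append((frame - 1, tid, left, top, left + w, top + h, conf))
    if unsorted:
        logger.warning("%s: frames out of order; sorting on load", path)
    df = pd.DataFrame(rows, columns=["frame", "id", "x1", "y1", "x2", "y2", "conf"])
    return df.sort_values(["frame", "id"], kind="stable").reset_index(drop=True)


def write_mot(path, df: pd.DataFrame, kind: str = "track") -> Path:
    """Write a tidy table (frame, id, x1, y1, x2, y2[, conf]) as a MOT file,
    converting back to 1-based frames and (left, top, width, height)."""
    if kind not in _MOT_KINDS:
        raise InvalidArgumentError(f"kind must be one of {_MOT_KINDS}, got {kind!r}")
    tail = "1,1.0,-1" if kind == "gt" else "-1,-1,-1"
    lines = []
    for row in df.sort_values(["frame", "id"], kind="stable").itertuples(index=False):
        conf = getattr(row, "conf", 1.0)
        lines.append(
            f"{int(row.frame) + 1},{int(row.id)},{row.x1:.4f},{row.y1:.4f},"
            f"{row.x2 - row.x1:.4f},{row.y2 - row.y1:.4f},{conf:.4f},{tail}"
        )
    return atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


def write_amplitude_csv(path, series: list[AmplitudeSeries]) -> Path:
    from .amplitude import amplitude_to_frame

    return atomic_write_text(path, amplitude_to_frame(series).to_csv(index=False))


def read_amplitude_csv(path, fps: float) -> list[AmplitudeSeries]:
    from .amplitude import amplitude_from_frame

    df = pd.read_csv(path)
    required = {"track_id", "part", "t_s", "ratio"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: amplitude CSV needs columns {sorted(required)}")
    return amplitude_from_frame(df, fps)


def write_episode_csvs(episodes_path, summary_path, report) -> tuple[Path, Path]:
    """Write the per-episode table and the per-track summary (with 'None'
    markers for non-stereotypic tracks)."""
    p1 = atomic_write_text(episodes_path, report.to_frame().to_csv(index=False))
    p2 = atomic_write_text(summary_path, report.summary_frame().to_csv(index=False))
    return p1, p2


def read_summary_csv(path) -> dict[int, tuple[float, float] | None]:
    """Read a per-track summary back into {id: (cycle_s, duration_s) | None}."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"track_id", "cycle_time_s", "duration_s"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: summary CSV needs columns {sorted(required)}")
    out: dict[int, tuple[float, float] | None] = {}
    for row in df.itertuples(index=False):
        tid = int(row.track_id)
        if str(row.cycle_time_s).strip().lower() == "none":
            out[tid] = None
        else:
            out[tid] = (float(row.cycle_time_s), float(row.duration_s))
    return out


def read_episodes_gt(path) -> dict[int, tuple[float, float] | None]:
    """Summarise a generator episode table (id, start_s, end_s, period_s)
    to {id: (mean period, total duration)}; ids absent have no episodes."""
    df = pd.read_csv(path)
    required = {"id", "start_s", "end_s", "period_s"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: episode table needs columns {sorted(required)}")
    out: dict[int, tuple[float, float] | None] = {}
    for tid, grp in df.groupby("id"):
        durations = grp["end_s"] - grp["start_s"]
        out[int(tid)] = (float(grp["period_s"].mean()), float(durations.sum()))
    return out


def write_json(path, payload: dict) -> Path:
    return atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated end-to-end run configuration (tracker, amplitude, episode
    and metric parameters plus the seed), loadable from YAML."""

    tracker: "TrackerConfig" = None  # type: ignore[assignment]
    fps: float | None = None
    max_gap_s: float = 1.0
    invert_ratio: bool = False
    smooth_window: int = 0
    episode: "EpisodeConfig" = None  # type: ignore[assignment]
    iou_thr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        from .episodes import EpisodeConfig
        from .tracker import TrackerConfig

        if self.tracker is None:
            self.tracker = TrackerConfig()
        elif isinstance(self.tracker, dict):
            self.tracker = TrackerConfig(**self.tracker)
        if self.episode is None:
            self.episode = EpisodeConfig()
        elif isinstance(self.episode, dict):
            ep = dict(self.episode)
            if "lag_range_s" in ep:
                ep["lag_range_s"] = tuple(ep["lag_range_s"])
            self.episode = EpisodeConfig(**ep)
        if self.fps is not None and self.fps <= 0:
            raise InvalidArgumentError(f"fps must be positive, got {self.fps}")
        if self.max_gap_s < 0:
            raise InvalidArgumentError("max_gap_s must be >= 0")
        if self.smooth_window < 0:
            raise InvalidArgumentError("smooth_window must be >= 0")
        if not 0.0 <= self.iou_thr <= 1.0:
            raise InvalidArgumentError("iou_thr must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        if not isinstance(payload, dict):
            raise ParseError(f"{path}: config must be a YAML mapping")
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ParseError(f"{path}: {exc}") from exc

    def to_yaml(self, path) -> Path:
        payload = asdict(self)
        payload["episode"]["lag_range_s"] = list(payload["episode"]["lag_range_s"])
        return atomic_write_text(path, yaml.safe_dump(payload, sort_keys=True))
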