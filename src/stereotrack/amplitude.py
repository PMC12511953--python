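"""Movement amplitude as a per-track aspect-ratio time series.

For a cage-confined animal whose centroid barely moves, the shape of a
tightly fitted bounding box still changes with every head shake or turn.
The aspect-ratio coefficient (width/height) of the per-frame box is
therefore used as the movement-amplitude signal.  Each track's observed
(frame, ratio) pairs are interpolated with a natural cubic spline and
evaluated on a uniform 1/fps grid; detector dropouts shorter than
``max_gap_s`` are bridged by the spline (and recorded), longer gaps split
the track into separate series.  Nothing is extrapolated beyond the
observed endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import InvalidArgumentError, InvalidDataError
from .tracker import Track

__all__ = [
    "AmplitudeSeries",
    "aspect_series",
    "spline_resample",
    "amplitude_from_tracks",
    "amplitude_to_frame",
    "amplitude_from_frame",
]

logger = logging.getLogger(__name__)

#: minimum observations a contiguous stretch needs for a cubic spline
MIN_SPLINE_POINTS = 4


@dataclass
class AmplitudeSeries:
    """Aspect-ratio coefficient of one track on a uniform time grid.

    ``t`` is in seconds with constant step 1/fps; ``source_gaps`` lists the
    (start_s, end_s) intervals whose values were bridged by the spline
    rather than observed.  ``part`` distinguishes the pieces of a track that
    was split at long detector gaps.
    """

    track_id: int
    fps: float
    t: np.ndarray
    r: np.ndarray
    source_gaps: list[tuple[float, float]] = field(default_factory=list)
    part: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.fps <= 0:
            raise InvalidArgumentError(f"fps must be positive, got {self.fps}")
        if self.t.shape != self.r.shape or self.t.ndim != 1:
            raise InvalidArgumentError("t and r must be 1-D arrays of equal length")
        if len(self.t) > 1:
            steps = np.diff(self.t)
            if not np.allclose(steps, 1.0 / self.fps, atol=1e-6):
                raise InvalidArgumentError("t must be uniform with step 1/fps")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def start_s(self) -> float:
        return float(self.t[0])

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.fps


def aspect_series(track) -> list[tuple[int, float]]:
    """Raw (frame, width/height) pairs for a track.

    Accepts a :class:`~stereotrack.tracker.Track` or an iterable of
    (frame, Box) pairs.  A zero-height box is invalid data and the error
    names the frame (and track id when known).
    """
    if isinstance(track, Track):
        pairs = [(f, b) for f, b, _ in track.history]
        tid = track.id
    else:
        pairs = [(f, b) for f, b in track]
        tid = None
    out = []
    for f, b in pairs:
        if b.height <= 0:
            where = f"frame {f}" + (f" in track {tid}" if tid is not None else "")
            raise InvalidDataError(f"zero-height box at {where}")
        out.append((int(f), b.width / b.height))
    return out


def spline_resample(
    raw: list[tuple[int, float]],
    fps: float,
    max_gap_s: float = 1.0,
    track_id: int = -1,
    invert: bool = False,
    smooth_window: int = 0,
) -> list[AmplitudeSeries]:
    """Natural cubic-spline resampling of raw (frame, ratio) pairs onto the
    uniform 1/fps grid.

    Gaps of at most ``max_gap_s`` are bridged by the spline and recorded in
    ``source_gaps``; longer gaps split the track into separate series
    (``part`` 0, 1, ...).  Stretches with fewer than four observations
    cannot support a cubic spline and are dropped with a logged warning —
    never silently.  ``invert`` analyses height/width instead (sensitivity
    flag); ``smooth_window`` > 1 applies a centered moving average before
    interpolation (off by default: the spline interpolates).
    """
    if fps <= 0:
        raise InvalidArgumentError(f"fps must be positive, got {fps}")
    if max_gap_s < 0:
        raise InvalidArgumentError(f"max_gap_s must be >= 0, got {max_gap_s}")
    raw = sorted(raw)
    frames = np.array([f for f, _ in raw], dtype=int)
    ratios = np.array([r for _, r in raw], dtype=float)
    if len(frames) and np.any(np.diff(frames) <= 0):
        raise InvalidDataError(f"duplicate frames in track {track_id}")
    if invert:
        if np.any(ratios <= 0):
            raise InvalidDataError("cannot invert a non-positive aspect ratio")
        ratios = 1.0 / ratios

    max_gap_frames = max_gap_s * fps
    series: list[AmplitudeSeries] = []
    part = 0
    start = 0
    breakpoints = list(np.nonzero(np.diff(frames) > max_gap_frames)[0] + 1) + [len(frames)]
    for stop in breakpoints:
        f_seg, r_seg = frames[start:stop], ratios[start:stop]
        start = stop
        if len(f_seg) < MIN_SPLINE_POINTS:
            logger.warning(
                "dropping stretch of %d observation(s) (< %d needed for a cubic "
                "spline) in track %d",
                len(f_seg),
                MIN_SPLINE_POINTS,
                track_id,
            )
            continue
        if smooth_window and smooth_window > 1:
            kernel = np.ones(smooth_window) / smooth_window
            padded = np.pad(r_seg, smooth_window // 2, mode="edge")
            r_seg = np.convolve(padded, kernel, mode="valid")[: len(f_seg)]
        spline = CubicSpline(f_seg, r_seg, bc_type="natural")
        grid = np.arange(f_seg[0], f_seg[-1] + 1)
        values = spline(grid)
        observed = np.isin(grid, f_seg)
        gaps = _gap_intervals(grid[~observed], fps)
        series.append(
            AmplitudeSeries(
                track_id=track_id,
                fps=fps,
                t=grid / fps,
                r=values,
                source_gaps=gaps,
                part=part,
            )
        )
        part += 1
    return series


def _gap_intervals(missing_frames: np.ndarray, fps: float) -> list[tuple[float, float]]:
    if len(missing_frames) == 0:
        return []
    runs = np.split(missing_frames, np.nonzero(np.diff(missing_frames) > 1)[0] + 1)
    return [(float(run[0] / fps), float(run[-1] / fps)) for run in runs]


def amplitude_from_tracks(
    tracks: list[Track],
    fps: float,
    max_gap_s: float = 1.0,
    invert: bool = False,
    smooth_window: int = 0,
) -> list[AmplitudeSeries]:
    """Aspect-ratio series for every track (possibly several parts each)."""
    out: list[AmplitudeSeries] = []
    for track in tracks:
        raw = aspect_series(track)
        out.extend(
            spline_resample(
                raw,
                fps,
                max_gap_s=max_gap_s,
                track_id=track.id,
                invert=invert,
                smooth_window=smooth_window,
            )
        )
    return out


def amplitude_to_frame(series: list[AmplitudeSeries]) -> pd.DataFrame:
    """Tidy export: one row per grid point (track_id, part, t_s, ratio)."""
    chunks = [
        pd.DataFrame(
            {"track_id": s.track_id, "part": s.part, "t_s": s.t, "ratio": s.r}
        )
        for s in series
    ]
    if not chunks:
        return pd.DataFrame(columns=["track_id", "part", "t_s", "ratio"])
    return pd.concat(chunks, ignore_index=True)


def amplitude_from_frame(df: pd.DataFrame, fps: float) -> list[AmplitudeSeries]:
    """Rebuild series objects from the tidy export."""
    out = []
    for (tid, part), grp in df.groupby(["track_id", "part"], sort=True):
        grp = grp.sort_values("t_s")
        out.append(
            AmplitudeSeries(
                track_id=int(tid),
                fps=fps,
                t=grp["t_s"].to_numpy(),
                r=grp["ratio"].to_numpy(),
                part=int(part),
            )
        )
    return out
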