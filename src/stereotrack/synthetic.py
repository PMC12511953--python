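"""Seeded generator of ground-truth scenes and corrupted detections.

Emulates the statistical structure of cage-confined animals filmed from a
fixed camera:

* each individual's centroid performs a small, mean-reverting random walk —
  the *small-displacement* regime in which trajectory analysis fails and
  the box aspect ratio carries the movement signal;
* the aspect-ratio coefficient sits at a flat baseline r0 with Gaussian
  jitter, except during stereotypy episodes, where a sinusoid
  r0 + (A/2)*sin(2*pi*t/T) of configurable period and duration is
  superimposed (stereotypy is intermittent; quiescent stretches lack
  fluctuations);
* detections are the ground-truth boxes after random dropout, corner
  jitter, a confidence model with dips during designated occlusion
  windows, and Poisson-rate spurious low-confidence boxes.

Randomness is fully deterministic under the config seed, with one
substream per individual (SeedSequence entropy (seed, individual, role)),
so adding an individual never perturbs the others' realisations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidArgumentError
from .geometry import Box, Detection

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "corrupt_to_detections",
    "write_fixture",
]

#: waveforms available for the episode oscillation
_WAVEFORMS = ("sine", "triangle", "sawtooth")

#: confidence range for spurious (false-positive) boxes
_FP_CONF_RANGE = (0.1, 0.45)


@dataclass
class SceneConfig:
    """Scene parameters; defaults describe the reference synthetic setup
    (25 fps, 60 s, baseline ratio 0.8 with sigma 0.03, one sinusoidal
    episode per individual with period 0.9-4.3 s, duration 4-19 s and 0.4
    peak-to-peak amplitude)."""

    n_individuals: int = 3
    fps: float = 25.0
    duration_s: float = 60.0
    img_w: float = 1920.0
    img_h: float = 1080.0
    base_height_px: float = 120.0
    base_ratio: float = 0.8
    episodes_per_individual: int = 1
    period_range_s: tuple[float, float] = (0.9, 4.3)
    episode_duration_range_s: tuple[float, float] = (4.0, 19.0)
    ratio_amplitude: float = 0.4  # peak-to-peak
    waveform: str = "sine"
    sigma_q: float = 0.03  # quiescent ratio jitter (dimensionless)
    walk_sigma_px: float = 1.0  # centroid random-walk step std (<= 2 px)
    walk_revert: float = 0.95  # mean-reversion factor toward the home point
    sigma_d: float = 1.0  # detection corner jitter std (px)
    p_miss: float = 0.0
    lambda_fp: float = 0.0  # spurious boxes per frame
    conf_mean: float = 0.85
    conf_std: float = 0.05
    occlusions_per_individual: int = 0
    occlusion_duration_s: float = 2.0
    occlusion_conf_mean: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0 or self.fps <= 0 or self.duration_s <= 0:
            raise InvalidArgumentError("n_individuals >= 0 and fps, duration_s > 0 required")
        if self.img_w <= 0 or self.img_h <= 0 or self.base_height_px <= 0:
            raise InvalidArgumentError("image and box dimensions must be positive")
        if self.base_ratio <= 0 or self.ratio_amplitude < 0:
            raise InvalidArgumentError("base_ratio > 0 and ratio_amplitude >= 0 required")
        for name in ("period_range_s", "episode_duration_range_s"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise InvalidArgumentError(f"{name} must be an ordered positive pair")
        for name in ("p_miss",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidArgumentError(f"{name} must lie in [0, 1]")
        if self.lambda_fp < 0 or self.sigma_d < 0 or self.sigma_q < 0:
            raise InvalidArgumentError("noise rates must be nonnegative")
        if self.waveform not in _WAVEFORMS:
            raise InvalidArgumentError(f"waveform must be one of {_WAVEFORMS}")
        if not 0.0 <= self.walk_revert < 1.0:
            raise InvalidArgumentError("walk_revert must lie in [0, 1)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class SceneTruth:
    """Ground truth: per-frame boxes, the episode table, the occlusion
    windows used by the confidence model, and the generating config."""

    boxes: pd.DataFrame  # columns: frame, id, x1, y1, x2, y2
    episodes: pd.DataFrame  # columns: id, start_s, end_s, period_s
    occlusions: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    config: SceneConfig = field(default_factory=SceneConfig)


def _rng(cfg: SceneConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed,) + key))


def _wave(phase: np.ndarray, waveform: str) -> np.ndarray:
    """Unit-amplitude waveform of the given shape, phase in cycles."""
    if waveform == "sine":
        return np.sin(2 * np.pi * phase)
    frac = np.mod(phase, 1.0)
    if waveform == "triangle":
        return 4.0 * np.abs(frac - 0.5) - 1.0
    return 2.0 * frac - 1.0  # sawtooth


def _sample_windows(
    rng: np.random.Generator,
    count: int,
    duration_range: tuple[float, float],
    total_s: float,
    max_tries: int = 200,
) -> list[tuple[float, float]]:
    """Non-overlapping (start, end) windows inside [0, total_s]."""
    windows: list[tuple[float, float]] = []
    for _ in range(count):
        for _ in range(max_tries):
            d = rng.uniform(*duration_range)
            if d >= total_s:
                continue
            s = rng.uniform(0.0, total_s - d)
            if all(s + d <= a or s >= b for a, b in windows):
                windows.append((s, s + d))
                break
    return sorted(windows)


def generate_scene(cfg: SceneConfig) -> SceneTruth:
    """Deterministic ground-truth scene for the given config."""
    n = cfg.n_frames
    t = np.arange(n) / cfg.fps
    rows = []
    episode_rows = []
    occlusions: dict[int, list[tuple[float, float]]] = {}
    # fixed 4x3 slot grid (independent of n_individuals, so adding an
    # individual never moves the others); slots wrap beyond 12
    n_cols, n_rows = 4, 3
    margin = 1.5 * cfg.base_height_px
    for i in range(cfg.n_individuals):
        rng = _rng(cfg, i, 0)
        row, col = divmod(i % (n_cols * n_rows), n_cols)
        home_x = margin + (cfg.img_w - 2 * margin) * (col + 0.5) / n_cols
        home_y = margin + (cfg.img_h - 2 * margin) * (row + 0.5) / n_rows
        home = np.array([home_x, home_y]) + rng.normal(0.0, 2.0, size=2)

        steps = rng.normal(0.0, cfg.walk_sigma_px, size=(n, 2))
        center = np.empty((n, 2))
        center[0] = home + steps[0]
        for k in range(1, n):
            center[k] = home + cfg.walk_revert * (center[k - 1] - home) + steps[k]

        ratio = cfg.base_ratio + rng.normal(0.0, cfg.sigma_q, size=n)
        windows = _sample_windows(
            rng, cfg.episodes_per_individual, cfg.episode_duration_range_s, cfg.duration_s
        )
        for start_s, end_s in windows:
            period = rng.uniform(*cfg.period_range_s)
            mask = (t >= start_s) & (t < end_s)
            phase = (t[mask] - start_s) / period
            ratio[mask] += 0.5 * cfg.ratio_amplitude * _wave(phase, cfg.waveform)
            episode_rows.append((i + 1, start_s, end_s, period))

        occlusions[i + 1] = _sample_windows(
            rng,
            cfg.occlusions_per_individual,
            (cfg.occlusion_duration_s, cfg.occlusion_duration_s),
            cfg.duration_s,
        )

        h = cfg.base_height_px
        w = np.maximum(ratio, 1e-3) * h
        for k in range(n):
            rows.append(
                (
                    k,
                    i + 1,
                    center[k, 0] - w[k] / 2,
                    center[k, 1] - h / 2,
                    center[k, 0] + w[k] / 2,
                    center[k, 1] + h / 2,
                )
            )
    boxes = pd.DataFrame(rows, columns=["frame", "id", "x1", "y1", "x2", "y2"])
    episodes = pd.DataFrame(
        episode_rows, columns=["id", "start_s", "end_s", "period_s"]
    ).sort_values(["id", "start_s"]).reset_index(drop=True)
    return SceneTruth(boxes=boxes, episodes=episodes, occlusions=occlusions, config=cfg)


def corrupt_to_detections(truth: SceneTruth, cfg: SceneConfig | None = None) -> dict[int, list[Detection]]:
    """Detector-style corruption of the ground truth.

    Each box is dropped independently with ``p_miss``; survivors get
    N(0, sigma_d^2) corner jitter and a confidence drawn from the high-mean
    model, dipping to ``occlusion_conf_mean`` inside that individual's
    occlusion windows; Poisson(lambda_fp) spurious low-confidence boxes are
    added per frame.
    """
    cfg = cfg if cfg is not None else truth.config
    n = cfg.n_frames
    out: dict[int, list[Detection]] = {f: [] for f in range(n)}
    for tid, grp in truth.boxes.groupby("id", sort=True):
        i = int(tid) - 1
        rng = _rng(cfg, i, 1)
        occ = truth.occlusions.get(int(tid), [])
        for row in grp.itertuples(index=False):
            f = int(row.frame)
            if rng.uniform() < cfg.p_miss:
                continue
            jitter = rng.normal(0.0, cfg.sigma_d, size=4)
            x1, y1 = row.x1 + jitter[0], row.y1 + jitter[1]
            x2, y2 = row.x2 + jitter[2], row.y2 + jitter[3]
            if x2 < x1:
                x1, x2 = x2, x1
            if y2 < y1:
                y1, y2 = y2, y1
            t_s = f / cfg.fps
            occluded = any(a <= t_s < b for a, b in occ)
            mean = cfg.occlusion_conf_mean if occluded else cfg.conf_mean
            conf = float(np.clip(rng.normal(mean, cfg.conf_std), 0.01, 0.99))
            out[f].append(Detection(frame=f, box=Box(x1, y1, x2, y2), confidence=conf))
    if cfg.lambda_fp > 0:
        rng = _rng(cfg, 2)  # scene-level substream, distinct from per-individual keys
        for f in range(n):
            for _ in range(rng.poisson(cfg.lambda_fp)):
                w = cfg.base_height_px * rng.uniform(0.5, 1.5)
                h = cfg.base_height_px * rng.uniform(0.5, 1.5)
                cx = rng.uniform(w / 2, cfg.img_w - w / 2)
                cy = rng.uniform(h / 2, cfg.img_h - h / 2)
                # spurious boxes score low: below the usual high-confidence gate
                conf = float(rng.uniform(*_FP_CONF_RANGE))
                out[f].append(
                    Detection(
                        frame=f,
                        box=Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2),
                        confidence=conf,
                    )
                )
    return out


def write_fixture(
    truth: SceneTruth, detections: dict[int, list[Detection]], out_dir
) -> dict[str, Path]:
    """Write gt.txt / det.txt (MOT dialect), episodes_gt.csv and the
    generating config; round-trips losslessly through the io module."""
    from . import io as stio  # deferred: io imports geometry only

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gt": out_dir / "gt.txt",
        "det": out_dir / "det.txt",
        "episodes": out_dir / "episodes_gt.csv",
        "config": out_dir / "config.yaml",
    }
    gt = truth.boxes.copy()
    gt["conf"] = 1.0
    stio.write_mot(paths["gt"], gt, kind="gt")
    det_rows = [
        (f, -1, d.box.x1, d.box.y1, d.box.x2, d.box.y2, d.confidence)
        for f, ds in sorted(detections.items())
        for d in ds
    ]
    det_df = pd.DataFrame(det_rows, columns=["frame", "id", "x1", "y1", "x2", "y2", "conf"])
    stio.write_mot(paths["det"], det_df, kind="det")
    stio.atomic_write_text(
        paths["episodes"], truth.episodes.to_csv(index=False)
    )
    cfg_dict = dataclasses.asdict(truth.config)
    for key in ("period_range_s", "episode_duration_range_s"):
        cfg_dict[key] = list(cfg_dict[key])
    stio.atomic_write_text(paths["config"], yaml.safe_dump(cfg_dict, sort_keys=True))
    return paths
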