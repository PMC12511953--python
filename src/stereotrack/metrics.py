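"""Evaluation stack: detection PR/AP/mAP, tracking IDF1/MOTA, behavior MAE.

Detection metrics follow the usual PR-curve construction (greedy matching
by descending confidence at a fixed IoU threshold, all-point interpolation
for AP, mAP the mean over classes).  Tracking metrics follow the
MOTChallenge conventions:

* identity metrics — a single global one-to-one assignment between
  ground-truth and predicted identities maximising the number of correctly
  identified detections IDTP, then
  IDF1 = 2*IDTP / (2*IDTP + IDFP + IDFN);
* CLEAR metrics — per-frame Hungarian matching at the IoU threshold, with
  carry-over preference for the previous frame's correspondence, giving
  MOTA = 1 - (FN + FP + IDSW) / GT, where an identity switch is counted
  when a ground-truth identity's matched predicted identity differs from
  its most recent previous match.

Behavior accuracy is the mean absolute error between predicted and
reference per-individual cycle times and durations, computed over the
individuals that show episodes on both sides; none/episode disagreements
are surfaced separately as a confusion count rather than folded into the
MAE.

Track tables are tidy DataFrames with columns (frame, id, x1, y1, x2, y2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import UndefinedStatisticError
from .geometry import Box, iou

__all__ = [
    "MatchCounts",
    "TrackingMetrics",
    "BehaviorErrors",
    "precision",
    "recall",
    "average_precision",
    "map_score",
    "id_metrics",
    "mota",
    "behavior_mae",
]


@dataclass(frozen=True)
class MatchCounts:
    """Confusion-matrix counts."""

    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise UndefinedStatisticError("match counts must be nonnegative")


@dataclass
class TrackingMetrics:
    """Identity and CLEAR tracking scores plus their raw counts."""

    IDF1: float
    IDP: float
    IDR: float
    Recall: float
    MOTA: float
    FN: int
    FP: int
    IDSW: int
    GT: int
    IDTP: int
    IDFP: int
    IDFN: int


@dataclass
class BehaviorErrors:
    """Cycle/duration MAEs over ids episodic on both sides, plus the
    none/episode confusion counts."""

    cycle_mae_s: float
    duration_mae_s: float
    n_compared: int
    n_agree_none: int
    n_false_alarm: int  # predicted episodes where the reference says none
    n_missed: int  # reference episodes the prediction marked none


def precision(c: MatchCounts) -> float:
    """TP / (TP + FP)."""
    if c.TP + c.FP == 0:
        raise UndefinedStatisticError("precision undefined: TP + FP = 0")
    return c.TP / (c.TP + c.FP)


def recall(c: MatchCounts) -> float:
    """TP / (TP + FN)."""
    if c.TP + c.FN == 0:
        raise UndefinedStatisticError("recall undefined: TP + FN = 0")
    return c.TP / (c.TP + c.FN)


# ---------------------------------------------------------------------------
# detection AP
# ---------------------------------------------------------------------------


def average_precision(detections, gt_boxes, iou_thr: float = 0.5) -> float:
    """Area under the precision-recall curve (all-point interpolation).

    ``detections`` is a sequence of :class:`~stereotrack.geometry.Detection`
    (scored, frame-indexed); ``gt_boxes`` maps frame -> list of Box (or is a
    sequence of (frame, Box) pairs).  Detections are matched greedily by
    descending confidence; each ground-truth box is matched at most once, at
    IoU >= ``iou_thr``.  Invariant to any confidence rescaling that
    preserves rank order.
    """
    if isinstance(gt_boxes, dict):
        gt_by_frame = {f: list(bs) for f, bs in gt_boxes.items()}
    else:
        gt_by_frame = {}
        for f, b in gt_boxes:
            gt_by_frame.setdefault(f, []).append(b)
    n_gt = sum(len(v) for v in gt_by_frame.values())
    if n_gt == 0:
        raise UndefinedStatisticError("AP undefined without ground-truth boxes")

    order = sorted(range(len(detections)), key=lambda i: (-detections[i].confidence, i))
    matched: dict[int, list[bool]] = {f: [False] * len(v) for f, v in gt_by_frame.items()}
    tp = np.zeros(len(order))
    for rank, i in enumerate(order):
        det = detections[i]
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gt_by_frame.get(det.frame, [])):
            if matched[det.frame][j]:
                continue
            v = iou(det.box, g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thr:
            matched[det.frame][best_j] = True
            tp[rank] = 1.0

    if len(order) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    rec = cum_tp / n_gt
    prec = cum_tp / (cum_tp + cum_fp)
    # precision envelope (running max from the right), then sum over recall steps
    env = np.maximum.accumulate(prec[::-1])[::-1]
    prev_r, ap = 0.0, 0.0
    for r, p in zip(rec, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def map_score(per_class_aps) -> float:
    """Mean of per-class APs."""
    aps = list(per_class_aps)
    if not aps:
        raise UndefinedStatisticError("mAP undefined without any class AP")
    return float(np.mean(aps))


# ---------------------------------------------------------------------------
# tracking metrics
# ---------------------------------------------------------------------------


def _boxes_by_id(df: pd.DataFrame) -> dict[int, dict[int, Box]]:
    out: dict[int, dict[int, Box]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(int(row.id), {})[int(row.frame)] = Box(
            float(row.x1), float(row.y1), float(row.x2), float(row.y2)
        )
    return out


def id_metrics(
    gt: pd.DataFrame, pred: pd.DataFrame, iou_thr: float = 0.5
) -> tuple[float, float, float, dict[str, int]]:
    """IDF1, IDP, IDR under the optimal global identity assignment.

    For every (gt identity, predicted identity) pair the number of frames
    where both are present with IoU >= ``iou_thr`` is counted; a one-to-one
    assignment maximising the total (IDTP) is found with the Hungarian
    algorithm.  Returns (IDF1, IDP, IDR, counts).
    """
    gt_tracks = _boxes_by_id(gt)
    pred_tracks = _boxes_by_id(pred)
    n_gt = sum(len(v) for v in gt_tracks.values())
    n_pred = sum(len(v) for v in pred_tracks.values())
    gids = sorted(gt_tracks)
    pids = sorted(pred_tracks)
    idtp = 0
    if gids and pids:
        overlap = np.zeros((len(gids), len(pids)))
        for i, g in enumerate(gids):
            for j, p in enumerate(pids):
                common = gt_tracks[g].keys() & pred_tracks[p].keys()
                overlap[i, j] = sum(
                    1 for f in common if iou(gt_tracks[g][f], pred_tracks[p][f]) >= iou_thr
                )
        rows, cols = linear_sum_assignment(-overlap)
        idtp = int(overlap[rows, cols].sum())
    idfp = n_pred - idtp
    idfn = n_gt - idtp
    idp = idtp / n_pred if n_pred else 0.0
    idr = idtp / n_gt if n_gt else 0.0
    idf1 = 2 * idtp / (2 * idtp + idfp + idfn) if (2 * idtp + idfp + idfn) else 0.0
    return idf1, idp, idr, {"IDTP": idtp, "IDFP": idfp, "IDFN": idfn}


def mota(gt: pd.DataFrame, pred: pd.DataFrame, iou_thr: float = 0.5) -> TrackingMetrics:
    """CLEAR-style MOTA/Recall plus the identity metrics, in one bundle.

    Per frame, previous-frame correspondences still valid at the IoU
    threshold are kept, then the remaining boxes are matched by the
    Hungarian algorithm.  An identity switch is a matched ground-truth
    identity whose predicted identity differs from its most recent previous
    match.  GT is the total number of ground-truth boxes; GT = 0 is
    undefined.
    """
    gt_tracks = _boxes_by_id(gt)
    pred_tracks = _boxes_by_id(pred)
    n_gt = sum(len(v) for v in gt_tracks.values())
    if n_gt == 0:
        raise UndefinedStatisticError("MOTA undefined without ground-truth boxes")

    frames = sorted(
        {f for v in gt_tracks.values() for f in v}
        | {f for v in pred_tracks.values() for f in v}
    )
    fn = fp = idsw = n_matched = 0
    active: dict[int, int] = {}  # gt id -> pred id matched in the previous frame
    last_match: dict[int, int] = {}  # gt id -> most recent matched pred id ever
    for f in frames:
        gt_here = {g: boxes[f] for g, boxes in gt_tracks.items() if f in boxes}
        pred_here = {p: boxes[f] for p, boxes in pred_tracks.items() if f in boxes}
        matches: dict[int, int] = {}
        # carry-over preference
        for g, p in active.items():
            if g in gt_here and p in pred_here and p not in matches.values():
                if iou(gt_here[g], pred_here[p]) >= iou_thr:
                    matches[g] = p
        rest_g = [g for g in sorted(gt_here) if g not in matches]
        rest_p = [p for p in sorted(pred_here) if p not in set(matches.values())]
        if rest_g and rest_p:
            mat = np.array([[iou(gt_here[g], pred_here[p]) for p in rest_p] for g in rest_g])
            rows, cols = linear_sum_assignment(1.0 - mat)
            for r, c in zip(rows, cols):
                if mat[r, c] >= iou_thr:
                    matches[rest_g[r]] = rest_p[c]
        for g, p in matches.items():
            if g in last_match and last_match[g] != p:
                idsw += 1
            last_match[g] = p
        n_matched += len(matches)
        fn += len(gt_here) - len(matches)
        fp += len(pred_here) - len(matches)
        active = matches

    idf1, idp, idr, idc = id_metrics(gt, pred, iou_thr)
    return TrackingMetrics(
        IDF1=idf1,
        IDP=idp,
        IDR=idr,
        Recall=n_matched / n_gt,
        MOTA=1.0 - (fn + fp + idsw) / n_gt,
        FN=fn,
        FP=fp,
        IDSW=idsw,
        GT=n_gt,
        IDTP=idc["IDTP"],
        IDFP=idc["IDFP"],
        IDFN=idc["IDFN"],
    )


# ---------------------------------------------------------------------------
# behavior accuracy
# ---------------------------------------------------------------------------


def behavior_mae(truth, predicted) -> BehaviorErrors:
    """MAE of per-individual cycle time and total duration.

    ``truth`` and ``predicted`` map track id -> (cycle_time_s, duration_s)
    or None (the *none* marker).  Ids marked none on both sides count as
    agreement; mixed none/episode ids are excluded from the MAE and
    reported as confusion counts.  Raises when no id has episodes on both
    sides.
    """
    cycle_errs, dur_errs = [], []
    agree_none = false_alarm = missed = 0
    for tid in sorted(set(truth) | set(predicted)):
        t = truth.get(tid)
        p = predicted.get(tid)
        if t is None and p is None:
            agree_none += 1
        elif t is None:
            false_alarm += 1
        elif p is None:
            missed += 1
        else:
            cycle_errs.append(abs(t[0] - p[0]))
            dur_errs.append(abs(t[1] - p[1]))
    if not cycle_errs:
        raise UndefinedStatisticError(
            "behavior MAE undefined: no track has episodes in both reports"
        )
    return BehaviorErrors(
        cycle_mae_s=float(np.mean(cycle_errs)),
        duration_mae_s=float(np.mean(dur_errs)),
        n_compared=len(cycle_errs),
        n_agree_none=agree_none,
        n_false_alarm=false_alarm,
        n_missed=missed,
    )
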