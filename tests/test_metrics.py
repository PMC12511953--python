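import itertools

import numpy as np
import pandas as pd
import pytest

from stereotrack.errors import UndefinedStatisticError
from stereotrack.geometry import Box, Detection, iou
from stereotrack.metrics import (
    MatchCounts,
    average_precision,
    behavior_mae,
    id_metrics,
    map_score,
    mota,
    precision,
    recall,
)


class TestPrecisionRecall:
    def test_examples(self):
        assert precision(MatchCounts(TP=3, FP=1)) == 0.75
        assert precision(MatchCounts(TP=5)) == 1.0
        assert recall(MatchCounts(TP=5)) == 1.0
        assert precision(MatchCounts(TP=0, FP=4)) == 0.0

    def test_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            precision(MatchCounts(FN=3))
        with pytest.raises(UndefinedStatisticError):
            recall(MatchCounts(FP=3))
        with pytest.raises(UndefinedStatisticError):
            MatchCounts(TP=-1)


def det(frame, x, conf, size=10.0):
    return Detection(frame=frame, box=Box(x, 0, x + size, size), confidence=conf)


class TestAveragePrecision:
    def test_perfect_detections(self):
        gt = {0: [Box(0, 0, 10, 10)], 1: [Box(0, 0, 10, 10)]}
        dets = [det(0, 0, 0.9), det(1, 0, 0.8)]
        assert average_precision(dets, gt) == pytest.approx(1.0)

    def test_rank_of_the_correct_detection_matters(self):
        gt = {0: [Box(0, 0, 10, 10)]}
        correct_first = [det(0, 0, 0.9), det(0, 100, 0.5)]
        correct_second = [det(0, 100, 0.9), det(0, 0, 0.5)]
        assert average_precision(correct_first, gt) == pytest.approx(1.0)
        assert average_precision(correct_second, gt) == pytest.approx(0.5)

    def test_hand_walked_pr_curve(self):
        """Frozen five-detection case walked by hand: ranks T F T F T over
        4 gt boxes -> recall steps at 1/4, 2/4, 3/4 with envelope precision
        1, 2/3, 3/5."""
        gt = {0: [Box(0, 0, 10, 10), Box(20, 0, 30, 10), Box(40, 0, 50, 10), Box(60, 0, 70, 10)]}
        dets = [
            det(0, 0, 0.95),     # TP
            det(0, 100, 0.9),    # FP
            det(0, 20, 0.85),    # TP
            det(0, 140, 0.8),    # FP
            det(0, 40, 0.75),    # TP
        ]
        expected = 0.25 * 1.0 + 0.25 * (2 / 3) + 0.25 * (3 / 5)
        assert average_precision(dets, gt) == pytest.approx(expected, abs=1e-12)

    def test_confidence_rescaling_invariance(self):
        gt = {0: [Box(0, 0, 10, 10), Box(20, 0, 30, 10)]}
        dets = [det(0, 0, 0.9), det(0, 100, 0.6), det(0, 20, 0.3)]
        rescaled = [
            Detection(d.frame, d.box, 0.05 + d.confidence / 2) for d in dets
        ]
        assert average_precision(dets, gt) == average_precision(rescaled, gt)

    def test_each_gt_matched_once(self):
        gt = {0: [Box(0, 0, 10, 10)]}
        dets = [det(0, 0, 0.9), det(0, 1, 0.8)]  # both overlap the one gt
        assert average_precision(dets, gt) == pytest.approx(1.0)  # second is FP at R=1

    def test_no_gt_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            average_precision([det(0, 0, 0.9)], {})

    def test_map_single_class(self):
        assert map_score([0.7]) == 0.7
        assert map_score([0.6, 0.8]) == pytest.approx(0.7)


def brute_force_idtp(gt_tracks, pred_tracks, iou_thr=0.5):
    gids, pids = sorted(gt_tracks), sorted(pred_tracks)
    best = 0
    k = min(len(gids), len(pids))
    for sub in itertools.permutations(pids, k):
        total = 0
        for g, p in zip(gids, sub):
            common = gt_tracks[g].keys() & pred_tracks[p].keys()
            total += sum(
                1 for f in common if iou(gt_tracks[g][f], pred_tracks[p][f]) >= iou_thr
            )
        best = max(best, total)
    return best


def tracks_frame(tracks):
    rows = [
        (f, tid, b.x1, b.y1, b.x2, b.y2)
        for tid, boxes in tracks.items()
        for f, b in boxes.items()
    ]
    return pd.DataFrame(rows, columns=["frame", "id", "x1", "y1", "x2", "y2"])


class TestIdMetrics:
    def test_identical_tracks(self, static_tracks):
        df = static_tracks({1: (range(50), 0.0), 2: (range(50), 200.0)})
        idf1, idp, idr, _ = id_metrics(df, df)
        assert (idf1, idp, idr) == (1.0, 1.0, 1.0)

    def test_constructed_counts(self, static_tracks):
        """IDTP=80, IDFP=20, IDFN=20 -> IDF1 = 160/200 = 0.8."""
        gt = static_tracks({1: (range(100), 0.0)})
        pred_rows = []
        for f in range(100):
            x = 0.0 if f < 80 else 500.0  # last 20 frames far away
            pred_rows.append((f, 7, x, 0.0, x + 40.0, 80.0, 1.0))
        pred = tracks_frame({7: {f: Box(*r[2:6]) for f, r in zip(range(100), pred_rows)}})
        idf1, idp, idr, counts = id_metrics(gt, pred)
        assert counts == {"IDTP": 80, "IDFP": 20, "IDFN": 20}
        assert idf1 == pytest.approx(0.8)

    @pytest.mark.parametrize("n_ids", [2, 3, 4])
    def test_matches_exhaustive_bijections(self, n_ids, rng):
        """Oracle: assignment equals brute-force enumeration for <= 4 ids."""
        for _ in range(10):
            gt_tracks, pred_tracks = {}, {}
            for i in range(n_ids):
                gt_tracks[i + 1] = {
                    f: Box.from_ltwh(100.0 * i + rng.uniform(-5, 5), 0, 40, 80)
                    for f in range(20)
                }
                pred_tracks[i + 101] = {
                    f: Box.from_ltwh(100.0 * rng.integers(0, n_ids) + rng.uniform(-5, 5), 0, 40, 80)
                    for f in range(20)
                }
            gt_df, pred_df = tracks_frame(gt_tracks), tracks_frame(pred_tracks)
            _, _, _, counts = id_metrics(gt_df, pred_df)
            assert counts["IDTP"] == brute_force_idtp(gt_tracks, pred_tracks)


class TestMOTA:
    def test_perfect_tracking(self, static_tracks):
        df = static_tracks({1: (range(60), 0.0), 2: (range(60), 300.0)})
        tm = mota(df, df)
        assert tm.MOTA == pytest.approx(1.0)
        assert tm.IDSW == 0
        assert tm.Recall == pytest.approx(1.0)

    def test_constructed_error_counts(self, static_tracks):
        """GT=100, FN=5, FP=3, IDSW=2 -> MOTA = 0.9 exactly."""
        gt = static_tracks({1: (range(100), 0.0)})
        rows = []
        for f in range(95):  # frames 95-99 missing -> FN = 5
            pid = 1 if f < 40 else (2 if f < 70 else 3)  # two identity switches
            rows.append((f, pid, 0.0, 0.0, 40.0, 80.0, 1.0))
        for f in range(3):  # three far-away spurious boxes -> FP = 3
            rows.append((f, 9, 800.0, 0.0, 840.0, 80.0, 1.0))
        pred = pd.DataFrame(rows, columns=["frame", "id", "x1", "y1", "x2", "y2", "conf"])
        tm = mota(gt, pred)
        assert (tm.FN, tm.FP, tm.IDSW, tm.GT) == (5, 3, 2, 100)
        assert tm.MOTA == pytest.approx(0.9, abs=1e-12)

    def test_single_swap_counts_once(self, static_tracks):
        gt = static_tracks({1: (range(50), 0.0)})
        rows = [(f, 1 if f < 25 else 2, 0.0, 0.0, 40.0, 80.0, 1.0) for f in range(50)]
        pred = pd.DataFrame(rows, columns=["frame", "id", "x1", "y1", "x2", "y2", "conf"])
        assert mota(gt, pred).IDSW == 1

    def test_time_reversal_symmetry_without_switches(self, static_tracks, rng):
        gt = static_tracks({1: (range(40), 0.0), 2: (range(40), 250.0)})
        pred = gt.copy()
        pred["x1"] += rng.uniform(-2, 2, len(pred))
        pred["x2"] = pred["x1"] + 40.0
        fwd = mota(gt, pred)
        rev_gt = gt.assign(frame=39 - gt["frame"])
        rev_pred = pred.assign(frame=39 - pred["frame"])
        rev = mota(rev_gt, rev_pred)
        assert fwd.MOTA == pytest.approx(rev.MOTA)
        assert fwd.IDSW == rev.IDSW == 0

    def test_no_gt_undefined(self, static_tracks):
        pred = static_tracks({1: (range(5), 0.0)})
        with pytest.raises(UndefinedStatisticError):
            mota(pred.iloc[0:0], pred)

    def test_carry_over_prevents_spurious_switches(self):
        """Two gt boxes drift close together; the previous-frame match must
        be preferred over a marginally better crossing."""
        rows_gt, rows_pred = [], []
        for f in range(30):
            xa, xb = 0.0 + 0.5 * f, 60.0 - 0.5 * f  # approach each other
            rows_gt += [(f, 1, xa, 0, xa + 40, 80, 1.0), (f, 2, xb, 0, xb + 40, 80, 1.0)]
            rows_pred += [(f, 11, xa, 0, xa + 40, 80, 1.0), (f, 12, xb, 0, xb + 40, 80, 1.0)]
        cols = ["frame", "id", "x1", "y1", "x2", "y2", "conf"]
        tm = mota(pd.DataFrame(rows_gt, columns=cols), pd.DataFrame(rows_pred, columns=cols))
        assert tm.IDSW == 0
        assert tm.MOTA == pytest.approx(1.0)


class TestBehaviorMAE:
    def test_identical_reports(self):
        report = {1: (1.5, 10.0), 2: None}
        errs = behavior_mae(report, dict(report))
        assert errs.cycle_mae_s == 0.0
        assert errs.duration_mae_s == 0.0
        assert errs.n_agree_none == 1

    def test_hand_example(self):
        truth = {1: (1.0, 5.0), 2: (2.0, 8.0)}
        pred = {1: (1.2, 5.5), 2: (1.8, 7.5)}
        errs = behavior_mae(truth, pred)
        assert errs.cycle_mae_s == pytest.approx(0.2)
        assert errs.duration_mae_s == pytest.approx(0.5)

    def test_mixed_markers_excluded_but_counted(self):
        truth = {1: (1.0, 5.0), 2: None, 3: (2.0, 6.0)}
        pred = {1: (1.0, 5.0), 2: (0.9, 3.0), 3: None}
        errs = behavior_mae(truth, pred)
        assert errs.n_compared == 1
        assert errs.n_false_alarm == 1
        assert errs.n_missed == 1
        assert errs.cycle_mae_s == 0.0

    def test_no_overlap_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            behavior_mae({1: None}, {1: None})
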