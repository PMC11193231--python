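"""Evaluation mathematics against brute-force PR-staircase and pixel oracles."""

import numpy as np
import pytest

from gazewalk import (
    CornerBox,
    Detection,
    MaskImage,
    average_precision,
    confusion_matrix,
    map50,
    mask_iou,
    match_detections,
    mean_mask_iou,
)


def det(label, box, conf=1.0):
    return Detection(CornerBox(*box), label, conf)


def unit_truth(i, label="hurdle"):
    """Disjoint unit-square ground-truth boxes indexed by i."""
    return det(label, (10 * i, 0, 10 * i + 1, 1), 1.0)


def staircase_ap_oracle(flags, n_truth):
    """All-point AP by direct enumeration of the PR staircase.

    For each recall level k/n_truth, takes the maximum precision over all
    ranked prefixes achieving at least k true positives.
    """
    if n_truth == 0:
        raise ValueError
    prefix = []
    tp = fp = 0
    for is_tp in flags:
        tp += int(is_tp)
        fp += int(not is_tp)
        prefix.append((tp, tp / (tp + fp)))
    ap = 0.0
    for k in range(1, n_truth + 1):
        precs = [p for t, p in prefix if t >= k]
        ap += (max(precs) if precs else 0.0) / n_truth
    return ap


class TestMatchDetections:
    def test_single_match(self):
        t = [det("hurdle", (0, 0, 10, 10))]
        p = [det("hurdle", (0, 0, 10, 6), 0.9)]  # IoU 0.6
        ms = match_detections(p, t)
        assert ms.n_tp == 1 and not ms.false_positives and not ms.false_negatives

    def test_duplicate_prediction_is_fp(self):
        t = [det("hurdle", (0, 0, 10, 10))]
        p = [det("hurdle", (0, 0, 10, 9), 0.7), det("hurdle", (0, 0, 10, 10), 0.9)]
        ms = match_detections(p, t)
        assert ms.n_tp == 1
        assert ms.matches[0][0].confidence == 0.9  # higher confidence claims the truth
        assert len(ms.false_positives) == 1

    def test_class_strict(self):
        t = [det("hurdle", (0, 0, 10, 10))]
        p = [det("support", (0, 0, 10, 10), 0.9)]
        ms = match_detections(p, t)
        assert ms.n_tp == 0 and len(ms.false_positives) == 1 and len(ms.false_negatives) == 1

    def test_conservation(self, rng):
        for _ in range(100):
            t = [unit_truth(i) for i in range(int(rng.integers(0, 5)))]
            slots = rng.integers(0, 6, size=int(rng.integers(0, 5)))
            p = [
                det("hurdle", (10 * int(s), 0, 10 * int(s) + 1, 1), float(rng.uniform(0, 1)))
                for s in slots
            ]
            ms = match_detections(p, t)
            assert ms.n_tp + len(ms.false_negatives) == len(t)
            assert ms.n_tp + len(ms.false_positives) == len(p)


class TestAveragePrecision:
    def test_perfect_detector(self):
        truths = [[unit_truth(0), unit_truth(1)]]
        assert average_precision(truths, truths, "hurdle") == pytest.approx(1.0)

    def test_tp_then_fp_is_one(self):
        truths = [[unit_truth(0)]]
        preds = [[det("hurdle", (0, 0, 1, 1), 0.9), det("hurdle", (50, 50, 51, 51), 0.8)]]
        assert average_precision(preds, truths, "hurdle") == pytest.approx(1.0)

    def test_fp_then_tp_is_half(self):
        truths = [[unit_truth(0)]]
        preds = [[det("hurdle", (50, 50, 51, 51), 0.9), det("hurdle", (0, 0, 1, 1), 0.8)]]
        assert average_precision(preds, truths, "hurdle") == pytest.approx(0.5)

    def test_no_matched_predictions_is_zero(self):
        truths = [[unit_truth(0)]]
        preds = [[det("hurdle", (50, 50, 51, 51), 0.9)]]
        assert average_precision(preds, truths, "hurdle") == 0.0

    def test_matches_staircase_oracle_exhaustively(self, rng):
        # random scenarios with <= 6 predictions on disjoint unit truths
        for _ in range(1000):
            n_truth = int(rng.integers(1, 4))
            truths = [[unit_truth(i) for i in range(n_truth)]]
            preds = []
            claims = []
            for _ in range(int(rng.integers(0, 7))):
                slot = int(rng.integers(0, n_truth + 2))
                conf = float(rng.uniform(0, 1))
                preds.append(det("hurdle", (10 * slot, 0, 10 * slot + 1, 1), conf))
                claims.append(slot)
            got = average_precision([preds], truths, "hurdle")
            # independent flags: highest-confidence prediction per real slot is TP
            order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
            taken = set()
            flags = []
            for i in order:
                slot = claims[i]
                if slot < n_truth and slot not in taken:
                    taken.add(slot)
                    flags.append(True)
                else:
                    flags.append(False)
            assert got == pytest.approx(staircase_ap_oracle(flags, n_truth), abs=1e-12)


class TestMap50:
    def frames(self, rng, n=20):
        out = []
        for _ in range(n):
            frame = []
            for i in range(int(rng.integers(1, 5))):
                label = ["hurdle", "tennis_ball", "support"][int(rng.integers(0, 3))]
                frame.append(det(label, (20 * i, 0, 20 * i + 10, 10), 1.0))
            out.append(frame)
        return out

    def test_oracle_detector_scores_one(self, rng, taxonomy):
        truths = self.frames(rng)
        summary = map50(truths, truths, taxonomy)
        assert summary.map50 == pytest.approx(1.0)
        assert summary.precision == pytest.approx(1.0)
        assert summary.recall == pytest.approx(1.0)

    def test_deleted_predictions_reduce_recall_only(self, rng, taxonomy):
        truths = self.frames(rng)
        kept = total = 0
        preds = []
        for frame in truths:
            keep = [d for d in frame if rng.random() > 0.2]
            kept += len(keep)
            total += len(frame)
            preds.append(keep)
        summary = map50(preds, truths, taxonomy)
        assert summary.precision == pytest.approx(1.0)
        assert summary.recall == pytest.approx(kept / total)

    def test_shifted_labels_score_zero(self, rng, taxonomy):
        truths = self.frames(rng)
        shift = {"hurdle": "tennis_ball", "tennis_ball": "support", "support": "hurdle"}
        preds = [
            [det(shift[d.class_label], (d.box.x1, d.box.y1, d.box.x2, d.box.y2), 1.0) for d in f]
            for f in truths
        ]
        summary = map50(preds, truths, taxonomy)
        assert summary.map50 == 0.0
        assert summary.recall == 0.0

    def test_empty_truth_rejected(self, taxonomy):
        with pytest.raises(ValueError, match="nothing to evaluate"):
            map50([[]], [[]], taxonomy)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self, rng, taxonomy):
        truths = [[unit_truth(0, "hurdle"), unit_truth(1, "bucket")]]
        cm = confusion_matrix(truths, truths, taxonomy)
        assert cm.cell("hurdle", "hurdle") == 1
        assert cm.cell("bucket", "bucket") == 1
        assert cm.counts.sum() == 2
        assert cm.counts[cm.background_index, :].sum() == 0
        assert cm.counts[:, cm.background_index].sum() == 0

    def test_misclassification_lands_off_diagonal(self, taxonomy):
        truths = [[det("hurdle", (0, 0, 10, 10))]]
        preds = [[det("support", (0, 0, 10, 8), 0.9)]]  # IoU 0.8, wrong class
        cm = confusion_matrix(preds, truths, taxonomy)
        assert cm.cell("hurdle", "support") == 1
        assert cm.counts.sum() == 1

    def test_missed_truth_goes_to_background(self, taxonomy):
        truths = [[det("hurdle", (0, 0, 10, 10))]]
        cm = confusion_matrix([[]], truths, taxonomy)
        assert cm.cell("hurdle", None) == 1

    def test_low_confidence_predictions_dropped(self, taxonomy):
        truths = [[det("hurdle", (0, 0, 10, 10))]]
        preds = [[det("hurdle", (0, 0, 10, 10), 0.1)]]
        cm = confusion_matrix(preds, truths, taxonomy, conf_threshold=0.25)
        assert cm.cell("hurdle", "hurdle") == 0
        assert cm.cell("hurdle", None) == 1

    def test_total_conservation(self, rng, taxonomy):
        for _ in range(50):
            truths = [[unit_truth(i, "hurdle") for i in range(int(rng.integers(0, 4)))]]
            slots = rng.integers(0, 5, size=int(rng.integers(0, 4)))
            preds = [[
                det("hurdle" if rng.random() > 0.3 else "support",
                    (10 * int(s), 0, 10 * int(s) + 1, 1), float(rng.uniform(0.3, 1.0)))
                for s in slots
            ]]
            cm = confusion_matrix(preds, truths, taxonomy)
            ms_like = cm.counts[: cm.background_index, : cm.background_index].sum()
            fp = cm.counts[cm.background_index, :].sum()
            fn = cm.counts[:, cm.background_index].sum()
            assert ms_like + fp + fn == cm.counts.sum()
            assert ms_like + fp == len(preds[0])
            assert ms_like + fn == len(truths[0])


class TestMaskIou:
    def test_identical(self, rng):
        px = rng.random((20, 30)) > 0.5
        assert mask_iou(MaskImage(px), MaskImage(px.copy())) == 1.0

    def test_disjoint(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:5] = True
        b[5:] = True
        assert mask_iou(MaskImage(a), MaskImage(b)) == 0.0

    def test_left_half_vs_three_quarters(self):
        truth = np.zeros((100, 100), bool)
        truth[:, :50] = True
        pred = np.zeros((100, 100), bool)
        pred[:, :75] = True
        assert mask_iou(MaskImage(pred), MaskImage(truth)) == pytest.approx(2 / 3)

    def test_both_empty_convention(self):
        e = MaskImage(np.zeros((5, 5), bool))
        assert mask_iou(e, e) == 1.0

    def test_symmetric_and_matches_pixel_count(self, rng):
        for _ in range(100):
            a = rng.random((16, 16)) > 0.6
            b = rng.random((16, 16)) > 0.6
            ma, mb = MaskImage(a), MaskImage(b)
            inter = int(np.sum(a & b))
            union = int(np.sum(a | b))
            expected = inter / union if union else 1.0
            assert mask_iou(ma, mb) == pytest.approx(expected)
            assert mask_iou(ma, mb) == mask_iou(mb, ma)

    def test_matches_rasterized_box_iou(self, rng):
        from gazewalk import box_iou

        for _ in range(200):
            def rand_box():
                x1, x2 = sorted(rng.integers(0, 30, 2).tolist())
                y1, y2 = sorted(rng.integers(0, 30, 2).tolist())
                return CornerBox(float(x1), float(y1), float(x2), float(y2))

            a, b = rand_box(), rand_box()
            ma = np.zeros((30, 30), bool)
            mb = np.zeros((30, 30), bool)
            ma[int(a.y1):int(a.y2), int(a.x1):int(a.x2)] = True
            mb[int(b.y1):int(b.y2), int(b.x1):int(b.x2)] = True
            if a.area > 0 or b.area > 0:
                assert mask_iou(MaskImage(ma), MaskImage(mb)) == pytest.approx(
                    box_iou(a, b), abs=1e-12
                )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mask_iou(MaskImage(np.ones((2, 2), bool)), MaskImage(np.ones((3, 3), bool)))

    def test_mean_mask_iou(self):
        a = MaskImage(np.ones((4, 4), bool))
        h = MaskImage(np.concatenate([np.ones((2, 4), bool), np.zeros((2, 4), bool)]))
        assert mean_mask_iou([a, a], [a, h]) == pytest.approx((1.0 + 0.5) / 2)
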