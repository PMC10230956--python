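"""COCO-style evaluation: P/R/F1, AP per IoU threshold, mAP, scale strata.

Matching is greedy on mask IoU, highest-scored detection first, one match
per ground-truth instance.  AP at an IoU threshold is the 101-point
interpolated area under the precision-recall curve (precision envelope
sampled at recalls 0, 0.01, ..., 1.0); mAP averages AP over the ten
thresholds 0.50, 0.55, ..., 0.95.  Scale-stratified variants restrict
ground truth to an area band; detections matched to out-of-band ground
truth are ignored, as are unmatched detections whose own area falls
outside the band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .coco_io import InstanceAnnotation
from .mask_decode import Detection
from .synthetic import area_cutoffs

IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 1.0, 0.05), 2))
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ap_iou: dict[float, float]
    map: float
    map_small: float
    map_medium: float
    map_large: float
    undefined_strata: list[str] = field(default_factory=list)
    pr_curves: dict[float, tuple[list[float], list[float]]] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        doc["ap_iou"] = {str(k): v for k, v in doc["ap_iou"].items()}
        doc["pr_curves"] = {str(k): v for k, v in doc["pr_curves"].items()}
        text = json.dumps(doc, indent=2)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = [
            f"TP={self.tp} FP={self.fp} FN={self.fn}",
            f"P={self.precision:.4f} R={self.recall:.4f} F1={self.f1:.4f}",
            f"mAP={self.map:.4f}  AP50={self.ap_iou[0.5]:.4f}  AP75={self.ap_iou[0.75]:.4f}",
            f"mAP_S={self.map_small:.4f} mAP_M={self.map_medium:.4f} mAP_L={self.map_large:.4f}",
        ]
        return "\n".join(lines)


def _mask_iou_pairs(dets: list[Detection], gts: list[InstanceAnnotation]) -> np.ndarray:
    if not dets or not gts:
        return np.zeros((len(dets), len(gts)))
    d = np.stack([x.mask for x in dets]).reshape(len(dets), -1).astype(np.float64)
    g = np.stack([x.mask for x in gts]).reshape(len(gts), -1).astype(np.float64)
    inter = d @ g.T
    union = d.sum(1)[:, None] + g.sum(1)[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def _match_image(iou: np.ndarray, dets: list[Detection],
                 gts: list[InstanceAnnotation], thr: float,
                 area_range: tuple[float, float]
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy match; returns per-detection (is_tp, is_ignored) and n_gt.

    Detections arrive score-sorted.  Each detection takes the unmatched
    same-category ground truth of highest IoU >= thr, preferring in-band
    ground truth; a detection whose only match is out-of-band, or which is
    unmatched with out-of-band area, is ignored.
    """
    lo, hi = area_range
    gt_ignored = np.array([not (lo <= g.area < hi) for g in gts], dtype=bool)
    n_gt = int((~gt_ignored).sum())
    taken = np.zeros(len(gts), dtype=bool)
    is_tp = np.zeros(len(dets), dtype=bool)
    ignored = np.zeros(len(dets), dtype=bool)
    for di, det in enumerate(dets):
        best, best_iou = -1, thr
        best_ign, best_ign_iou = -1, thr
        for gi, gt in enumerate(gts):
            if taken[gi] or gt.category_id != det.category:
                continue
            v = iou[di, gi]
            if gt_ignored[gi]:
                if v >= best_ign_iou:
                    best_ign, best_ign_iou = gi, v
            elif v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            taken[best] = True
            is_tp[di] = True
        elif best_ign >= 0:
            taken[best_ign] = True
            ignored[di] = True
        else:
            det_area = int(det.mask.sum())
            if not (lo <= det_area < hi):
                ignored[di] = True
    return is_tp, ignored, n_gt


def _average_precision(scores: np.ndarray, is_tp: np.ndarray, n_gt: int
                       ) -> tuple[float, np.ndarray]:
    """101-point interpolated AP from flat (score, tp) detection lists."""
    if n_gt == 0:
        return 0.0, np.zeros_like(RECALL_GRID)
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(is_tp[order])
    fp = np.cumsum(~is_tp[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope (monotone non-increasing from the right)
    env = np.maximum.accumulate(precision[::-1])[::-1]
    sampled = np.zeros_like(RECALL_GRID)
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    valid = idx < len(env)
    sampled[valid] = env[idx[valid]]
    return float(sampled.mean()), sampled


def evaluate(detections: list[list[Detection]],
             ground_truth: list[list[InstanceAnnotation]],
             image_size: tuple[int, int],
             iou_thresholds: tuple[float, ...] = IOU_THRESHOLDS) -> EvalReport:
    """Score predictions against ground truth over a set of images."""
    if len(detections) != len(ground_truth):
        raise ValueError("detections and ground truth must align per image")
    ious = [_mask_iou_pairs(sorted(d, key=lambda x: -x.score), g)
            for d, g in zip(detections, ground_truth)]
    dets_sorted = [sorted(d, key=lambda x: -x.score) for d in detections]

    small_cut, med_cut = area_cutoffs(image_size)
    strata = {
        "all": (0.0, np.inf),
        "small": (0.0, small_cut),
        "medium": (small_cut, med_cut),
        "large": (med_cut, np.inf),
    }

    def run(thr: float, area_range) -> tuple[float, np.ndarray, tuple[int, int, int]]:
        all_scores, all_tp = [], []
        n_gt_total, n_tp, n_fp = 0, 0, 0
        for dets, gts, iou in zip(dets_sorted, ground_truth, ious):
            is_tp, ignored, n_gt = _match_image(iou, dets, gts, thr, area_range)
            n_gt_total += n_gt
            use = ~ignored
            all_scores.extend(d.score for d, u in zip(dets, use) if u)
            all_tp.extend(is_tp[use])
            n_tp += int(is_tp.sum())
            n_fp += int((use & ~is_tp).sum())
        ap, curve = _average_precision(np.asarray(all_scores),
                                       np.asarray(all_tp, dtype=bool), n_gt_total)
        return ap, curve, (n_tp, n_fp, n_gt_total - n_tp)

    ap_iou, pr_curves = {}, {}
    counts_50 = (0, 0, 0)
    for thr in iou_thresholds:
        ap, curve, counts = run(thr, strata["all"])
        ap_iou[float(thr)] = ap
        pr_curves[float(thr)] = (RECALL_GRID.tolist(), curve.tolist())
        if abs(thr - 0.5) < 1e-9:
            counts_50 = counts
    mean_ap = float(np.mean(list(ap_iou.values())))

    undefined = []
    if sum(len(g) for g in ground_truth) == 0:
        undefined.append("all")
    strata_map = {}
    for name in ("small", "medium", "large"):
        aps = [run(thr, strata[name])[0] for thr in iou_thresholds]
        has_gt = any(strata[name][0] <= g.area < strata[name][1]
                     for gts in ground_truth for g in gts)
        if not has_gt:
            undefined.append(name)
        strata_map[name] = float(np.mean(aps))

    tp, fp, fn = counts_50
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
                      f1=f1, ap_iou=ap_iou, map=mean_ap,
                      map_small=strata_map["small"],
                      map_medium=strata_map["medium"],
                      map_large=strata_map["large"],
                      undefined_strata=undefined, pr_curves=pr_curves)


def pr_curves_to_csv(report: EvalReport, path) -> None:
    """Export the per-threshold PR curves as a single CSV."""
    from pathlib import Path
    lines = ["iou_threshold,recall,precision"]
    for thr, (recs, precs) in sorted(report.pr_curves.items()):
        for r, p in zip(recs, precs):
            lines.append(f"{thr},{r},{p}")
    Path(path).write_text("\n".join(lines) + "\n")
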