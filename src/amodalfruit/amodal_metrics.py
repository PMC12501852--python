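"""Instance-level evaluation statistics for amodal segmentation.

Metrics follow the standard amodal-evaluation toolbox:

* pixel Precision / Recall / F1 between binary masks,
* **F@.75** — the fraction of ground-truth instances whose optimally
  matched prediction reaches pixel F1 >= 0.75, with the one-to-one
  matching chosen by the Hungarian algorithm to maximise total F1
  (greedy matching is *not* equivalent and is guarded against in the
  tests),
* **mIoU** — mean intersection-over-union; in the default *instance*
  mode matched pairs contribute their IoU, unmatched ground truths
  contribute 0, and the mean is taken per class then across classes;
  a *semantic* mode aggregates pixels per class (plus background),
* **AP / mAP** — area under the 101-point interpolated precision-recall
  curve at a mask-IoU matching threshold, with mAP the mean AP over IoU
  thresholds 0.50:0.05:0.95.

All statistics live in [0, 1]; callers multiply by 100 for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .amodal_masks import OCCLUSION_BINS, InstanceMasks, bin_occlusion

__all__ = [
    "UndefinedMetricError",
    "MatchMatrix",
    "EvalReport",
    "pixel_f1",
    "pixel_precision_recall_f1",
    "mask_iou",
    "build_match_matrix",
    "f_at_075",
    "miou",
    "average_precision",
    "mean_ap",
    "evaluate_frame",
    "evaluate_dataset",
    "AP_THRESHOLDS",
]

AP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


class UndefinedMetricError(ValueError):
    """The statistic is undefined (e.g. no ground-truth instances)."""


def _as_bool(m) -> np.ndarray:
    return np.asarray(m).astype(bool)


# ---------------------------------------------------------------------------
# Pairwise pixel statistics
# ---------------------------------------------------------------------------

def pixel_precision_recall_f1(pred, gt) -> Tuple[float, float, float]:
    """TP/FP/FN pixel counts -> (precision, recall, F1).

    Empty-vs-empty is a perfect (vacuous) match: all three are 1.
    """
    a, b = _as_bool(pred), _as_bool(gt)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    if tp == fp == fn == 0:
        return 1.0, 1.0, 1.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn)
    return precision, recall, f1


def pixel_f1(pred, gt) -> float:
    return pixel_precision_recall_f1(pred, gt)[2]


def mask_iou(pred, gt) -> float:
    a, b = _as_bool(pred), _as_bool(gt)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


# ---------------------------------------------------------------------------
# Hungarian matching
# ---------------------------------------------------------------------------

@dataclass
class MatchMatrix:
    """Pairwise pixel-F1 matrix and the optimal one-to-one assignment."""

    f1: np.ndarray                       # (|preds|, |gts|)
    pairs: List[Tuple[int, int]]         # matched (pred_idx, gt_idx)
    n_gt: int

    @property
    def total_f1(self) -> float:
        return float(sum(self.f1[i, j] for i, j in self.pairs))


def build_match_matrix(pred_masks: Sequence, gt_masks: Sequence) -> MatchMatrix:
    """All pairwise pixel F1 scores plus the max-total-F1 assignment."""
    P, G = len(pred_masks), len(gt_masks)
    f1 = np.zeros((P, G))
    for i, pm in enumerate(pred_masks):
        for j, gm in enumerate(gt_masks):
            f1[i, j] = pixel_f1(pm, gm)
    if P and G:
        rows, cols = linear_sum_assignment(-f1)
        pairs = sorted(zip(rows.tolist(), cols.tolist()))
    else:
        pairs = []
    return MatchMatrix(f1=f1, pairs=pairs, n_gt=G)


def f_at_075(pred_masks: Sequence, gt_masks: Sequence,
             threshold: float = 0.75) -> float:
    """Fraction of ground truths whose matched prediction has F1 >= threshold."""
    if len(gt_masks) == 0:
        raise UndefinedMetricError("F@.75 undefined with no ground truths")
    mm = build_match_matrix(pred_masks, gt_masks)
    hits = sum(1 for i, j in mm.pairs if mm.f1[i, j] >= threshold)
    return hits / mm.n_gt


# ---------------------------------------------------------------------------
# mIoU
# ---------------------------------------------------------------------------

def miou(pred_masks: Sequence, gt_masks: Sequence,
         pred_classes: Optional[Sequence] = None,
         gt_classes: Optional[Sequence] = None,
         mode: str = "instance") -> float:
    """Mean IoU of predictions against ground truths.

    ``instance`` (default): Hungarian-matched pair IoUs, unmatched ground
    truths scored 0, averaged over ground truths within each class and
    then across classes present.  ``semantic``: pixels are pooled per
    class (background included) and per-class IoUs averaged.
    """
    if len(gt_masks) == 0:
        raise UndefinedMetricError("mIoU undefined with no ground truths")
    if gt_classes is None:
        gt_classes = [0] * len(gt_masks)
    if pred_classes is None:
        pred_classes = [0] * len(pred_masks)

    if mode == "semantic":
        shape = _as_bool(gt_masks[0]).shape
        classes = sorted(set(gt_classes) | set(pred_classes))
        ious = []
        pred_union_all = np.zeros(shape, dtype=bool)
        gt_union_all = np.zeros(shape, dtype=bool)
        for c in classes:
            pu = np.zeros(shape, dtype=bool)
            gu = np.zeros(shape, dtype=bool)
            for m, k in zip(pred_masks, pred_classes):
                if k == c:
                    pu |= _as_bool(m)
            for m, k in zip(gt_masks, gt_classes):
                if k == c:
                    gu |= _as_bool(m)
            ious.append(mask_iou(pu, gu))
            pred_union_all |= pu
            gt_union_all |= gu
        # the +1 background term
        ious.append(mask_iou(~pred_union_all, ~gt_union_all))
        return float(np.mean(ious))
    if mode != "instance":
        raise ValueError(f"unknown mIoU mode {mode!r}")

    mm = build_match_matrix(pred_masks, gt_masks)
    matched = {j: i for i, j in mm.pairs}
    per_class: Dict = {}
    for j, gm in enumerate(gt_masks):
        if j in matched:
            iou = mask_iou(pred_masks[matched[j]], gm)
        else:
            iou = 0.0
        per_class.setdefault(gt_classes[j], []).append(iou)
    return float(np.mean([np.mean(v) for v in per_class.values()]))


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------

def average_precision(scored_preds: Sequence[Tuple[np.ndarray, float]],
                      gt_masks: Sequence, iou_threshold: float) -> float:
    """AP of score-ranked mask predictions at one IoU matching threshold.

    ``scored_preds``: (mask, score) pairs for one frame.  Predictions are
    greedily matched, in descending score order, to the unmatched ground
    truth of highest IoU >= threshold; the precision-recall curve is
    integrated with 101-point interpolation.
    """
    groups = [(scored_preds, gt_masks)]
    return _ap_grouped(groups, iou_threshold)


def _ap_grouped(groups, iou_threshold: float) -> float:
    """AP over (preds, gts) groups (e.g. frames); matching stays in-group."""
    n_gt = sum(len(g) for _, g in groups)
    if n_gt == 0:
        raise UndefinedMetricError("AP undefined with no ground truths")
    scored = []  # (score, order, is_tp)
    order = 0
    for preds, gts in groups:
        idx = sorted(range(len(preds)),
                     key=lambda i: (-float(preds[i][1]), i))
        taken = np.zeros(len(gts), dtype=bool)
        for i in idx:
            mask, score = preds[i][0], float(preds[i][1])
            # match to the unmatched gt of highest IoU, TP iff >= threshold
            best_j, best_iou = -1, -1.0
            for j, gm in enumerate(gts):
                if taken[j]:
                    continue
                iou = mask_iou(mask, gm)
                if iou > best_iou:
                    best_j, best_iou = j, iou
            tp = best_j >= 0 and best_iou >= iou_threshold
            if tp:
                taken[best_j] = True
            scored.append((score, order, bool(tp)))
            order += 1
    scored.sort(key=lambda t: (-t[0], t[1]))
    tps = np.array([t[2] for t in scored], dtype=float)
    if len(tps) == 0:
        return 0.0
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum(1.0 - tps)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # monotone envelope, then 101-point interpolation
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recall >= r - 1e-12
        ap += precision[mask].max() if mask.any() else 0.0
    return float(ap / 101.0)


def mean_ap(aps: Sequence[float]) -> float:
    """Arithmetic mean of per-setting APs."""
    if len(aps) == 0:
        raise UndefinedMetricError("mAP of an empty AP list")
    return float(np.mean(aps))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """All statistics for one evaluation run, values in [0, 1]."""

    precision: float
    recall: float
    f1: float
    f_at_075: float
    miou: float
    ap50: float
    ap75: float
    map: float
    n_gt: int
    per_bin: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("precision", "recall", "f1", "f_at_075", "miou",
              "ap50", "ap75", "map", "n_gt")}
        d["per_bin"] = self.per_bin
        return d


def evaluate_frame(preds: Sequence[dict], gts: Sequence[InstanceMasks],
                   use_mask: str = "amodal",
                   miou_mode: str = "instance") -> EvalReport:
    """Evaluate one frame; see :func:`evaluate_dataset` for conventions."""
    return evaluate_dataset({0: preds}, {0: gts}, use_mask=use_mask,
                            miou_mode=miou_mode)


def evaluate_dataset(preds_by_image: Dict, gts_by_image: Dict,
                     use_mask: str = "amodal",
                     miou_mode: str = "instance",
                     per_bin: bool = True) -> EvalReport:
    """Aggregate evaluation over frames.

    ``preds_by_image[i]`` is a list of ``{"amodal": mask, "visible": mask,
    "score": s}`` dicts (visible optional); ``gts_by_image[i]`` a list of
    :class:`InstanceMasks`.  ``use_mask`` selects which mask pair (amodal
    or visible) is compared.  Matching is always within-frame; F@.75 and
    mIoU are averaged over all ground-truth instances, AP pools
    predictions by score across frames.
    """
    if use_mask not in ("amodal", "visible"):
        raise ValueError("use_mask must be 'amodal' or 'visible'")
    image_ids = sorted(gts_by_image)
    n_gt_total = sum(len(gts_by_image[i]) for i in image_ids)
    if n_gt_total == 0:
        raise UndefinedMetricError("no ground-truth instances to evaluate")

    def pmask(p):
        m = p.get(use_mask) if p.get(use_mask) is not None else p.get("amodal")
        return _as_bool(m)

    def gmask(g: InstanceMasks):
        return g.amodal if use_mask == "amodal" else g.visible

    hits = 0
    iou_all: List[float] = []
    bin_stats: Dict[str, Dict[str, List[float]]] = {
        b[0]: {"hits": [], "ious": []} for b in OCCLUSION_BINS}
    tp_px = fp_px = fn_px = 0
    ap_groups = []
    for i in image_ids:
        gts = gts_by_image[i]
        preds = preds_by_image.get(i, [])
        p_masks = [pmask(p) for p in preds]
        g_masks = [gmask(g) for g in gts]
        mm = build_match_matrix(p_masks, g_masks)
        matched = {j: pi for pi, j in mm.pairs}
        for j, g in enumerate(gts):
            ok = j in matched and mm.f1[matched[j], j] >= 0.75
            hits += ok
            iou = mask_iou(p_masks[matched[j]], g_masks[j]) if j in matched else 0.0
            iou_all.append(iou)
            label = bin_occlusion(g.occlusion_rate)
            bin_stats[label]["hits"].append(float(ok))
            bin_stats[label]["ious"].append(iou)
        # pixel-level aggregate: union of instance masks as foreground
        shape = g_masks[0].shape if g_masks else (
            p_masks[0].shape if p_masks else None)
        if shape is not None:
            pu = np.zeros(shape, dtype=bool)
            gu = np.zeros(shape, dtype=bool)
            for m in p_masks:
                pu |= m
            for m in g_masks:
                gu |= m
            tp_px += int((pu & gu).sum())
            fp_px += int((pu & ~gu).sum())
            fn_px += int((~pu & gu).sum())
        ap_groups.append(([(m, p.get("score", 1.0))
                           for m, p in zip(p_masks, preds)], g_masks))

    precision = tp_px / (tp_px + fp_px) if tp_px + fp_px else 1.0
    recall = tp_px / (tp_px + fn_px) if tp_px + fn_px else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)

    # mIoU: instance mode reuses the per-gt IoUs (single class); semantic
    # mode pools pixels per frame and averages over frames.
    if miou_mode == "instance":
        miou_val = float(np.mean(iou_all))
    else:
        vals = []
        for i in image_ids:
            gts = gts_by_image[i]
            preds = preds_by_image.get(i, [])
            vals.append(miou([pmask(p) for p in preds],
                             [gmask(g) for g in gts], mode="semantic"))
        miou_val = float(np.mean(vals))

    aps = {t: _ap_grouped(ap_groups, t) for t in AP_THRESHOLDS}
    report = EvalReport(
        precision=precision, recall=recall, f1=f1,
        f_at_075=hits / n_gt_total,
        miou=miou_val,
        ap50=aps[0.5], ap75=aps[0.75],
        map=mean_ap(list(aps.values())),
        n_gt=n_gt_total,
    )
    if per_bin:
        for label, st in bin_stats.items():
            if st["hits"]:
                report.per_bin[label] = {
                    "f_at_075": float(np.mean(st["hits"])),
                    "miou": float(np.mean(st["ious"])),
                    "n_gt": len(st["hits"]),
                }
    return report
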