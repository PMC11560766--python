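"""Pick-target selection and the evaluation metric suite.

Selection: among pickable instances, the pick circle is the minimum
circumscribed circle over the instance's visible pixels plus its blind-spot
pixels (the occluded part of the fruit is part of the fruit), and candidates
are ranked by a closest-and-largest composite score

    score = w_a * area / max(area)  +  w_d * min(depth) / depth

so a fruit that is simultaneously the largest and the closest scores exactly
w_a + w_d = 1.

Metrics: pixel accuracy and per-class IoU (per-image, then averaged over
images), detection precision/recall/F1 under the overlap-over-ground-truth >
0.5 matching rule, and the positioning error |C_p - C_g| / R * 100 (a relative
center offset in percent of the ground-truth radius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .obstacle_perception import InstanceMask, OcclusionReport
from .scene_io import DepthMap, SemanticMap


@dataclass
class PickTarget:
    instance_id: int
    center: tuple[float, float]  # (row, col)
    radius: float
    mean_depth: float  # mm
    score: float


@dataclass
class GroundTruthTarget:
    center: tuple[float, float]
    radius: float
    pickable: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ground-truth radius must be positive")


# ---------------------------------------------------------------------------
# Minimum enclosing circle (Welzl, randomized incremental)


def _circle_two(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2.0
    return c, float(np.linalg.norm(p - c))


def _circle_three(p, q, r) -> Optional[tuple[np.ndarray, float]]:
    ax, ay = p[1], p[0]
    bx, by = q[1], q[0]
    cx, cy = r[1], r[0]
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None  # collinear
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([uy, ux])
    return center, float(np.linalg.norm(p - center))


def _in_circle(c: np.ndarray, r: float, p: np.ndarray, eps: float) -> bool:
    return np.linalg.norm(p - c) <= r + eps


def min_enclosing_circle(points, eps: float = 1e-7) -> tuple[tuple[float, float], float]:
    """Smallest circle containing all (row, col) points (Welzl's algorithm)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    pts = np.unique(pts, axis=0)
    rng = np.random.default_rng(20240917)  # internal shuffle; result is unique
    rng.shuffle(pts)

    def circle_with_two_boundary(sub: np.ndarray, p, q):
        c, r = _circle_two(p, q)
        for s in sub:
            if not _in_circle(c, r, s, eps):
                res = _circle_three(p, q, s)
                if res is not None:
                    c, r = res
        return c, r

    def circle_with_one_boundary(sub: np.ndarray, p):
        c, r = np.array(p, dtype=float), 0.0
        for i, q in enumerate(sub):
            if not _in_circle(c, r, q, eps):
                c, r = circle_with_two_boundary(sub[:i], p, q)
        return c, r

    c, r = np.array(pts[0], dtype=float), 0.0
    for i in range(1, len(pts)):
        if not _in_circle(c, r, pts[i], eps):
            c, r = circle_with_one_boundary(pts[:i], pts[i])
    return (float(c[0]), float(c[1])), float(r)


# ---------------------------------------------------------------------------
# Candidate scoring and target selection


def composite_score(
    candidates: Sequence[tuple[float, float]],
    weights: tuple[float, float] = (0.5, 0.5),
) -> np.ndarray:
    """Closest-and-largest scores in (0, 1] for (area_px, mean_depth_mm) pairs."""
    arr = np.asarray(candidates, dtype=float).reshape(-1, 2)
    if len(arr) == 0:
        raise ValueError("need at least one candidate")
    areas, depths = arr[:, 0], arr[:, 1]
    if np.any(depths <= 0):
        raise ValueError("candidate depths must be positive")
    w_a, w_d = weights
    return w_a * areas / areas.max() + w_d * depths.min() / depths


def select_target(
    reports: Sequence[OcclusionReport],
    instances: Sequence[InstanceMask],
    depth: DepthMap,
    weights: tuple[float, float] = (0.5, 0.5),
) -> Optional[PickTarget]:
    """Pick the best pickable instance, or None.

    Per pickable instance: pick circle over visible ∪ blind-spot pixels, mean
    depth over the instance's valid visible pixels (a candidate with no valid
    depth cannot be localized and is skipped).  Ranking is by composite score,
    ties broken by smaller mean depth, then larger area, then lower id.
    """
    by_id = {inst.instance_id: inst for inst in instances}
    cands = []
    for rep in reports:
        if not rep.pickable:
            continue
        inst = by_id[rep.instance_id]
        pix = inst.pixels
        extra = [s.pixels for s in rep.blind_spots if len(s.pixels)]
        pts = np.vstack([pix] + extra) if extra else pix
        d = depth.depth[pix[:, 0], pix[:, 1]]
        d = d[d != depth.invalid_value]
        if len(d) == 0:
            continue
        center, radius = min_enclosing_circle(pts)
        cands.append((rep.instance_id, center, radius, float(d.mean()), inst.area))
    if not cands:
        return None
    scores = composite_score([(a, md) for (_, _, _, md, a) in cands], weights)
    order = sorted(
        range(len(cands)),
        key=lambda i: (-scores[i], cands[i][3], -cands[i][4], cands[i][0]),
    )
    iid, center, radius, mean_depth, _area = cands[order[0]]
    return PickTarget(
        instance_id=iid,
        center=center,
        radius=radius,
        mean_depth=mean_depth,
        score=float(scores[order[0]]),
    )


# ---------------------------------------------------------------------------
# Segmentation metrics (per-image, then averaged over the image set)


def _label_arrays(maps) -> list[np.ndarray]:
    out = []
    for m in maps:
        out.append(m.labels if isinstance(m, SemanticMap) else np.asarray(m))
    return out


def pixel_accuracy(pred_maps, gt_maps) -> float:
    """Mean over images of correctly-classified / valid pixels, in percent."""
    preds, gts = _label_arrays(pred_maps), _label_arrays(gt_maps)
    if len(preds) != len(gts) or not preds:
        raise ValueError("need equally many non-empty prediction and truth maps")
    accs = []
    for p, g in zip(preds, gts):
        if p.shape != g.shape:
            raise ValueError("prediction / ground-truth shape mismatch")
        accs.append((p == g).mean())
    return float(np.mean(accs) * 100.0)


def class_iou(pred_maps, gt_maps, class_id: int) -> float:
    """Per-image IoU of one class averaged over images, in percent.

    Images where the class appears in neither prediction nor truth carry no
    information about it and are skipped; NaN if the class appears nowhere.
    """
    preds, gts = _label_arrays(pred_maps), _label_arrays(gt_maps)
    ious = []
    for p, g in zip(preds, gts):
        pi = p == class_id
        gi = g == class_id
        union = (pi | gi).sum()
        if union == 0:
            continue
        ious.append((pi & gi).sum() / union)
    return float(np.mean(ious) * 100.0) if ious else float("nan")


def mean_iou(pred_maps, gt_maps, class_ids: Sequence[int]) -> float:
    """Unweighted mean of per-class IoU over the classes that occur."""
    vals = [class_iou(pred_maps, gt_maps, c) for c in class_ids]
    vals = [v for v in vals if not math.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Detection metrics (IoU>0.5-of-ground-truth matching) and positioning error


def circle_mask(center, radius: float, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _target_mask(t, shape) -> np.ndarray:
    if isinstance(t, np.ndarray):
        return t.astype(bool)
    if isinstance(t, InstanceMask):
        return t.mask
    if isinstance(t, (PickTarget, GroundTruthTarget)):
        return circle_mask(t.center, t.radius, shape)
    raise TypeError(f"unsupported target type {type(t).__name__}")


def detection_prf(
    pred_targets,
    gt_targets,
    iou_threshold: float = 0.5,
    shape: Optional[tuple[int, int]] = None,
) -> tuple[float, float, float]:
    """Precision / recall / F1 (percent) with greedy one-to-one matching.

    A prediction matches a ground truth when their overlap area exceeds
    `iou_threshold` of the ground-truth area; pairs are matched greedily by
    descending overlap ratio.  With no predictions, precision is 0 by
    convention.  Targets may be boolean masks, instance masks, or circles
    (rasterized onto `shape`).
    """
    preds = [_target_mask(t, shape) for t in pred_targets]
    gts = [_target_mask(t, shape) for t in gt_targets]
    pairs = []
    for i, p in enumerate(preds):
        for j, g in enumerate(gts):
            ga = g.sum()
            ratio = (p & g).sum() / ga if ga else 0.0
            if ratio > iou_threshold:
                pairs.append((ratio, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        tp += 1
    fp = len(preds) - tp
    fn = len(gts) - tp
    precision = 100.0 * tp / (tp + fp) if (tp + fp) else 0.0
    recall = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return precision, recall, f1


def positioning_error(pred, gt: GroundTruthTarget) -> float:
    """Center offset as a percentage of the ground-truth radius."""
    if gt.radius <= 0:
        raise ValueError("ground-truth radius must be positive")
    pc = np.asarray(pred.center if hasattr(pred, "center") else pred, dtype=float)
    gc = np.asarray(gt.center, dtype=float)
    return float(np.linalg.norm(pc - gc) / gt.radius * 100.0)
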