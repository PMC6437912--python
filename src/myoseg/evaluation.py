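"""Cell-wise segmentation evaluation: precision, recall, F1, PR sweeps.

For each matched (segmented cell S, ground-truth cell G) pair,

    precision = |S ∩ G| / |S|,  recall = |S ∩ G| / |G|,
    F1 = 2 P R / (P + R),

and per-image metrics average the per-cell values.  Matching is greedy
one-to-one by descending intersection area.  By default, unmatched
segmented cells count as precision 0 and unmatched ground-truth cells as
recall 0 (both as F1 = 0), so the averages penalize false positives and
misses; averaging over matched cells only is available as an alternative
convention since the choice changes absolute numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np


@dataclass(frozen=True)
class MatchTable:
    """One-to-one matches: (seg id, gt id, intersection, |S|, |G|)."""

    pairs: tuple


def match_cells(seg: np.ndarray, gt: np.ndarray) -> MatchTable:
    """Greedy one-to-one matching by descending intersection area.

    Ties break toward the smaller (seg id, gt id) pair; zero-intersection
    pairs are excluded.
    """
    seg = np.asarray(seg)
    gt = np.asarray(gt)
    if seg.shape != gt.shape:
        raise ValueError("segmentation and ground truth shapes differ")
    n_s, n_g = int(seg.max()), int(gt.max())
    if n_s == 0 or n_g == 0:
        return MatchTable(pairs=())
    both = (seg > 0) & (gt > 0)
    keys = seg[both].astype(np.int64) * (n_g + 1) + gt[both]
    uk, counts = np.unique(keys, return_counts=True)
    area_s = np.bincount(seg.ravel(), minlength=n_s + 1)
    area_g = np.bincount(gt.ravel(), minlength=n_g + 1)
    cand = sorted(
        ((-int(c), int(k // (n_g + 1)), int(k % (n_g + 1))) for k, c in zip(uk, counts))
    )
    used_s, used_g = set(), set()
    pairs = []
    for neg_i, s, g in cand:
        if s in used_s or g in used_g:
            continue
        used_s.add(s)
        used_g.add(g)
        pairs.append((s, g, -neg_i, int(area_s[s]), int(area_g[g])))
    return MatchTable(pairs=tuple(pairs))


def cell_prf(intersection: int, s_area: int, g_area: int) -> Tuple[float, float, float]:
    """Per-cell precision, recall and F1 from the overlap areas."""
    if s_area <= 0 or g_area <= 0:
        raise ValueError("cell areas must be positive")
    if intersection > min(s_area, g_area):
        raise ValueError("intersection cannot exceed either area")
    p = intersection / s_area
    r = intersection / g_area
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return float(p), float(r), float(f1)


def image_metrics(
    table: MatchTable,
    n_seg: int,
    n_gt: int,
    convention: str = "penalize_unmatched",
) -> Tuple[float, float, float]:
    """Average the per-cell metrics over an image.

    With the default convention, the precision average runs over all
    segmented cells (unmatched ones contribute 0), the recall average over
    all ground-truth cells, and the F1 average over max(n_seg, n_gt).
    With ``convention="matched_only"`` averages run over matched pairs.
    """
    if n_seg == 0 and n_gt == 0:
        raise ValueError("no segmented and no ground-truth cells: undefined")
    ps, rs, fs = [], [], []
    for s, g, inter, sa, ga in table.pairs:
        p, r, f1 = cell_prf(inter, sa, ga)
        ps.append(p)
        rs.append(r)
        fs.append(f1)
    if convention == "matched_only":
        if not ps:
            return 0.0, 0.0, 0.0
        return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))
    if convention != "penalize_unmatched":
        raise ValueError(f"unknown convention: {convention}")
    mean_p = sum(ps) / n_seg if n_seg else 0.0
    mean_r = sum(rs) / n_gt if n_gt else 0.0
    mean_f = sum(fs) / max(n_seg, n_gt)
    return float(mean_p), float(mean_r), float(mean_f)


def evaluate_rasters(seg: np.ndarray, gt: np.ndarray, convention="penalize_unmatched"):
    """Convenience wrapper: match two rasters and average the metrics."""
    table = match_cells(seg, gt)
    return image_metrics(table, int(seg.max()), int(gt.max()), convention)


DEFAULT_THRESHOLDS = tuple(
    sorted(set(np.round(np.arange(0.0, 1.0, 0.05), 3).tolist() + [0.26]))
)


def pr_curve(
    image: np.ndarray,
    gt: np.ndarray,
    models,
    config,
    thresholds=None,
) -> List[Tuple[float, float, float, float]]:
    """Precision/recall sweep over the cell-score threshold.

    Runs the pipeline once keeping every selected node with its score,
    then for each threshold keeps only cells scoring at least that value
    and recomputes the metrics.  Returns (threshold, mean P, mean R,
    mean F1) tuples.  The default grid includes the 0.26 operating point.
    """
    from .pipeline import segment_image

    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    thresholds = list(thresholds)
    if any(t2 < t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    labels, cells = segment_image(image, models, config, score_threshold=None)
    gt_labels = gt.labels if hasattr(gt, "labels") else np.asarray(gt)
    n_gt = int(gt_labels.max())
    out = []
    for t in thresholds:
        keep = [c["id"] for c in cells if c["score"] is not None and c["score"] >= t]
        seg_t = np.where(np.isin(labels, keep), labels, 0)
        if len(keep) == 0 and n_gt == 0:
            out.append((float(t), 0.0, 0.0, 0.0))
            continue
        table = match_cells(seg_t, gt_labels)
        p, r, f1 = image_metrics(table, len(keep), n_gt)
        out.append((float(t), p, r, f1))
    return out
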