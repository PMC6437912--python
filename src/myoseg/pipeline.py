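"""End-to-end pipeline: contour detection -> candidates -> region selection.

`train_models` fits the two learned components (the structured-forest
contour detector and the random-forest region scorer) on images with
ground-truth label rasters; `segment_image` runs the full single-image
pipeline deterministically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Optional

import numpy as np
from skimage.color import rgb2lab

from . import hierarchy, regions, srf, synthetic
from .hierarchy import RegionScorer, train_region_scorer
from .srf import ForestModel, ForestParams, predict_contours, train_forest
from .synthetic import GroundTruth, sample_patches, sample_region_training_set


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline, with defaults.

    Round-trips losslessly through YAML (see :mod:`myoseg.io`).
    """

    # structured forest
    n_trees: int = 8
    d_in: int = 32
    d_out: int = 16
    stride: int = 16
    feature_frac: float = 0.25
    sample_frac: float = 0.5
    max_depth: int = 32
    min_samples_leaf: int = 8
    n_patches_per_image: int = 600
    # region candidates
    smoothing_sigma: float = 1.0
    min_region_area: int = 30
    scorer_ucm_levels: tuple = (0.0, 0.15, 0.3, 0.45, 0.6)
    iou_pos: float = 0.7
    # hierarchical CRF
    mu: float = 0.01
    epsilon: float = 1e-6
    cut_threshold: float = 0.5
    max_exhaustive_leaves: int = 10
    score_threshold: float = 0.26
    # tiling
    tile_size: int = 1024
    pad: int = 300
    n_workers: int = 1
    # randomness
    seed: int = 0

    def forest_params(self) -> ForestParams:
        return ForestParams(
            n_trees=self.n_trees,
            d_in=self.d_in,
            d_out=self.d_out,
            feature_frac=self.feature_frac,
            sample_frac=self.sample_frac,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scorer_ucm_levels"] = list(self.scorer_ucm_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scorer_ucm_levels" in d:
            d["scorer_ucm_levels"] = tuple(d["scorer_ucm_levels"])
        return cls(**d)


@dataclass
class Models:
    forest: ForestModel
    scorer: RegionScorer


def _as_lab(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    return rgb2lab(img.astype(np.float64) / 255.0 if img.dtype == np.uint8 else img)


def train_srf(pairs, config: PipelineConfig) -> ForestModel:
    """Train the contour detector on (image, ground-truth) pairs."""
    X, Y = [], []
    for i, (image, gt) in enumerate(pairs):
        samples = sample_patches(
            image,
            gt,
            d_in=config.d_in,
            d_out=config.d_out,
            n=config.n_patches_per_image,
            seed=config.seed + 10_000 + i,
        )
        X.extend(s.x for s in samples)
        Y.extend(s.y for s in samples)
    return train_forest(
        np.stack(X), np.stack(Y), config.forest_params(), seed=config.seed
    )


def train_scorer(pairs, forest: ForestModel, config: PipelineConfig) -> RegionScorer:
    """Train the region scorer on candidate regions of the training images.

    Candidates are the full merge-tree nodes of each training image — the
    exact population the scorer sees at inference time, from leaf
    fragments through cell-sized merges (positives by IoU >= iou_pos) up
    to root-level giants (negatives) — plus the regions of the greedy
    merges at the configured boundary-strength levels.  An empty
    interstitial field of view is appended as hard negatives, since
    whole-slide tiles regularly contain no tissue at all.
    """
    feats, labels = [], []
    rng = np.random.default_rng(config.seed + 77_000)
    blank = np.clip(
        rng.normal(synthetic.INTERSTITIAL_RGB, 6.0, size=(128, 128, 3)), 0, 255
    ).astype(np.uint8)
    blank_gt = synthetic.GroundTruth(
        labels=np.zeros((128, 128), dtype=np.int32), n_cells=0
    )
    for image, gt in list(pairs) + [(blank, blank_gt)]:
        contour = predict_contours(image, forest, stride=config.stride)
        rm = regions.oversegment(
            contour, config.smoothing_sigma, config.min_region_area
        )
        adj = regions.build_adjacency(rm, contour)
        tree = hierarchy.build_tree(rm, adj)
        lab_img = _as_lab(image)
        ids, X = hierarchy.node_features(tree, rm, lab_img, contour)
        iou = hierarchy.node_iou_labels(tree, rm, gt.labels, config.iou_pos)
        feats.extend(X)
        labels.extend(iou[n] for n in ids)
        for level in config.scorer_ucm_levels:
            if level <= 0:
                continue
            merged = regions.threshold_merge(rm, adj, level)
            for f, lab in sample_region_training_set(
                merged, gt, image, contour, iou_pos=config.iou_pos
            ):
                feats.append(f)
                labels.append(lab)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError(
            "scorer training produced a single class; training images must "
            "yield both cell-like and non-cell candidate regions"
        )
    return train_region_scorer(np.stack(feats), y, seed=config.seed)


def train_models(pairs, config: PipelineConfig) -> Models:
    forest = train_srf(pairs, config)
    scorer = train_scorer(pairs, forest, config)
    return Models(forest=forest, scorer=scorer)


def segment_image(
    image: np.ndarray,
    models: Models,
    config: PipelineConfig,
    score_threshold: Optional[float] = "default",
    return_details: bool = False,
    grid_origin: tuple = (0, 0),
):
    """Run the full pipeline on one image.

    ``grid_origin`` anchors the contour-detection patch grid to global
    coordinates when the image is a tile crop of a larger image.

    Returns ``(label_raster, cells)``; with ``return_details=True`` a dict
    with the intermediate contour map and region map is appended.
    """
    if score_threshold == "default":
        score_threshold = config.score_threshold
    contour = predict_contours(
        image, models.forest, stride=config.stride, grid_origin=grid_origin
    )
    rm = regions.oversegment(contour, config.smoothing_sigma, config.min_region_area)
    adj = regions.build_adjacency(rm, contour)
    tree = hierarchy.build_tree(rm, adj)
    forest_trees = hierarchy.cut_tree(tree, adj, config.cut_threshold)

    lab_img = _as_lab(image)
    edge_lookup: Dict[tuple, tuple] = {
        (i, j): (b, l) for i, j, b, l in adj.edges
    }
    labelings = []
    all_scores: Dict[int, float] = {}
    for sub in forest_trees:
        scores = hierarchy.score_nodes(sub, models.scorer, rm, lab_img, contour)
        all_scores.update(scores)
        leaf_regions = {
            sub.nodes[l].region_label for l in sub.leaves_under(sub.root)
        }
        pairwise = [
            (i, j, b, l)
            for (i, j), (b, l) in edge_lookup.items()
            if i in leaf_regions and j in leaf_regions
        ]
        model = hierarchy.EnergyModel(
            scores=scores, pairwise=pairwise, mu=config.mu, epsilon=config.epsilon
        )
        try:
            labeling = hierarchy.infer_exact(
                sub, model, max_leaves=config.max_exhaustive_leaves
            )
        except hierarchy.SubtreeTooLarge:
            labeling = hierarchy.infer_fast(sub, model)
        labelings.append(labeling)

    out, cells = hierarchy.select_segments(
        forest_trees, labelings, rm, scores=all_scores, score_threshold=score_threshold
    )
    if return_details:
        return out, cells, {"contour": contour, "region_map": rm, "tree": tree}
    return out, cells
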