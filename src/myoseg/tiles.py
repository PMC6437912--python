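"""Tile-based parallel segmentation of large images.

A large image is split into a grid of disjoint core rectangles, each
padded on every side (default 300 px, clipped at image borders) so cells
crossing tile seams are fully visible to at least one tile.  Tiles are
processed concurrently by an in-process worker pool; each worker runs the
complete single-image pipeline on its padded crop and returns a masked
label raster.  Stitching keeps a cell iff its centroid falls in the owning
tile's core, deduplicates near-identical cells found by neighboring tiles
(mask IoU > 0.5), and renumbers the kept masks globally.  The result is
independent of the number of workers and of tile completion order.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np

from .pipeline import Models, PipelineConfig, segment_image


class TileProcessingError(RuntimeError):
    """Pipeline failure on one tile; carries the tile index."""


@dataclass(frozen=True)
class TileSpec:
    """Core and padded rectangles (y0, x0, y1, x1), half-open pixel coords."""

    core: tuple
    padded: tuple
    index: tuple


@dataclass
class TileResult:
    """Label raster over the padded rectangle of one tile."""

    labels: np.ndarray
    tile: TileSpec


def split_tiles(
    image_h: int, image_w: int, tile_size: int = 1024, pad: int = 300
) -> List[TileSpec]:
    """Grid of disjoint cores covering the image, each padded and clipped."""
    if image_h <= 0 or image_w <= 0:
        raise ValueError("image dimensions must be positive")
    if tile_size < 64:
        raise ValueError("tile_size must be >= 64")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    rows = math.ceil(image_h / tile_size)
    cols = math.ceil(image_w / tile_size)
    tiles = []
    for r in range(rows):
        for c in range(cols):
            y0, x0 = r * tile_size, c * tile_size
            y1, x1 = min(y0 + tile_size, image_h), min(x0 + tile_size, image_w)
            py0, px0 = max(0, y0 - pad), max(0, x0 - pad)
            py1, px1 = min(image_h, y1 + pad), min(image_w, x1 + pad)
            tiles.append(
                TileSpec(core=(y0, x0, y1, x1), padded=(py0, px0, py1, px1), index=(r, c))
            )
    return tiles


def tile_seed(base_seed: int, row: int, col: int) -> int:
    """Deterministic per-tile seed, independent of scheduling order."""
    return (base_seed * 1_000_003 + row * 8_191 + col * 131 + 17) % (2**31)


def process_tile(
    image_crop: np.ndarray,
    models: Models,
    config: PipelineConfig,
    tile: Optional[TileSpec] = None,
) -> TileResult:
    """Run the full pipeline on one padded crop."""
    if tile is None:
        h, w = image_crop.shape[:2]
        tile = TileSpec(core=(0, 0, h, w), padded=(0, 0, h, w), index=(0, 0))
    cfg = replace(config, seed=tile_seed(config.seed, *tile.index))
    try:
        labels, _ = segment_image(
            image_crop, models, cfg, grid_origin=tile.padded[:2]
        )
    except Exception as exc:  # noqa: BLE001 - report the failing tile
        raise TileProcessingError(f"pipeline failed on tile {tile.index}: {exc}") from exc
    return TileResult(labels=labels, tile=tile)


def _collect_cells(results: List[TileResult], image_w: int):
    """All candidate cells whose centroid lies in their tile's core."""
    cells = []
    for res in sorted(results, key=lambda r: r.tile.index):
        py0, px0, _, _ = res.tile.padded
        y0, x0, y1, x1 = res.tile.core
        for cell_id in np.unique(res.labels):
            if cell_id == 0:
                continue
            ys, xs = np.nonzero(res.labels == cell_id)
            gy, gx = ys + py0, xs + px0
            cy, cx = float(gy.mean()), float(gx.mean())
            if not (y0 <= cy < y1 and x0 <= cx < x1):
                continue
            depth = min(cy - y0, y1 - cy, cx - x0, x1 - cx)
            coords = set((gy.astype(np.int64) * image_w + gx).tolist())
            cells.append(
                {
                    "tile": res.tile.index,
                    "cell_id": int(cell_id),
                    "coords": coords,
                    "bbox": (gy.min(), gx.min(), gy.max(), gx.max()),
                    "depth": depth,
                }
            )
    return cells


def stitch(results: List[TileResult], image_h: int, image_w: int) -> np.ndarray:
    """Combine per-tile label rasters into one global segmentation.

    Ownership by centroid-in-core, IoU > 0.5 deduplication across tiles
    (the cell whose centroid lies deeper inside its core wins; ties go to
    the earlier tile), then masks written in (tile, cell) order with any
    residual overlap resolved in favor of the earlier-kept cell.
    """
    covered = np.zeros((image_h, image_w), dtype=bool)
    for res in results:
        y0, x0, y1, x1 = res.tile.core
        if covered[y0:y1, x0:x1].any():
            raise ValueError("overlapping tile cores")
        covered[y0:y1, x0:x1] = True
        py0, px0, py1, px1 = res.tile.padded
        if res.labels.shape != (py1 - py0, px1 - px0):
            raise ValueError(f"tile {res.tile.index}: raster does not match padded rect")
    if not covered.all():
        raise ValueError("missing tiles: cores do not cover the image")

    cells = _collect_cells(results, image_w)
    dropped = [False] * len(cells)
    for a in range(len(cells)):
        if dropped[a]:
            continue
        for b in range(a + 1, len(cells)):
            if dropped[b] or cells[a]["tile"] == cells[b]["tile"]:
                continue
            ay0, ax0, ay1, ax1 = cells[a]["bbox"]
            by0, bx0, by1, bx1 = cells[b]["bbox"]
            if ay1 < by0 or by1 < ay0 or ax1 < bx0 or bx1 < ax0:
                continue
            inter = len(cells[a]["coords"] & cells[b]["coords"])
            if inter == 0:
                continue
            union = len(cells[a]["coords"]) + len(cells[b]["coords"]) - inter
            if inter / union > 0.5:
                # keep the deeper cell; ties go to the earlier tile (a)
                if cells[b]["depth"] > cells[a]["depth"]:
                    dropped[a] = True
                    break
                dropped[b] = True

    out = np.zeros((image_h, image_w), dtype=np.int32)
    next_id = 0
    flat = out.ravel()
    for cell, drop in zip(cells, dropped):
        if drop:
            continue
        idx = np.fromiter(cell["coords"], dtype=np.int64, count=len(cell["coords"]))
        idx.sort()
        idx = idx[flat[idx] == 0]
        if idx.size == 0:
            continue
        next_id += 1
        flat[idx] = next_id
    return out


def run_parallel(
    image: np.ndarray,
    models: Models,
    config: PipelineConfig,
    n_workers: Optional[int] = None,
    tile_size: Optional[int] = None,
    pad: Optional[int] = None,
) -> np.ndarray:
    """Segment a large image tile-by-tile with an in-process worker pool.

    The output raster is identical for every ``n_workers >= 1``.
    """
    n_workers = config.n_workers if n_workers is None else n_workers
    tile_size = config.tile_size if tile_size is None else tile_size
    pad = config.pad if pad is None else pad
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    h, w = image.shape[:2]
    tiles = split_tiles(h, w, tile_size=tile_size, pad=pad)

    def work(tile: TileSpec) -> TileResult:
        py0, px0, py1, px1 = tile.padded
        crop = image[py0:py1, px0:px1]
        return process_tile(crop, models, config, tile)

    if n_workers == 1 or len(tiles) == 1:
        results = [work(t) for t in tiles]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(work, tiles))
    return stitch(results, h, w)
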