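"""Box-counting fractal detection of defective boundary blocks.

A healthy lung boundary on a 2D slice is smooth; a juxtapleural nodule (or a
carved-out vessel) leaves an indentation whose boundary is locally longer
and more convoluted.  The minimum enclosing rectangle (MER) of the lung
region is tiled into 10x10 blocks (2x2 when only one lung subregion
remains), the box-counting dimension D of the boundary restricted to each
boundary-containing block is computed, and blocks with
``D > T_f = mean(D) + std(D)`` are flagged as defective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

__all__ = [
    "Rect",
    "BlockGrid",
    "FractalStats",
    "min_enclosing_rect",
    "make_block_grid",
    "extract_boundary",
    "boundary_blocks",
    "box_counting_dimension",
    "defect_threshold",
    "detect_defective_blocks",
]


class Rect(NamedTuple):
    """Half-open axis-aligned rectangle [row0, row0+height) x [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int


@dataclass
class BlockGrid:
    """Partition of a rectangle into n_rows x n_cols blocks tiling it exactly.

    Uneven division pushes the remainder pixels into the last block row and
    column.  ``row_edges``/``col_edges`` are offsets relative to the
    rectangle origin.
    """

    rect: Rect
    n_rows: int
    n_cols: int
    row_edges: np.ndarray
    col_edges: np.ndarray

    def blocks(self):
        """Yield ``(bi, bj, row_slice, col_slice)`` in absolute image coords."""
        for bi in range(self.n_rows):
            for bj in range(self.n_cols):
                yield (
                    bi,
                    bj,
                    slice(self.rect.row0 + self.row_edges[bi],
                          self.rect.row0 + self.row_edges[bi + 1]),
                    slice(self.rect.col0 + self.col_edges[bj],
                          self.rect.col0 + self.col_edges[bj + 1]),
                )


@dataclass
class FractalStats:
    """Per-block box-counting dimensions, flags and the global threshold."""

    dims: np.ndarray           # (n_rows, n_cols), NaN off boundary blocks
    is_boundary_block: np.ndarray
    is_defective: np.ndarray
    t_f: float
    mean_dim: float
    std_dim: float

    def to_dict(self) -> dict:
        return {
            "t_f": self.t_f,
            "mean_dim": self.mean_dim,
            "std_dim": self.std_dim,
            "dims": [[None if np.isnan(v) else float(v) for v in row]
                     for row in self.dims],
            "is_boundary_block": self.is_boundary_block.astype(int).tolist(),
            "is_defective": self.is_defective.astype(int).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def min_enclosing_rect(mask: np.ndarray) -> Rect:
    """Tight bounding box of the foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return Rect(int(rows[0]), int(cols[0]),
                int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1))


def make_block_grid(rect: Rect, n_subregions: int) -> BlockGrid:
    """10x10 grid for two or more lung subregions, 2x2 for a single one."""
    n = 10 if n_subregions >= 2 else 2
    if rect.height < n or rect.width < n:
        raise ValueError(
            f"rectangle {rect.height}x{rect.width} too small for a {n}x{n} grid; "
            "consider the 2x2 fallback"
        )
    row_edges = np.array([i * (rect.height // n) for i in range(n)] + [rect.height])
    col_edges = np.array([j * (rect.width // n) for j in range(n)] + [rect.width])
    return BlockGrid(rect=rect, n_rows=n, n_cols=n,
                     row_edges=row_edges, col_edges=col_edges)


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """1-px boundary: foreground pixels with at least one background 4-neighbour."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=1)
    return mask & ~eroded


def boundary_blocks(grid: BlockGrid, boundary: np.ndarray) -> np.ndarray:
    """Flag blocks containing at least one boundary pixel."""
    boundary = np.asarray(boundary, dtype=bool)
    flags = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for bi, bj, rs, cs in grid.blocks():
        flags[bi, bj] = boundary[rs, cs].any()
    return flags


def _box_count(boundary: np.ndarray, s: int) -> int:
    """Number of s x s boxes (anchored at the block origin) hit by the set."""
    h, w = boundary.shape
    count = 0
    for r0 in range(0, h, s):
        for c0 in range(0, w, s):
            if boundary[r0:r0 + s, c0:c0 + s].any():
                count += 1
    return count


def box_counting_dimension(block_boundary: np.ndarray) -> float:
    """Box-counting dimension of the boundary pixels inside one block.

    ``log N(s)`` is regressed on ``log(1/s)`` over box sides
    ``s = 2^k, 2^(k-1), ..., 2`` where ``2^k`` is the largest power of two
    not exceeding the block's shorter side; at least three scales are
    required.  Boxes are anchored at the block's top-left corner.
    """
    boundary = np.asarray(block_boundary, dtype=bool)
    if not boundary.any():
        raise ValueError("block contains no boundary pixels")
    side = min(boundary.shape)
    kmax = int(np.floor(np.log2(side)))
    scales = [2**k for k in range(kmax, 0, -1)]
    if len(scales) < 3:
        raise ValueError(
            f"block of side {side} px yields only {len(scales)} box scales (< 3)"
        )
    counts = np.array([_box_count(boundary, s) for s in scales], dtype=np.float64)
    x = np.log(1.0 / np.array(scales, dtype=np.float64))
    slope, _ = np.polyfit(x, np.log(counts), 1)
    return float(slope)


def defect_threshold(dims, multiplier: float = 1.0) -> float:
    """Statistical flag threshold ``T_f = mean + multiplier * std`` (sample std)."""
    dims = np.asarray(dims, dtype=np.float64)
    if dims.size < 2:
        raise ValueError("need at least two boundary blocks to set a threshold")
    return float(dims.mean() + multiplier * dims.std(ddof=1))


def count_subregions(mask: np.ndarray) -> int:
    _, n = ndimage.label(np.asarray(mask, dtype=bool), structure=np.ones((3, 3)))
    return int(n)


def detect_defective_blocks(mask: np.ndarray, n_subregions: int | None = None,
                            multiplier: float = 1.0):
    """Full detection pipeline; returns ``(FractalStats, BlockGrid)``.

    The mask is expected hole-filled and airway-excluded.  ``n_subregions``
    defaults to the 8-connected component count of the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_subregions is None:
        n_subregions = count_subregions(mask)
    rect = min_enclosing_rect(mask)
    grid = make_block_grid(rect, n_subregions)
    boundary = extract_boundary(mask)
    on_boundary = boundary_blocks(grid, boundary)

    dims = np.full((grid.n_rows, grid.n_cols), np.nan)
    for bi, bj, rs, cs in grid.blocks():
        if on_boundary[bi, bj]:
            dims[bi, bj] = box_counting_dimension(boundary[rs, cs])
    vals = dims[on_boundary]
    t_f = defect_threshold(vals, multiplier)
    defective = np.zeros_like(on_boundary)
    defective[on_boundary] = dims[on_boundary] > t_f
    stats = FractalStats(
        dims=dims,
        is_boundary_block=on_boundary,
        is_defective=defective,
        t_f=t_f,
        mean_dim=float(vals.mean()),
        std_dim=float(vals.std(ddof=1)),
    )
    return stats, grid
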