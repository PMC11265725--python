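"""Overlapping block decomposition and per-block statistics.

The detector slides a B×B window over the grayscale image with stride one:
an H×W image yields (H−B+1)·(W−B+1) blocks, row-major, the first at pixel
(0, 0) and the last at (H−B, W−B). Windows are half-open
``[r, r+B) × [c, c+B)`` in 0-based pixel coordinates.

Each block carries the population standard deviation of its grayscale
intensities (the matching feature of the equilibrium stage) and the number of
SIFT keypoint pixels it covers (its suspicion seed count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Block", "BlockGrid", "decompose", "block_std", "candidate_blocks"]


@dataclass(frozen=True)
class Block:
    """One B×B window: origin (top-left pixel), size, std, keypoint count."""

    origin_row: int
    origin_col: int
    size: int
    std: float
    keypoint_count: int = 0


class BlockGrid:
    """All stride-1 overlapping B×B blocks of a grayscale image.

    Per-block data is stored as dense ``(H−B+1, W−B+1)`` arrays indexed by
    block origin; :class:`Block` objects are materialized on demand.
    """

    def __init__(self, gray: np.ndarray, block_size: int) -> None:
        gray = np.asarray(gray, dtype=np.float64)
        if gray.ndim != 2:
            raise ValueError("expected a 2-D grayscale array")
        h, w = gray.shape
        b = int(block_size)
        if b < 2:
            raise ValueError("block size must be >= 2")
        if b > min(h, w):
            raise ValueError(
                f"block size {b} exceeds image dimensions {h}x{w}"
            )
        self.height = h
        self.width = w
        self.block_size = b
        windows = sliding_window_view(gray, (b, b))
        self.stds = windows.std(axis=(2, 3))  # population std per origin
        self.keypoint_counts = np.zeros(self.stds.shape, dtype=np.int64)

    @property
    def n_rows(self) -> int:
        return self.height - self.block_size + 1

    @property
    def n_cols(self) -> int:
        return self.width - self.block_size + 1

    @property
    def n_blocks(self) -> int:
        return self.n_rows * self.n_cols

    def block_at(self, origin_row: int, origin_col: int) -> Block:
        return Block(
            origin_row=origin_row,
            origin_col=origin_col,
            size=self.block_size,
            std=float(self.stds[origin_row, origin_col]),
            keypoint_count=int(self.keypoint_counts[origin_row, origin_col]),
        )

    @property
    def blocks(self) -> Iterator[Block]:
        """Row-major iterator over all blocks."""
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield self.block_at(r, c)

    def candidate_origins(self) -> np.ndarray:
        """Origins (row, col) of keypoint-bearing blocks, row-major, (K, 2)."""
        rows, cols = np.nonzero(self.keypoint_counts >= 1)
        return np.column_stack([rows, cols])


def decompose(gray: np.ndarray, block_size: int) -> BlockGrid:
    """Decompose a grayscale image into its overlapping block grid."""
    return BlockGrid(gray, block_size)


def block_std(gray: np.ndarray, block: Block) -> float:
    """Population standard deviation of a block's grayscale intensities."""
    gray = np.asarray(gray, dtype=np.float64)
    r, c, b = block.origin_row, block.origin_col, block.size
    if r < 0 or c < 0 or r + b > gray.shape[0] or c + b > gray.shape[1]:
        raise ValueError("block window outside image")
    return float(gray[r : r + b, c : c + b].std())


def candidate_blocks(grid: BlockGrid) -> list[Block]:
    """Blocks covering at least one keypoint pixel, in row-major order.

    These form the particle population of the equilibrium matching stage.
    """
    return [grid.block_at(r, c) for r, c in grid.candidate_origins()]
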