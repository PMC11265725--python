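"""Color Histogram Matching (CHM): grow flagged blocks into full regions.

The equilibrium stage flags forged blocks but cannot recover the full extent
of the duplicated region. This stage grows the region block-by-block: for
every suspected block, the color histograms of its eight block-sized compass
neighbors are compared with the block's own histogram by Euclidean distance,
and the closest neighbor is absorbed when the distance falls below a
threshold. Newly absorbed blocks join the frontier; blocks with more SIFT
keypoints are expanded first. Remaining gaps are filled by a morphological
closing with a disk structuring element (radius 5 by default).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from sec.block_grid import BlockGrid
from sec.eom_matcher import SuspicionMap

__all__ = [
    "color_histogram",
    "histogram_distance",
    "neighbor_blocks",
    "expand_regions",
    "morphological_close",
]

# compass offsets (drow, dcol) in units of the block size, in the listed
# angle order 45°, 90°, ..., 360° (45 = up-right, 90 = up, 360 = right)
_NEIGHBOR_OFFSETS = (
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
    (0, 1),
)


def color_histogram(
    img: np.ndarray, origin: tuple[int, int], block_size: int, n_bins: int = 32
) -> np.ndarray:
    """Per-channel, L1-normalized intensity histogram of one block.

    Returns a ``(3, n_bins)`` array; each channel's bins are equal-width over
    [0, 255] and sum to 1.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    r, c = origin
    b = block_size
    if r < 0 or c < 0 or r + b > img.shape[0] or c + b > img.shape[1]:
        raise ValueError("block window outside image")
    window = img[r : r + b, c : c + b]
    hist = np.empty((3, n_bins), dtype=np.float64)
    for ch in range(3):
        counts, _ = np.histogram(window[..., ch], bins=n_bins, range=(0, 255))
        hist[ch] = counts / counts.sum()
    return hist


def histogram_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """Euclidean distance between two concatenated histogram descriptors."""
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ValueError(f"histogram layout mismatch: {h1.shape} vs {h2.shape}")
    return float(np.linalg.norm((h1 - h2).ravel()))


def neighbor_blocks(
    origin: tuple[int, int], image_shape: tuple[int, int], block_size: int
) -> list[tuple[int, int]]:
    """In-image block origins at the eight compass offsets of ``origin``.

    Offsets are one block size per axis; neighbors whose windows would leave
    the image are omitted. Order follows the compass angles 45°, 90°, …, 360°.
    """
    h, w = image_shape
    b = block_size
    r, c = origin
    out: list[tuple[int, int]] = []
    for dr, dc in _NEIGHBOR_OFFSETS:
        nr, nc = r + dr * b, c + dc * b
        if 0 <= nr <= h - b and 0 <= nc <= w - b:
            out.append((nr, nc))
    return out


def _suspected_block_origins(suspicion: np.ndarray, block_size: int) -> np.ndarray:
    """Block origins whose window is majority-suspected, row-major (K, 2)."""
    b = block_size
    windows = np.lib.stride_tricks.sliding_window_view(
        suspicion.astype(np.float64), (b, b)
    )
    means = windows.mean(axis=(2, 3))
    rows, cols = np.nonzero(means >= 0.5 - 1e-12)
    return np.column_stack([rows, cols])


def expand_regions(
    img: np.ndarray,
    suspicion: SuspicionMap,
    grid: BlockGrid,
    distance_threshold: float = 0.1,
    max_rounds: int = 50,
    n_bins: int = 32,
) -> np.ndarray:
    """Grow the suspected region by color-histogram matching.

    Seeds are the blocks whose windows are majority-covered by the binarized
    suspicion map, processed in descending keypoint-count order (ties broken
    row-major). Each processed block absorbs its minimum-distance in-image
    neighbor when that distance is at most ``distance_threshold``; absorbed
    blocks join the next round's frontier. Expansion stops when a round adds
    nothing or after ``max_rounds`` rounds. The output mask always contains
    the input suspected pixels.
    """
    if distance_threshold < 0:
        raise ValueError("distance_threshold must be >= 0")
    img = np.asarray(img)
    b = grid.block_size
    binarized = np.asarray(suspicion.binarized, dtype=bool)
    if binarized.shape != (grid.height, grid.width):
        raise ValueError("suspicion map does not match grid dimensions")
    mask = binarized.copy()
    seeds = _suspected_block_origins(binarized, b)
    if seeds.size == 0:
        return mask

    visited: set[tuple[int, int]] = {tuple(o) for o in seeds}
    hist_cache: dict[tuple[int, int], np.ndarray] = {}

    def hist(origin: tuple[int, int]) -> np.ndarray:
        h = hist_cache.get(origin)
        if h is None:
            h = color_histogram(img, origin, b, n_bins)
            hist_cache[origin] = h
        return h

    def priority(origin: tuple[int, int]) -> tuple[int, int, int]:
        return (
            -int(grid.keypoint_counts[origin[0], origin[1]]),
            origin[0],
            origin[1],
        )

    frontier = sorted((tuple(o) for o in seeds), key=priority)
    for _ in range(max_rounds):
        if not frontier:
            break
        next_frontier: list[tuple[int, int]] = []
        for origin in frontier:
            neighbors = neighbor_blocks(origin, (grid.height, grid.width), b)
            if not neighbors:
                continue
            h0 = hist(origin)
            dists = [histogram_distance(h0, hist(nb)) for nb in neighbors]
            best = int(np.argmin(dists))  # first minimum wins ties
            if dists[best] > distance_threshold:
                continue
            chosen = neighbors[best]
            if chosen in visited:
                continue
            visited.add(chosen)
            r, c = chosen
            mask[r : r + b, c : c + b] = True
            next_frontier.append(chosen)
        frontier = sorted(next_frontier, key=priority)
    return mask


def morphological_close(mask: np.ndarray, radius: int = 5) -> np.ndarray:
    """Binary closing (dilation then erosion) with a disk of the given radius.

    The disk contains every pixel within Euclidean distance ``radius`` of its
    center. The mask is padded by the radius before the operation so border
    regions are treated exactly; closing is extensive and idempotent.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    footprint = disk(radius)
    padded = np.pad(mask, radius, mode="constant", constant_values=False)
    dilated = ndimage.binary_dilation(padded, structure=footprint)
    closed = ndimage.binary_erosion(dilated, structure=footprint)
    return closed[radius:-radius, radius:-radius]
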