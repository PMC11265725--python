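"""SIFT keypoint detection and assignment of keypoints to overlapping blocks.

Keypoints are used purely as suspicion seeds: no descriptor matching (g2NN or
otherwise) is performed — the decision about which blocks are forged is made
by the equilibrium matching stage. A keypoint is binned to the integer pixel
``(floor(row), floor(col))`` it falls in, and every B×B block window covering
that pixel gains one seed; keypoints sharing an integer pixel are deduplicated
so a block's count never exceeds B².
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.feature import SIFT

from sec.block_grid import BlockGrid

__all__ = ["KeypointSet", "detect_sift", "assign_keypoints", "keypoints_to_csv"]

_MIN_SIDE = 16  # minimum image side for a usable scale pyramid


@dataclass
class KeypointSet:
    """SIFT keypoints of one image: positions, scales, orientations, descriptors.

    ``rows``/``cols`` are real-valued pixel coordinates (0-based),
    ``orientations`` are in degrees, ``descriptors`` is an (n, 128) array.
    """

    rows: np.ndarray
    cols: np.ndarray
    scales: np.ndarray
    orientations: np.ndarray
    descriptors: np.ndarray
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return int(self.rows.shape[0])


def _empty_set(shape: tuple[int, int]) -> KeypointSet:
    return KeypointSet(
        rows=np.empty(0),
        cols=np.empty(0),
        scales=np.empty(0),
        orientations=np.empty(0),
        descriptors=np.empty((0, 128)),
        image_shape=shape,
    )


def detect_sift(
    gray: np.ndarray,
    contrast_threshold: float = 0.04,
    edge_threshold: float = 10.0,
) -> KeypointSet:
    """Detect SIFT keypoints on a grayscale image (0–255 scale).

    Standard SIFT semantics: difference-of-Gaussians extrema with 128-d
    gradient-histogram descriptors, computed by scikit-image's detector.
    ``contrast_threshold`` follows the convention of the original SIFT
    publication (default 0.04, applied per scale as ``c_dog = threshold / 3``);
    ``edge_threshold`` is the principal-curvature ratio limit (default 10).
    Deterministic for a fixed image and parameters. A featureless (e.g.
    constant) image yields an empty set.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    h, w = gray.shape
    if min(h, w) < _MIN_SIDE:
        raise ValueError(
            f"image {h}x{w} too small for SIFT (needs at least "
            f"{_MIN_SIDE}x{_MIN_SIDE})"
        )
    detector = SIFT(c_dog=contrast_threshold / 3.0, c_edge=edge_threshold)
    try:
        detector.detect_and_extract(gray / 255.0)
    except RuntimeError:
        # no DoG extrema (flat or near-flat image)
        return _empty_set((h, w))
    rows = detector.keypoints[:, 0].astype(np.float64)
    cols = detector.keypoints[:, 1].astype(np.float64)
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    return KeypointSet(
        rows=rows[inside],
        cols=cols[inside],
        scales=np.asarray(detector.sigmas, dtype=np.float64)[inside],
        orientations=np.degrees(
            np.asarray(detector.orientations, dtype=np.float64)
        )[inside],
        descriptors=np.asarray(detector.descriptors, dtype=np.float64)[inside],
        image_shape=(h, w),
    )


def assign_keypoints(kps: KeypointSet, grid: BlockGrid) -> np.ndarray:
    """Count, per block, the distinct keypoint pixels its window covers.

    Mutates ``grid.keypoint_counts`` in place and returns it. A keypoint at
    real position (row, col) belongs to integer pixel (⌊row⌋, ⌊col⌋); every
    block whose window contains that pixel is incremented. Counts are capped
    at B² by construction since keypoints sharing a pixel count once.
    """
    if kps.image_shape != (grid.height, grid.width):
        raise ValueError(
            f"keypoint set from image {kps.image_shape} does not match "
            f"grid image ({grid.height}, {grid.width})"
        )
    b = grid.block_size
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=np.int64)
    if len(kps):
        pixels = np.unique(
            np.column_stack(
                [np.floor(kps.rows).astype(np.int64), np.floor(kps.cols).astype(np.int64)]
            ),
            axis=0,
        )
        for r, c in pixels:
            r0 = max(0, r - b + 1)
            r1 = min(grid.n_rows - 1, r)
            c0 = max(0, c - b + 1)
            c1 = min(grid.n_cols - 1, c)
            counts[r0 : r1 + 1, c0 : c1 + 1] += 1
    grid.keypoint_counts = counts
    return counts


def keypoints_to_csv(kps: KeypointSet, path: str | Path) -> None:
    """Dump keypoints as CSV with columns row, col, scale, orientation."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "scale", "orientation"])
        for i in range(len(kps)):
            writer.writerow(
                [kps.rows[i], kps.cols[i], kps.scales[i], kps.orientations[i]]
            )
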