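"""End-to-end detection pipeline: gray → SIFT → blocks → EOM → CHM → close."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from sec.block_grid import decompose
from sec.chm_expander import expand_regions, morphological_close
from sec.config import RunConfig
from sec.eom_matcher import EomParams, SuspicionMap, run_eom
from sec.image_io import to_gray
from sec.keypoint_stage import assign_keypoints, detect_sift
from sec.metrics import image_verdict

__all__ = ["DetectionResult", "detect_forgery"]


@dataclass
class DetectionResult:
    """Output of one detection run."""

    mask: np.ndarray  # final boolean tamper mask
    verdict: bool  # True = forged
    n_keypoints: int
    n_candidates: int
    suspicion: SuspicionMap
    stage_seconds: dict[str, float] = field(default_factory=dict)


def detect_forgery(img: np.ndarray, config: RunConfig | None = None) -> DetectionResult:
    """Run the full three-stage detector on an RGB image.

    Deterministic given ``config.seed``. Images with fewer than four
    candidate blocks (e.g. featureless images with no SIFT keypoints) are
    declared authentic with an empty mask.
    """
    if config is None:
        config = RunConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    gray = to_gray(img, variant=config.gray_variant)
    timings["gray"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    kps = detect_sift(
        gray,
        contrast_threshold=config.contrast_threshold,
        edge_threshold=config.edge_threshold,
    )
    timings["sift"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    grid = decompose(gray, config.block_size)
    assign_keypoints(kps, grid)
    n_candidates = int(grid.candidate_origins().shape[0])
    timings["blocks"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    params = EomParams(
        a1=config.a1,
        a2=config.a2,
        gp=config.gp,
        max_iter=config.max_iter,
        lambda_floor=config.lambda_floor,
        seed=config.seed,
        white_black_threshold=config.threshold,
        f_variant=config.f_variant,
    )
    suspicion = run_eom(gray, grid, params)
    timings["eom"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    expanded = expand_regions(
        img,
        suspicion,
        grid,
        distance_threshold=config.distance_threshold,
        max_rounds=config.max_rounds,
        n_bins=config.n_bins,
    )
    mask = morphological_close(expanded, radius=config.closing_radius)
    timings["chm"] = time.perf_counter() - t0

    verdict = image_verdict(mask, min_region_pixels=config.min_region_pixels)
    return DetectionResult(
        mask=mask,
        verdict=verdict,
        n_keypoints=len(kps),
        n_candidates=n_candidates,
        suspicion=suspicion,
        stage_seconds=timings,
    )
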