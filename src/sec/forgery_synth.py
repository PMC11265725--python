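"""Synthetic medical-like images with copy-move forgeries and exact masks.

The generator emulates the kind of test material used for copy-move studies
on CT/radiology teaching images: a dark background, a handful of overlapping
soft-edged elliptical "organ" structures at soft-tissue intensities, and
band-limited texture so a SIFT detector finds keypoints. Forgeries copy a
rectangular region and paste it elsewhere in the same image, optionally
rotated (5/10/15° are the typical study conditions) and optionally followed
by global zero-mean Gaussian noise (sigma 0.1 on the unit intensity scale).
The ground-truth mask marks both members of the duplicated pair: the source
rectangle and the pasted destination pixels.

What this emulates — and what it does not — is discussed in
``docs/methods.md``; notably the images are not DICOM-derived and contain no
acquisition artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, transform

from sec.image_io import write_mask

__all__ = [
    "ForgerySpec",
    "CATEGORIES",
    "generate_base_image",
    "apply_copy_move",
    "make_forgery",
    "make_dataset",
]

CATEGORIES = ("simple", "rot5", "rot10", "rot15", "noise")
_CATEGORY_PARAMS = {
    "simple": (0.0, 0.0),
    "rot5": (5.0, 0.0),
    "rot10": (10.0, 0.0),
    "rot15": (15.0, 0.0),
    "noise": (0.0, 0.1),  # Gaussian factor 0.1 on the unit scale
}


@dataclass(frozen=True)
class ForgerySpec:
    """Parameters of one copy-move forgery.

    ``noise_sigma`` is the Gaussian noise standard deviation on the [0, 1]
    intensity scale (i.e. sigma·255 in 8-bit units), applied to the whole
    image after pasting. Source and destination rectangles must be disjoint
    unless ``allow_overlap`` is set — overlapping pairs would make the
    ground truth ambiguous.
    """

    source_origin: tuple[int, int]
    region_size: tuple[int, int]
    dest_origin: tuple[int, int]
    rotation: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    allow_overlap: bool = False


def generate_base_image(seed: int, height: int = 256, width: int = 256) -> np.ndarray:
    """Deterministic anatomy-like RGB test image.

    Dark background (~20), 4–7 soft-edged overlapping ellipses at
    soft-tissue-like intensities, plus band-limited texture (Gaussian noise
    smoothed at sigma 1.5, rescaled to std 8) so SIFT finds keypoints.
    Channels are near-grayscale: a fixed ±2% per-channel gain.
    """
    if height < 64 or width < 64:
        raise ValueError("base image must be at least 64x64")
    rng = np.random.default_rng(seed)
    canvas = np.full((height, width), 20.0)
    n_ellipses = int(rng.integers(4, 8))
    for _ in range(n_ellipses):
        cr = rng.uniform(0.15, 0.85) * height
        cc = rng.uniform(0.15, 0.85) * width
        r_rad = rng.uniform(0.08, 0.28) * height
        c_rad = rng.uniform(0.08, 0.28) * width
        angle = rng.uniform(0.0, np.pi)
        level = rng.uniform(40.0, 120.0)
        rr, cc_idx = draw.ellipse(
            cr, cc, r_rad, c_rad, shape=(height, width), rotation=angle
        )
        layer = np.zeros((height, width))
        layer[rr, cc_idx] = level
        # soft edges: additive layers blend where ellipses overlap
        canvas += ndimage.gaussian_filter(layer, sigma=3.0) * 0.6
    texture = rng.normal(0.0, 1.0, size=(height, width))
    texture = ndimage.gaussian_filter(texture, sigma=1.5)
    texture *= 8.0 / max(texture.std(), 1e-12)
    gray = np.clip(canvas + texture, 0.0, 255.0)
    gains = np.array([1.02, 1.0, 0.98])
    rgb = np.clip(gray[..., None] * gains[None, None, :], 0.0, 255.0)
    return rgb.astype(np.uint8)


def _check_window(origin: tuple[int, int], size: tuple[int, int], shape) -> None:
    r, c = origin
    h, w = size
    if r < 0 or c < 0 or h < 1 or w < 1 or r + h > shape[0] or c + w > shape[1]:
        raise ValueError(f"window {origin}+{size} outside image {shape[:2]}")


def _windows_overlap(spec: ForgerySpec) -> bool:
    (sr, sc), (h, w), (dr, dc) = (
        spec.source_origin,
        spec.region_size,
        spec.dest_origin,
    )
    return sr < dr + h and dr < sr + h and sc < dc + w and dc < sc + w


def apply_copy_move(
    img: np.ndarray, spec: ForgerySpec
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one copy-move forgery; return the forged image and its mask.

    The source window is rotated about its center with bilinear
    interpolation; destination pixels where the rotated indicator window
    reaches at least 0.5 (majority coverage) are overwritten. With
    ``noise_sigma > 0``, zero-mean Gaussian noise of that sigma (unit scale)
    is added to the whole image and clipped. The mask marks the source
    rectangle and the pasted destination pixels.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    _check_window(spec.source_origin, spec.region_size, img.shape)
    _check_window(spec.dest_origin, spec.region_size, img.shape)
    if not spec.allow_overlap and _windows_overlap(spec):
        raise ValueError("source and destination windows overlap")
    (sr, sc), (h, w), (dr, dc) = (
        spec.source_origin,
        spec.region_size,
        spec.dest_origin,
    )
    out = img.astype(np.float64)
    patch = out[sr : sr + h, sc : sc + w].copy()
    if spec.rotation != 0.0:
        rotated = transform.rotate(
            patch, spec.rotation, resize=False, order=1, preserve_range=True
        )
        indicator = (
            transform.rotate(
                np.ones((h, w)), spec.rotation, resize=False, order=1
            )
            >= 0.5
        )
    else:
        rotated = patch
        indicator = np.ones((h, w), dtype=bool)
    dest = out[dr : dr + h, dc : dc + w]
    dest[indicator] = rotated[indicator]
    mask = np.zeros(img.shape[:2], dtype=bool)
    mask[sr : sr + h, sc : sc + w] = True
    mask[dr : dr + h, dc : dc + w] |= indicator
    if spec.noise_sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        out = out + rng.normal(0.0, spec.noise_sigma * 255.0, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), mask


def make_forgery(
    seed: int,
    height: int = 256,
    width: int = 256,
    category: str = "simple",
    region_size: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, ForgerySpec]:
    """Generate one forged image in memory: (image, mask, spec).

    ``region_size`` defaults to sides drawn uniformly from [32, 64], capped
    at half the image side so a disjoint source/destination pair exists.
    Source and destination are drawn until disjoint. Deterministic per seed.
    """
    if category not in _CATEGORY_PARAMS:
        raise ValueError(f"unknown category {category!r}")
    rotation, noise_sigma = _CATEGORY_PARAMS[category]
    rng = np.random.default_rng(seed)
    base = generate_base_image(seed, height, width)
    if region_size is None:
        hi = min(64, min(height, width) // 2)
        lo = min(32, hi)
        h = int(rng.integers(lo, hi + 1))
        w = int(rng.integers(lo, hi + 1))
    else:
        h, w = region_size
    for _ in range(1000):
        sr = int(rng.integers(0, height - h + 1))
        sc = int(rng.integers(0, width - w + 1))
        dr = int(rng.integers(0, height - h + 1))
        dc = int(rng.integers(0, width - w + 1))
        spec = ForgerySpec(
            source_origin=(sr, sc),
            region_size=(h, w),
            dest_origin=(dr, dc),
            rotation=rotation,
            noise_sigma=noise_sigma,
            seed=seed,
        )
        if not _windows_overlap(spec):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw disjoint source/destination")
    forged, mask = apply_copy_move(base, spec)
    return forged, mask, spec


_MANIFEST_COLUMNS = [
    "path",
    "category",
    "mask_path",
    "src_row",
    "src_col",
    "h",
    "w",
    "dst_row",
    "dst_col",
    "rotation",
    "noise_sigma",
    "seed",
]


def make_dataset(
    out_dir: str | Path,
    n_per_category: int,
    base_size: int = 256,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a synthetic dataset: originals, five forged categories, masks.

    Produces ``n_per_category`` originals plus ``n_per_category`` images for
    each of the five forged categories (simple, rot5, rot10, rot15, noise),
    each forged image with a mask PNG, plus ``manifest.csv``. Fully
    reproducible per seed. Returns the manifest as a DataFrame.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    from PIL import Image

    records: list[dict] = []
    child = np.random.SeedSequence(seed).generate_state(
        (1 + len(CATEGORIES)) * n_per_category
    ) % (2**31)
    k = 0
    for i in range(n_per_category):
        img = generate_base_image(int(child[k]), base_size, base_size)
        k += 1
        name = f"original_{i:03d}.png"
        Image.fromarray(img).save(out_dir / name)
        records.append(
            {
                "path": name,
                "category": "original",
                "mask_path": "",
                "src_row": -1,
                "src_col": -1,
                "h": -1,
                "w": -1,
                "dst_row": -1,
                "dst_col": -1,
                "rotation": 0.0,
                "noise_sigma": 0.0,
                "seed": int(child[k - 1]),
            }
        )
    for category in CATEGORIES:
        for i in range(n_per_category):
            s = int(child[k])
            k += 1
            forged, mask, spec = make_forgery(s, base_size, base_size, category)
            name = f"{category}_{i:03d}.png"
            mask_name = f"{category}_{i:03d}_mask.png"
            Image.fromarray(forged).save(out_dir / name)
            write_mask(mask, out_dir / mask_name)
            records.append(
                {
                    "path": name,
                    "category": category,
                    "mask_path": mask_name,
                    "src_row": spec.source_origin[0],
                    "src_col": spec.source_origin[1],
                    "h": spec.region_size[0],
                    "w": spec.region_size[1],
                    "dst_row": spec.dest_origin[0],
                    "dst_col": spec.dest_origin[1],
                    "rotation": spec.rotation,
                    "noise_sigma": spec.noise_sigma,
                    "seed": s,
                }
            )
    manifest = pd.DataFrame.from_records(records, columns=_MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
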