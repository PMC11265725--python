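"""Raster I/O and grayscale conversion.

Images are plain numpy arrays: RGB images are ``uint8`` of shape ``(H, W, 3)``,
grayscale images are ``float64`` of shape ``(H, W)`` on the 0–255 scale, and
forgery masks are boolean ``(H, W)`` arrays (True = tampered).

Grayscale conversion defaults to the weights 0.299 R + 0.583 G + 0.116 B used
by the detector; the common ITU-R BT.601 weights (0.299, 0.587, 0.114) are
available as a variant since the default looks like a transcription of them.
Gray values stay real-valued internally — quantization to 8-bit happens only
at file export — so block standard deviations are not contaminated by rounding.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "GRAY_WEIGHTS",
    "GRAY_WEIGHTS_BT601",
    "read_image",
    "to_gray",
    "write_mask",
    "read_mask",
]

GRAY_WEIGHTS = (0.299, 0.583, 0.116)
GRAY_WEIGHTS_BT601 = (0.299, 0.587, 0.114)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG/BMP file as an ``(H, W, 3) uint8`` RGB array.

    Single-channel files are replicated to three identical channels; 16-bit
    inputs are rescaled linearly to [0, 255]; an alpha channel is dropped.

    Raises
    ------
    IOError
        If the file is missing, truncated or not a decodable image.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.float64)
                peak = max(arr.max(), 1.0)
                scale = 255.0 / 65535.0 if peak > 255 else 1.0
                arr = np.clip(arr * scale, 0, 255).astype(np.uint8)
                im = Image.fromarray(arr, mode="L")
            if im.mode != "RGB":
                im = im.convert("RGB")
            data = np.asarray(im, dtype=np.uint8)
    except OSError as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if data.ndim != 3 or data.shape[2] != 3:
        raise IOError(f"cannot read image {path}: unexpected shape {data.shape}")
    return data


def to_gray(img: np.ndarray, variant: str = "printed") -> np.ndarray:
    """Convert an RGB image to a real-valued grayscale array on [0, 255].

    ``variant`` selects the channel weights: ``"printed"`` (default) uses
    (0.299, 0.583, 0.116) whose sum is 0.998, ``"bt601"`` the ITU-R BT.601
    luma weights.
    """
    data = np.asarray(img, dtype=np.float64)
    if data.ndim != 3 or data.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {data.shape}")
    if variant == "printed":
        w = GRAY_WEIGHTS
    elif variant == "bt601":
        w = GRAY_WEIGHTS_BT601
    else:
        raise ValueError(f"unknown grayscale variant {variant!r}")
    return data[..., 0] * w[0] + data[..., 1] * w[1] + data[..., 2] * w[2]


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean tamper mask as a lossless single-channel PNG.

    Encoding is {0, 255}; ``read_mask`` inverts it bit-exactly.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    data = np.where(mask.astype(bool), 255, 0).astype(np.uint8)
    try:
        Image.fromarray(data, mode="L").save(Path(path), format="PNG")
    except OSError as exc:
        raise IOError(f"cannot write mask {path}: {exc}") from exc


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG back as a boolean array (any nonzero pixel = True)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode != "L":
                im = im.convert("L")
            data = np.asarray(im, dtype=np.uint8)
    except OSError as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    return data > 0
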