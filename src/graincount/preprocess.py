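"""Image loading, working-resolution downscale, and Otsu binarization.

The pipeline operates on photographs of grains scattered on white paper.
Preprocessing reduces such a photograph to a binary foreground mask:
grayscale conversion, Gaussian denoising, a global Otsu threshold, an
automatic foreground-polarity decision, and a small-blob noise filter.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
from PIL import Image, ImageOps, UnidentifiedImageError
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .config import PipelineConfig

__all__ = [
    "load_image",
    "resize_long_side",
    "to_grayscale",
    "binarize",
    "preprocess_image",
    "InputImageError",
]

#: minimum gray-level spread for a scene to be considered non-degenerate;
#: a blank sheet of paper with sensor noise stays well below this.
_MIN_CONTRAST = 25.0


class InputImageError(ValueError):
    """Raised when an input photograph cannot be read or decoded."""


def load_image(path: str) -> np.ndarray:
    """Load a JPEG/PNG photograph as an 8-bit array.

    EXIF orientation is applied so the returned pixel order matches the
    display orientation.  Alpha channels are dropped (composited over
    white); grayscale images come back 2-D, colour images ``(H, W, 3)``.
    """
    if not os.path.exists(path):
        raise InputImageError(f"input image does not exist: {path}")
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            if im.mode in ("RGBA", "LA", "P"):
                im = im.convert("RGBA")
                bg = Image.new("RGBA", im.size, (255, 255, 255, 255))
                im = Image.alpha_composite(bg, im).convert("RGB")
            elif im.mode not in ("L", "RGB"):
                im = im.convert("RGB")
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise InputImageError(f"unsupported or corrupt image file: {path}") from exc
    except OSError as exc:
        raise InputImageError(f"cannot read image: {path}") from exc
    return arr


def resize_long_side(img: np.ndarray, target_long_side: int) -> np.ndarray:
    """Downscale so the long side equals ``target_long_side``; never upscale.

    Aspect ratio is preserved (short side rounded to the nearest integer,
    minimum 1).  Downscaling uses area-averaging (anti-aliased) resampling.
    """
    if target_long_side < 1:
        raise ValueError("target_long_side must be >= 1")
    h, w = img.shape[:2]
    long_side = max(h, w)
    if long_side <= target_long_side:
        return img
    scale = target_long_side / long_side
    new_h = max(1, int(round(h * scale)))
    new_w = max(1, int(round(w * scale)))
    if h >= w:
        new_h = target_long_side
    else:
        new_w = target_long_side
    pil = Image.fromarray(img)
    resized = pil.resize((new_w, new_h), resample=Image.Resampling.BOX)
    return np.asarray(resized)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Standard luminance conversion (Rec. 601 weights) to float gray."""
    if img.ndim == 2:
        return img.astype(np.float64)
    if img.ndim == 3 and img.shape[2] >= 3:
        rgb = img[..., :3].astype(np.float64)
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"unsupported image shape {img.shape}")


def binarize(img: np.ndarray, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Binarize a photograph into a grain-foreground mask.

    Steps: grayscale -> Gaussian smoothing -> global Otsu threshold ->
    polarity resolution -> small-blob removal.  Otsu yields two classes;
    the one occupying the smaller fraction of the image border is taken as
    foreground (on a white-paper scene the background touches the border
    almost everywhere), which also handles light-on-dark fixtures.

    A nearly uniform image (Otsu degenerate, e.g. an empty sheet) produces
    an all-background mask and a warning rather than an exception.
    """
    cfg = cfg or PipelineConfig()
    gray = to_grayscale(img)
    if gray.size == 0:
        raise ValueError("empty image")
    smooth = ndi.gaussian_filter(gray, sigma=cfg.effective_sigma)
    if float(smooth.max() - smooth.min()) < _MIN_CONTRAST:
        warnings.warn(
            "image is nearly uniform; Otsu threshold is degenerate -> "
            "returning an empty foreground mask",
            stacklevel=2,
        )
        return np.zeros(gray.shape, dtype=bool)
    t = threshold_otsu(smooth)
    dark = smooth < t
    border = np.concatenate(
        [dark[0, :], dark[-1, :], dark[1:-1, 0], dark[1:-1, -1]]
    )
    fg = dark if border.mean() <= 0.5 else ~dark
    if cfg.min_blob_area > 1:
        # drop components strictly smaller than the noise floor
        fg = remove_small_objects(fg, max_size=cfg.min_blob_area - 1, connectivity=2)
    return fg


def preprocess_image(path: str, cfg: PipelineConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load → downscale → binarize; returns ``(working_image, mask)``."""
    cfg = cfg or PipelineConfig()
    img = load_image(path)
    img = resize_long_side(img, cfg.target_long_side)
    return img, binarize(img, cfg)
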