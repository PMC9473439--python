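"""Result display: red-dot / yellow-number annotation and its aggregation.

Every counted region gets a red dot at its centroid.  Regions holding two
or more grains additionally get a yellow number at the upper right of the
dot; such a dot no longer counts as a single grain.  The image total is
therefore: (dots without a number) + (sum of the numbers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .counting import CountResult

__all__ = ["Annotation", "build_annotation", "total_from_annotation", "annotate_image"]

_RED = (220, 30, 30)
_YELLOW = (240, 200, 20)


@dataclass
class Annotation:
    """Render directives: one dot per region, numbers on multi-grain regions."""

    dots: list[tuple[float, float]] = field(default_factory=list)
    adhesion_labels: list[tuple[tuple[float, float], int]] = field(default_factory=list)


def build_annotation(result: CountResult) -> Annotation:
    ann = Annotation()
    for (centroid, count) in result.annotations:
        ann.dots.append(centroid)
        if count >= 2:
            ann.adhesion_labels.append((centroid, count))
    return ann


def total_from_annotation(ann: Annotation) -> int:
    """Dots without a number + sum of the numbers."""
    labeled = {tuple(pos) for pos, _ in ann.adhesion_labels}
    plain = sum(1 for d in ann.dots if tuple(d) not in labeled)
    return plain + sum(count for _, count in ann.adhesion_labels)


def annotate_image(img: np.ndarray, result: CountResult, dot_radius: int = 4) -> np.ndarray:
    """Return an annotated copy of ``img``; the original is untouched.

    Red dots mark region centroids; yellow counts sit at the upper right
    of dots on regions holding >= 2 grains.  Centroids outside the image
    are skipped with a warning.
    """
    if img.ndim == 2:
        canvas = np.stack([img] * 3, axis=-1)
    else:
        canvas = img[..., :3].copy()
    H, W = canvas.shape[:2]
    pil = Image.fromarray(canvas.astype(np.uint8))
    draw = ImageDraw.Draw(pil)
    ann = build_annotation(result)
    labeled = {tuple(pos): count for pos, count in ann.adhesion_labels}
    for (r, c) in ann.dots:
        if not (0 <= r < H and 0 <= c < W):
            warnings.warn(f"annotation centroid ({r:.0f}, {c:.0f}) outside image; skipped",
                          stacklevel=2)
            continue
        draw.ellipse(
            [c - dot_radius, r - dot_radius, c + dot_radius, r + dot_radius],
            fill=_RED,
        )
        count = labeled.get((r, c))
        if count is not None:
            draw.text((c + dot_radius + 2, r - dot_radius - 10), str(count), fill=_YELLOW)
    return np.asarray(pil)
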