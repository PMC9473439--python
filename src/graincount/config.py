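"""Pipeline configuration.

All tunable parameters of the counting pipeline live in one dataclass so a
run is fully described by (image, config, seed).  Defaults are the operating
point of the method: a 1920-px working resolution, erosion scale w = 0.4 of
the grain short axis, a 13x13 corner window with a 0.66 foreground-fraction
threshold, and the linear-adhesion rule (skeleton longer than 1.5x the mean
with a nearly straight, 160-200 degree included angle).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Parameters controlling every stage of the grain-counting pipeline.

    Parameters
    ----------
    target_long_side:
        Working resolution: photographs whose long side exceeds this many
        pixels are downscaled so the long side equals it (never upscaled).
    gaussian_kernel:
        Odd side length (px) of the Gaussian denoising kernel applied before
        Otsu thresholding.
    gaussian_sigma:
        Gaussian sigma; ``0`` derives it from the kernel size using the
        conventional ``0.3*((k-1)*0.5 - 1) + 0.8`` rule.
    w:
        Erosion scale coefficient: each region is eroded by a disk of
        diameter ``e = w * X`` where X is the region's short axis.
    corner_window:
        Odd side length (px) of the window used to score boundary pixels for
        concave corner detection.
    corner_fraction:
        A boundary pixel is a corner candidate when the foreground fraction
        of its window strictly exceeds this value.
    length_factor:
        Linear-adhesion rule: a region qualifies only if its skeleton is
        longer than ``length_factor`` times the image-mean skeleton length.
    angle_band:
        Inclusive (low, high) band in degrees for the included angle at the
        skeleton midpoint; (160, 200) means "nearly straight".
    min_blob_area:
        Connected components smaller than this many px^2 are discarded as
        noise.
    random_seed:
        Seed recorded with results for provenance of any stochastic step.
    """

    target_long_side: int = 1920
    gaussian_kernel: int = 5
    gaussian_sigma: float = 0.0
    w: float = 0.4
    corner_window: int = 13
    corner_fraction: float = 0.66
    length_factor: float = 1.5
    angle_band: tuple[float, float] = (160.0, 200.0)
    min_blob_area: int = 9
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_long_side < 1:
            raise ValueError("target_long_side must be >= 1")
        if self.gaussian_kernel < 1 or self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be odd and >= 1")
        if not 0.0 < self.w < 1.0:
            raise ValueError("w must lie strictly between 0 and 1")
        if self.corner_window < 3 or self.corner_window % 2 == 0:
            raise ValueError("corner_window must be odd and >= 3")
        if not 0.0 < self.corner_fraction < 1.0:
            raise ValueError("corner_fraction must lie strictly in (0, 1)")
        if self.length_factor <= 0:
            raise ValueError("length_factor must be positive")
        lo, hi = self.angle_band
        if not (0 <= lo <= 360 and 0 <= hi <= 360):
            raise ValueError("angle_band must lie within [0, 360]")
        self.angle_band = (float(lo), float(hi))
        if self.min_blob_area < 0:
            raise ValueError("min_blob_area must be non-negative")

    # -- effective derived values ------------------------------------------

    @property
    def effective_sigma(self) -> float:
        """Gaussian sigma actually used (auto-derived when sigma <= 0)."""
        if self.gaussian_sigma > 0:
            return float(self.gaussian_sigma)
        k = self.gaussian_kernel
        return 0.3 * ((k - 1) * 0.5 - 1) + 0.8

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["angle_band"] = list(self.angle_band)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "angle_band" in d:
            d["angle_band"] = tuple(d["angle_band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Short stable hash identifying this parameterisation in logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
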