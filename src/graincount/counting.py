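"""Region topology, concave corner points, and the grain-count formula.

After adaptive erosion has split most adhesions, any region may still hold
several grains.  Three topology classes occur: a single grain, an adhesion
cluster, and an adhesion cluster enclosing holes (e.g. a ring of grains).
Each junction between two adhered convex grains creates a pair of concave
boundary points; a hole "absorbs" one grain-equivalent.  The per-region
estimate is therefore

    count = C/2 - H + 1

with C the number of detected concave corner points and H the number of
enclosed background holes.

A corner point is a boundary pixel whose surrounding window (13x13 by
default) contains a foreground fraction above 0.66 and is a local maximum
of that fraction — convex or straight boundary sits near 0.5, while a
concave junction pushes past the threshold.

Nearly collinear overlaps can occlude a junction's corners entirely; such
regions are recognised by an abnormally long, nearly straight skeleton
(length > 1.5x the image mean, included angle within 160-200 degrees) and
counted by dividing their area by the mean single-grain area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.segmentation import watershed

from .config import PipelineConfig
from .morphology import (
    Skeleton,
    ShortAxisEstimate,
    estimate_short_axis,
    separate,
    skeletonize_region,
)

__all__ = [
    "GrainRegion",
    "CornerPoint",
    "RegionCount",
    "CountResult",
    "label_regions",
    "count_holes",
    "detect_corners",
    "region_count_formula",
    "is_linear_adhesion",
    "average_area_count",
    "count_image",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class GrainRegion:
    """One 8-connected foreground region with its derived geometry.

    ``mask_crop`` is the region's pixels within ``bbox`` (row, col, height,
    width); coordinates reported by other fields are in full-image frame.
    """

    id: int
    bbox: tuple[int, int, int, int]
    mask_crop: np.ndarray
    area: int
    centroid: tuple[float, float]
    holes: int
    skeleton: Skeleton
    short_axis: ShortAxisEstimate

    @property
    def pixel_set(self) -> np.ndarray:
        r0, c0, _, _ = self.bbox
        return np.argwhere(self.mask_crop) + np.array([r0, c0])


@dataclass
class CornerPoint:
    """A concave boundary location: windowed foreground fraction peak."""

    position: tuple[int, int]
    score: float


@dataclass
class RegionCount:
    region_id: int
    raw_value: float
    corrected: int
    method: str  # 'single' | 'corner_formula' | 'average_area'
    corners_used: int
    holes_used: int
    centroid: tuple[float, float] = (0.0, 0.0)


@dataclass
class CountResult:
    total: int
    regions: list[RegionCount] = field(default_factory=list)
    mean_single_area: float = 0.0
    annotations: list[tuple[tuple[float, float], int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# region extraction


def count_holes(region_mask: np.ndarray) -> int:
    """Number of background components (4-connected) fully enclosed."""
    padded = np.pad(~region_mask.astype(bool), 1, constant_values=True)
    bg_labels, nbg = sk_label(padded, connectivity=1, return_num=True)
    border_label = bg_labels[0, 0]
    enclosed = set(np.unique(bg_labels)) - {0, border_label}
    return len(enclosed)


def _make_region(rid: int, sl: tuple, crop: np.ndarray) -> GrainRegion:
    r0, c0 = sl[0].start, sl[1].start
    area = int(crop.sum())
    rows, cols = np.nonzero(crop)
    centroid = (float(rows.mean()) + r0, float(cols.mean()) + c0)
    skel = skeletonize_region(crop)
    sax = estimate_short_axis(crop, skel)
    return GrainRegion(
        id=rid,
        bbox=(r0, c0, crop.shape[0], crop.shape[1]),
        mask_crop=crop,
        area=area,
        centroid=centroid,
        holes=count_holes(crop),
        skeleton=skel,
        short_axis=sax,
    )


def label_regions(mask: np.ndarray, cfg: PipelineConfig | None = None) -> list[GrainRegion]:
    """8-connected components of ``mask`` as `GrainRegion` records.

    Components smaller than ``cfg.min_blob_area`` are dropped as noise.
    """
    cfg = cfg or PipelineConfig()
    labels, n = sk_label(mask, connectivity=2, return_num=True)
    regions: list[GrainRegion] = []
    rid = 0
    for lab, sl in zip(range(1, n + 1), ndi.find_objects(labels)):
        crop = labels[sl] == lab
        if crop.sum() < cfg.min_blob_area:
            continue
        rid += 1
        regions.append(_make_region(rid, sl, crop))
    return regions


# ---------------------------------------------------------------------------
# corner detection


def _window_fraction_map(
    region: GrainRegion,
    image_shape: tuple[int, int],
    window: int,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Foreground fraction of the centred window at every pixel of a padded
    crop around the region, plus the region's boundary-pixel map.

    Only the region's own pixels count as foreground.  The window is
    clipped at the image borders and the fraction uses the visible window
    area, so flat boundary along the photo edge cannot fake a corner.
    """
    half = window // 2
    r0, c0, h, w = region.bbox
    H, W = image_shape
    # pad the crop so every window around a boundary pixel is fully inside,
    # but never beyond the image rectangle
    pr0 = max(0, r0 - half)
    pc0 = max(0, c0 - half)
    pr1 = min(H, r0 + h + half)
    pc1 = min(W, c0 + w + half)
    fg = np.zeros((pr1 - pr0, pc1 - pc0), dtype=np.float64)
    fg[r0 - pr0 : r0 - pr0 + h, c0 - pc0 : c0 - pc0 + w] = region.mask_crop

    # integral-image window sums with clipping at the image rectangle
    integ = np.pad(fg.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    ph, pw = fg.shape
    rows = np.arange(ph) + pr0
    cols = np.arange(pw) + pc0
    top = np.maximum(rows - half, 0) - pr0
    bot = np.minimum(rows + half + 1, H) - pr0
    left = np.maximum(cols - half, 0) - pc0
    right = np.minimum(cols + half + 1, W) - pc0
    # clip to the padded crop; outside the crop the region has no pixels
    top_c = np.clip(top, 0, ph)
    bot_c = np.clip(bot, 0, ph)
    left_c = np.clip(left, 0, pw)
    right_c = np.clip(right, 0, pw)
    # window sums via broadcasting
    tt = top_c[:, None]
    bb = bot_c[:, None]
    ll = left_c[None, :]
    rr = right_c[None, :]
    sums = integ[bb, rr] - integ[tt, rr] - integ[bb, ll] + integ[tt, ll]
    # visible window area clipped at image borders only
    vis_h = (np.minimum(rows + half + 1, H) - np.maximum(rows - half, 0))[:, None]
    vis_w = (np.minimum(cols + half + 1, W) - np.maximum(cols - half, 0))[None, :]
    frac = sums / (vis_h * vis_w)

    # boundary pixels: region pixels with a 4-connected background neighbour
    # inside the image — the photo edge itself is not part of the outline,
    # so a grain cut by the image border cannot fake corners there
    reg = fg.astype(bool)
    pad_val = np.pad(reg, 1, constant_values=True)
    # outside the padded crop: image border -> foreground (not outline);
    # crop border inside the image -> background
    if pr0 > 0:
        pad_val[0, :] = False
    if pr1 < H:
        pad_val[-1, :] = False
    if pc0 > 0:
        pad_val[:, 0] = False
    if pc1 < W:
        pad_val[:, -1] = False
    interior = ndi.binary_erosion(
        pad_val, structure=ndi.generate_binary_structure(2, 1)
    )[1:-1, 1:-1]
    boundary = reg & ~interior
    return frac, boundary, (pr0, pc0)


def detect_corners(
    region: GrainRegion,
    image_shape: tuple[int, int],
    cfg: PipelineConfig | None = None,
) -> list[CornerPoint]:
    """Concave corner points of one region.

    Every boundary pixel is scored with the foreground fraction of its
    centred ``corner_window`` square; candidates exceed
    ``corner_fraction`` strictly, and returned corners are candidates that
    are local maxima among candidates within a ``corner_window``-radius
    (Chebyshev) neighbourhood.  Ties break toward earlier scan order
    (top-to-bottom, left-to-right).  Convex regions return no corners.
    """
    cfg = cfg or PipelineConfig()
    window = cfg.corner_window
    frac, boundary, (pr0, pc0) = _window_fraction_map(region, image_shape, window)
    cand_mask = boundary & (frac > cfg.corner_fraction)
    cand = np.argwhere(cand_mask)  # already scan order
    if len(cand) == 0:
        return []
    scores = frac[cand[:, 0], cand[:, 1]]
    keep: list[int] = []
    radius = window
    for i in range(len(cand)):
        ri, ci = cand[i]
        si = scores[i]
        dominated = False
        for j in range(len(cand)):
            if j == i:
                continue
            if max(abs(int(cand[j, 0]) - ri), abs(int(cand[j, 1]) - ci)) > radius:
                continue
            sj = scores[j]
            if sj > si or (sj == si and j < i):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return [
        CornerPoint(position=(int(cand[i, 0]) + pr0, int(cand[i, 1]) + pc0),
                    score=float(scores[i]))
        for i in keep
    ]


# ---------------------------------------------------------------------------
# the count formula and its corrections


def region_count_formula(n_corners: int, holes: int) -> float:
    """Per-region grain estimate: ``n_corners / 2 - holes + 1``."""
    if n_corners < 0 or holes < 0:
        raise ValueError("corner and hole counts must be non-negative")
    return n_corners / 2.0 - holes + 1.0


def _segment_direction(points: np.ndarray) -> np.ndarray | None:
    """Unit direction of a least-squares line through ordered points,
    oriented from the first point toward the last."""
    if len(points) < 2:
        return None
    pts = points.astype(float)
    centered = pts - pts.mean(axis=0)
    # principal axis via SVD
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if d @ (pts[-1] - pts[0]) < 0:
        d = -d
    n = np.linalg.norm(d)
    return d / n if n > 0 else None


def skeleton_included_angle(skel: Skeleton) -> float | None:
    """Included angle (degrees) at the midpoint of the longest skeleton path.

    Straight line segments are fitted to the two halves of the path; the
    included angle between them is 180 for a perfectly straight skeleton
    and shrinks as the path bends.  Returns None when undefined (<3 px).
    """
    path = skel.longest_path()
    if len(path) < 3:
        return None
    mid = len(path) // 2
    first = path[: mid + 1]
    second = path[mid:]
    d1 = _segment_direction(first)
    d2 = _segment_direction(second)
    if d1 is None or d2 is None:
        return None
    cosang = float(np.clip(d1 @ d2, -1.0, 1.0))
    turn = math.degrees(math.acos(cosang))  # 0 for collinear halves
    return 180.0 - turn


def is_linear_adhesion(
    region: GrainRegion,
    mean_skeleton_length: float,
    cfg: PipelineConfig | None = None,
) -> bool:
    """Linear-adhesion test: long, nearly straight skeleton.

    True iff the region's skeleton length strictly exceeds
    ``length_factor`` x the image-mean skeleton length AND the included
    angle at the skeleton midpoint falls inside ``angle_band`` (the band is
    checked clockwise and counterclockwise, so 160-200 means within 20
    degrees of straight).
    """
    cfg = cfg or PipelineConfig()
    if len(region.skeleton) < 3:
        return False
    if mean_skeleton_length <= 0:
        return False
    if region.skeleton.total_length <= cfg.length_factor * mean_skeleton_length:
        return False
    angle = skeleton_included_angle(region.skeleton)
    if angle is None:
        return False
    lo, hi = cfg.angle_band
    return lo <= angle <= hi or lo <= 360.0 - angle <= hi


def average_area_count(region_area: float, mean_single_area: float) -> int:
    """Count by area ratio, half-values rounded up, floored at 1."""
    if mean_single_area <= 0:
        raise ValueError("mean_single_area must be positive")
    return max(1, round_half_up(region_area / mean_single_area))


# ---------------------------------------------------------------------------
# whole-image orchestration


def _partition_by_fragments(
    parent_crop: np.ndarray, fragment_labels_crop: np.ndarray
) -> np.ndarray:
    """Partition a parent region's pixels among its eroded fragments.

    Marker-based watershed on the negated distance transform assigns every
    original pixel to the nearest fragment, reconstructing per-grain
    geometry from the original (pre-erosion) silhouette.
    """
    dt = ndi.distance_transform_edt(parent_crop)
    return watershed(-dt, markers=fragment_labels_crop, mask=parent_crop)


def count_image(mask: np.ndarray, cfg: PipelineConfig | None = None) -> CountResult:
    """Count grains in a binarized foreground mask.

    Pipeline: (1) short-axis-adaptive erosion splits adhesions; (2) each
    original region's silhouette is partitioned among its surviving
    fragments, so corner detection and hole counting always see original
    (pre-erosion) geometry; (3) the mean single-grain area is estimated
    from units that are plainly single (un-split, no corners, no holes);
    (4) each unit is counted as a single grain, by the corner formula, or —
    for linear adhesions — by the average-area method; (5) totals and
    annotation directives are assembled.
    """
    cfg = cfg or PipelineConfig()
    if not mask.any():
        warnings.warn("empty foreground mask: nothing to count", stacklevel=2)
        return CountResult(total=0)

    sep = separate(mask, cfg)
    parent_labels, n_parents = sk_label(mask, connectivity=2, return_num=True)
    frag_labels, _ = sk_label(sep, connectivity=2, return_num=True)

    # drop fragments below the noise floor (mirrors label_regions)
    frag_sizes = np.bincount(frag_labels.ravel())
    small = np.nonzero(frag_sizes < cfg.min_blob_area)[0]
    if len(small):
        frag_labels[np.isin(frag_labels, small)] = 0

    units: list[GrainRegion] = []
    unsplit: list[bool] = []
    rid = 0
    for plab, sl in zip(range(1, n_parents + 1), ndi.find_objects(parent_labels)):
        parent_crop = parent_labels[sl] == plab
        if parent_crop.sum() < cfg.min_blob_area:
            continue
        frag_crop = np.where(parent_crop, frag_labels[sl], 0)
        frag_ids = np.unique(frag_crop)
        frag_ids = frag_ids[frag_ids != 0]
        if len(frag_ids) <= 1:
            rid += 1
            units.append(_make_region(rid, sl, parent_crop))
            unsplit.append(True)
            continue
        # relabel fragments 1..k locally and partition the parent silhouette
        local = np.searchsorted(frag_ids, frag_crop) + 1
        local[frag_crop == 0] = 0
        parts = _partition_by_fragments(parent_crop, local)
        for k in range(1, len(frag_ids) + 1):
            piece = parts == k
            if not piece.any():
                continue
            psl = ndi.find_objects(piece.astype(int))[0]
            abs_sl = (
                slice(sl[0].start + psl[0].start, sl[0].start + psl[0].stop),
                slice(sl[1].start + psl[1].start, sl[1].start + psl[1].stop),
            )
            rid += 1
            units.append(_make_region(rid, abs_sl, piece[psl]))
            unsplit.append(False)

    if not units:
        warnings.warn("all foreground components fell below the noise floor",
                      stacklevel=2)
        return CountResult(total=0)

    image_shape = mask.shape
    corners_per_unit = [detect_corners(u, image_shape, cfg) for u in units]
    raws = [
        region_count_formula(len(c), u.holes)
        for u, c in zip(units, corners_per_unit)
    ]

    # mean single-grain area from plainly single units
    single_areas = [
        u.area
        for u, c, r, us in zip(units, corners_per_unit, raws, unsplit)
        if us and len(c) == 0 and u.holes == 0 and round_half_up(r) == 1
    ]
    # relaxed: a unit carved out of a split parent is also a usable single
    if len(single_areas) < 3:
        single_areas = [
            u.area
            for u, c, r in zip(units, corners_per_unit, raws)
            if len(c) == 0 and u.holes == 0 and round_half_up(r) == 1
        ]
    if len(single_areas) >= 3:
        mean_single_area = float(np.mean(single_areas))
    else:
        warnings.warn(
            "fewer than 3 single grains found; falling back to median-based "
            "mean single-grain area estimate",
            stacklevel=2,
        )
        med_area = float(np.median([u.area for u in units]))
        med_raw = float(np.median([max(1.0, r) for r in raws]))
        mean_single_area = med_area / max(1.0, med_raw)

    mean_skel_len = float(np.mean([u.skeleton.total_length for u in units]))

    region_counts: list[RegionCount] = []
    for u, cpts, raw in zip(units, corners_per_unit, raws):
        linear = is_linear_adhesion(u, mean_skel_len, cfg)
        if len(cpts) == 0 and u.holes == 0 and not linear:
            method, corrected = "single", 1
        elif linear:
            method = "average_area"
            corrected = average_area_count(u.area, mean_single_area)
        else:
            method = "corner_formula"
            corrected = max(1, round_half_up(raw))
        region_counts.append(
            RegionCount(
                region_id=u.id,
                raw_value=raw,
                corrected=corrected,
                method=method,
                corners_used=len(cpts),
                holes_used=u.holes,
                centroid=u.centroid,
            )
        )

    total = int(sum(rc.corrected for rc in region_counts))
    annotations = [
        (rc.centroid, rc.corrected) for rc in region_counts
    ]
    return CountResult(
        total=total,
        regions=region_counts,
        mean_single_area=mean_single_area,
        annotations=annotations,
    )
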