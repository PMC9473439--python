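"""Seeded synthetic grain scenes with exact ground truth.

Real evaluation photographs are grains sprinkled on white paper.  This
module renders the same situation with known truth: dark convex grains
(ellipse, wedge, or round silhouettes with the length/width proportions of
the six reference crops) on a near-white background with mild illumination
gradient and pixel noise, plus controllable pairwise adhesion — pairs and
triples forced to touch with a prescribed overlap depth.

Every scene is reproducible bit-exact from ``(seed, parameters)`` and
carries its true grain count N1, per-grain geometry, a per-pixel truth
label map, and cluster bookkeeping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "GrainSpec",
    "GrainTruth",
    "SyntheticScene",
    "PlacementError",
    "PRESETS",
    "generate_scene",
    "auto_px_per_mm",
    "render_occluded_pair_fixture",
    "occluded_pair_with_context",
]


@dataclass(frozen=True)
class GrainSpec:
    """Silhouette model of one crop's grain.

    Dimensions are in mm (scaled to px by the generator's ``px_per_mm``);
    ``intensity_mean``/``intensity_sd`` set the grain's gray level against
    the ~245 white-paper background.  The wedge silhouette is an ellipse
    clipped by a chord at 70% of the major axis, giving one flat end with
    two convex corners, as corn kernels present.
    """

    name: str
    shape: str  # 'ellipse' | 'wedge' | 'round'
    length_mm: float
    width_mm: float
    intensity_mean: float
    intensity_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.width_mm > self.length_mm:
            raise ValueError("width must not exceed length")
        if self.shape not in ("ellipse", "wedge", "round"):
            raise ValueError(f"unknown shape {self.shape!r}")


#: Six reference crops: length x width (mm) and silhouette class, with
#: gray levels chosen for each seed coat colour against white paper.
PRESETS: dict[str, GrainSpec] = {
    "wheat": GrainSpec("wheat", "ellipse", 7.2, 3.4, 170.0),
    "corn": GrainSpec("corn", "wedge", 11.8, 8.8, 175.0),
    "mung_bean": GrainSpec("mung_bean", "ellipse", 5.5, 3.9, 90.0),
    "soybean": GrainSpec("soybean", "ellipse", 11.1, 6.9, 160.0),
    "peanut": GrainSpec("peanut", "ellipse", 13.0, 8.0, 120.0),
    "rape": GrainSpec("rape", "round", 2.1, 2.1, 40.0),
}

#: wedge chord position as a fraction of the semi-major axis
_WEDGE_CLIP = 0.4


def auto_px_per_mm(
    n: int,
    preset: GrainSpec | str,
    canvas: tuple[int, int] = (1440, 1920),
    fill: float = 0.12,
    cap: float = 10.0,
) -> float:
    """Pixel scale emulating a photographer framing ``n`` grains.

    More grains mean the camera moves back, so the px/mm scale shrinks to
    keep the total grain area near ``fill`` of the canvas (capped at
    ``cap`` px/mm for few-grain close-ups).
    """
    spec = PRESETS[preset] if isinstance(preset, str) else preset
    H, W = canvas
    scale = math.sqrt(fill * H * W / (n * spec.length_mm * spec.width_mm))
    return float(min(cap, scale))


class PlacementError(RuntimeError):
    """Could not place the requested number of grains on the canvas."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"placed only {achieved} of {requested} grains within the retry budget"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class GrainTruth:
    """Ground-truth geometry of one rendered grain."""

    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]    # semi-major, semi-minor (px)
    orientation: float           # radians, 0 = major axis along columns
    shape: str


@dataclass
class SyntheticScene:
    image: np.ndarray                       # uint8 grayscale
    truth: list[GrainTruth]
    N1: int
    adhesion_pairs: list[tuple[int, int]]
    clusters: list[list[int]]               # grain indices per placement group
    seed: int
    background_mean: float
    truth_labels: np.ndarray                # int32, 0 = background
    gt_mask: np.ndarray                     # bool, analytic coverage >= 0.5
    px_per_mm: float = 10.0
    preset_name: str = ""

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def save(self, png_path: str, truth_path: str | None = None) -> None:
        """Write the scene as PNG plus a JSON ground-truth sidecar."""
        Image.fromarray(self.image).save(png_path)
        if truth_path is None:
            truth_path = png_path.rsplit(".", 1)[0] + ".truth.json"
        payload = {
            "N1": self.N1,
            "seed": self.seed,
            "preset": self.preset_name,
            "px_per_mm": self.px_per_mm,
            "background_mean": self.background_mean,
            "adhesion_pairs": [list(p) for p in self.adhesion_pairs],
            "clusters": [list(c) for c in self.clusters],
            "grains": [
                {
                    "center": list(g.center),
                    "axes": list(g.axes),
                    "orientation": g.orientation,
                    "shape": g.shape,
                }
                for g in self.truth
            ],
        }
        with open(truth_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# geometry helpers


def _radial_extent(a: float, b: float, shape: str, psi: float) -> float:
    """Distance from centre to silhouette boundary along local angle psi."""
    r_ell = a * b / math.hypot(b * math.cos(psi), a * math.sin(psi))
    if shape == "wedge":
        c = math.cos(psi)
        if c > 1e-9:
            r_chord = _WEDGE_CLIP * a / c
            return min(r_ell, r_chord)
    return r_ell


def _coverage(
    grain: GrainTruth, shape: tuple[int, int], supersample: int = 3
) -> tuple[tuple[int, int], np.ndarray]:
    """Anti-aliased coverage of one grain inside its bounding box.

    Returns ``((r0, c0), cov)`` where ``cov`` holds per-pixel area coverage
    in [0, 1] estimated by ``supersample^2`` subsamples.
    """
    a, b = grain.axes
    cy, cx = grain.center
    H, W = shape
    pad = a + 1.5
    r0 = max(0, int(math.floor(cy - pad)))
    r1 = min(H, int(math.ceil(cy + pad)) + 1)
    c0 = max(0, int(math.floor(cx - pad)))
    c1 = min(W, int(math.ceil(cx + pad)) + 1)
    if r1 <= r0 or c1 <= c0:
        return (0, 0), np.zeros((0, 0))
    s = supersample
    sub = (np.arange(s) + 0.5) / s - 0.5
    ys = (np.arange(r0, r1)[:, None] + sub[None, :]).ravel()
    xs = (np.arange(c0, c1)[:, None] + sub[None, :]).ravel()
    dy = ys[:, None] - cy
    dx = xs[None, :] - cx
    cos_t, sin_t = math.cos(grain.orientation), math.sin(grain.orientation)
    # local frame: x' along the major axis
    xp = dx * cos_t + dy * sin_t
    yp = -dx * sin_t + dy * cos_t
    inside = (xp / a) ** 2 + (yp / b) ** 2 <= 1.0
    if grain.shape == "wedge":
        inside &= xp <= _WEDGE_CLIP * a
    cov = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    return (r0, c0), cov


def _render(
    grains: list[GrainTruth],
    canvas: tuple[int, int],
    rng: np.random.Generator,
    spec_by_grain: list[GrainSpec],
    background_mean: float,
    background_sd: float,
    gradient_amplitude: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render grains; returns (uint8 image, truth label map, gt mask)."""
    H, W = canvas
    img = np.full((H, W), background_mean, dtype=np.float64)
    if gradient_amplitude > 0:
        theta = rng.uniform(0, 2 * math.pi)
        yy = (np.arange(H)[:, None] - H / 2) / max(H, 1)
        xx = (np.arange(W)[None, :] - W / 2) / max(W, 1)
        img += gradient_amplitude * (yy * math.sin(theta) + xx * math.cos(theta))
    if background_sd > 0:
        img += rng.normal(0.0, background_sd, size=(H, W))

    labels = np.zeros((H, W), dtype=np.int32)
    best_cov = np.zeros((H, W), dtype=np.float32)
    gt_mask = np.zeros((H, W), dtype=bool)
    for gid, (grain, spec) in enumerate(zip(grains, spec_by_grain), start=1):
        (r0, c0), cov = _coverage(grain, (H, W))
        if cov.size == 0:
            continue
        h, w = cov.shape
        val = rng.normal(spec.intensity_mean, spec.intensity_sd)
        val_map = val + rng.normal(0.0, 3.0, size=cov.shape)
        sl = (slice(r0, r0 + h), slice(c0, c0 + w))
        img[sl] = img[sl] * (1 - cov) + val_map * cov
        solid = cov >= 0.5
        gt_mask[sl] |= solid
        take = solid & (cov > best_cov[sl])
        labels[sl][take] = gid
        best_cov[sl][take] = cov[take]
    return np.clip(img, 0, 255).astype(np.uint8), labels, gt_mask


# ---------------------------------------------------------------------------
# scene generation


def _cluster_plan(n: int, adhesion_frac: float, rng: np.random.Generator) -> list[int]:
    """Group sizes: pairs/triples for the adhering fraction, then singles."""
    n_adh = int(round(adhesion_frac * n))
    sizes: list[int] = []
    rem = n_adh
    while rem >= 2:
        size = 3 if (rem >= 3 and rng.random() < 1 / 3) else 2
        sizes.append(size)
        rem -= size
    n_singles = n - sum(sizes)
    sizes.extend([1] * n_singles)
    return sizes


def _make_cluster_geometry(
    size: int,
    a: np.ndarray,
    b: np.ndarray,
    shape: str,
    depth: float,
    rng: np.random.Generator,
    max_tries: int = 50,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Local member centres and orientations for a touching pair/triple.

    Members are chained: each new member touches the previous one with a
    radial overlap of ``depth`` px along the centre line; non-adjacent
    members must not touch.
    """
    for _ in range(max_tries):
        centers = np.zeros((size, 2))
        orients = rng.uniform(0, math.pi, size=size)
        ok = True
        for k in range(1, size):
            phi = rng.uniform(0, 2 * math.pi) if k == 1 else prev_phi + rng.uniform(-1.0, 1.0)
            prev_phi = phi
            u = np.array([math.sin(phi), math.cos(phi)])  # (row, col) step
            r_prev = _radial_extent(a[k - 1], b[k - 1], shape, phi - orients[k - 1])
            r_new = _radial_extent(a[k], b[k], shape, (phi + math.pi) - orients[k])
            d = r_prev + r_new - depth
            centers[k] = centers[k - 1] + d * u
            if k == 1:
                prev_phi = phi
        # non-adjacent members must stay clear of each other
        for i in range(size):
            for j in range(i + 2, size):
                vec = centers[j] - centers[i]
                dist = float(np.hypot(*vec))
                ang = math.atan2(vec[0], vec[1])
                ri = _radial_extent(a[i], b[i], shape, ang - orients[i])
                rj = _radial_extent(a[j], b[j], shape, (ang + math.pi) - orients[j])
                if dist < ri + rj + 2.0:
                    ok = False
        if ok:
            return centers, orients
    return None


def generate_scene(
    n: int,
    preset: GrainSpec | str = "wheat",
    adhesion_frac: float = 0.0,
    overlap_depth_frac: float = 0.05,
    canvas: tuple[int, int] = (1440, 1920),
    seed: int = 0,
    px_per_mm: float = 10.0,
    background_mean: float = 245.0,
    background_sd: float = 4.0,
    gradient_amplitude: float = 8.0,
    size_jitter: float = 0.04,
    max_tries: int = 4000,
) -> SyntheticScene:
    """Generate a seeded scene of ``n`` grains with exact ground truth.

    A fraction ``adhesion_frac`` of grains is placed in touching
    pairs/triples whose members overlap radially by
    ``overlap_depth_frac * width_px`` (at least 1.5 px so contacts render
    as genuine adhesions); the rest are isolated.  Raises `PlacementError`
    when the canvas cannot accommodate ``n`` grains within the retry
    budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= adhesion_frac <= 1.0:
        raise ValueError("adhesion_frac must lie in [0, 1]")
    spec = PRESETS[preset] if isinstance(preset, str) else preset
    rng = np.random.default_rng(seed)
    H, W = canvas
    a0 = spec.length_mm * px_per_mm / 2.0
    b0 = spec.width_mm * px_per_mm / 2.0
    depth = max(1.5, overlap_depth_frac * spec.width_mm * px_per_mm)

    sizes = _cluster_plan(n, adhesion_frac, rng)
    placed_centers: list[np.ndarray] = []
    placed_radius: list[float] = []
    grains: list[GrainTruth] = []
    clusters: list[list[int]] = []
    adhesion_pairs: list[tuple[int, int]] = []

    for size in sizes:
        jit = 1.0 + size_jitter * rng.standard_normal(size)
        jit = np.clip(jit, 0.85, 1.15)
        a = a0 * jit
        b = b0 * jit
        if size == 1:
            local = np.zeros((1, 2))
            orients = rng.uniform(0, math.pi, size=1)
        else:
            geom = _make_cluster_geometry(size, a, b, spec.shape, depth, rng)
            if geom is None:
                raise PlacementError(n, len(grains))
            local, orients = geom
        group_r = float(max(np.hypot(*c) + ai for c, ai in zip(local, a))) + 2.0
        placed = False
        for _ in range(max_tries):
            anchor = np.array(
                [rng.uniform(group_r + 2, H - group_r - 2),
                 rng.uniform(group_r + 2, W - group_r - 2)]
            )
            centers = local + anchor
            ok = True
            for c, ai in zip(centers, a):
                for pc, pr in zip(placed_centers, placed_radius):
                    if np.hypot(*(c - pc)) < ai + pr + 2.0:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                placed = True
                break
        if not placed:
            raise PlacementError(n, len(grains))
        base = len(grains)
        clusters.append(list(range(base, base + size)))
        for k in range(size):
            grains.append(
                GrainTruth(
                    center=(float(centers[k][0]), float(centers[k][1])),
                    axes=(float(a[k]), float(b[k])),
                    orientation=float(orients[k]),
                    shape=spec.shape,
                )
            )
            placed_centers.append(centers[k])
            placed_radius.append(float(a[k]))
            if k >= 1:
                adhesion_pairs.append((base + k - 1, base + k))

    img, labels, gt_mask = _render(
        grains, canvas, rng, [spec] * len(grains),
        background_mean, background_sd, gradient_amplitude,
    )
    return SyntheticScene(
        image=img,
        truth=grains,
        N1=len(grains),
        adhesion_pairs=adhesion_pairs,
        clusters=clusters,
        seed=seed,
        background_mean=background_mean,
        truth_labels=labels,
        gt_mask=gt_mask,
        px_per_mm=px_per_mm,
        preset_name=spec.name,
    )


# ---------------------------------------------------------------------------
# the occluded collinear pair fixture


def _occluded_pair_truth(
    center: tuple[float, float] = (100.0, 130.0),
    a: float = 60.0,
    b: float = 24.0,
    axial_gap_frac: float = 0.7,
    lateral_frac: float = 0.3,
    tilt_deg: float = 14.0,
) -> list[GrainTruth]:
    """Two identical ellipses in the occluded near-collinear configuration.

    The second ellipse is displaced mostly along the shared major axis and
    slightly sideways, and tilted by a few degrees: on one side of the
    junction the boundaries blend smoothly (the concavity is occluded by
    the overlap), on the other a single concave notch survives.
    """
    cy, cx = center
    g1 = GrainTruth(center=(cy, cx), axes=(a, b), orientation=0.0, shape="ellipse")
    tilt = math.radians(tilt_deg)
    g2 = GrainTruth(
        center=(cy - lateral_frac * b, cx + 2 * a * axial_gap_frac),
        axes=(a, b),
        orientation=tilt,
        shape="ellipse",
    )
    return [g1, g2]


def render_occluded_pair_fixture(seed: int = 0) -> SyntheticScene:
    """Two near-collinear overlapped grains whose upper junction corner is
    occluded: one connected region, exactly one detectable corner, true
    count 2."""
    rng = np.random.default_rng(seed)
    grains = _occluded_pair_truth()
    canvas = (200, 340)
    spec = GrainSpec("fixture", "ellipse", 12.0, 4.8, 70.0, 4.0)
    img, labels, gt_mask = _render(
        grains, canvas, rng, [spec] * 2,
        background_mean=245.0, background_sd=3.0, gradient_amplitude=4.0,
    )
    return SyntheticScene(
        image=img,
        truth=grains,
        N1=2,
        adhesion_pairs=[(0, 1)],
        clusters=[[0, 1]],
        seed=seed,
        background_mean=245.0,
        truth_labels=labels,
        gt_mask=gt_mask,
        px_per_mm=10.0,
        preset_name="fixture",
    )


def occluded_pair_with_context(n_singles: int = 6, seed: int = 0) -> SyntheticScene:
    """The occluded collinear pair surrounded by isolated single grains.

    The singles establish the image-mean skeleton length and the mean
    single-grain area, so the linear-adhesion rule has the population
    context it needs; N1 = 2 + n_singles.
    """
    rng = np.random.default_rng(seed)
    a, b = 60.0, 24.0
    canvas = (760, 900)
    pair = _occluded_pair_truth(center=(380.0, 330.0), a=a, b=b)
    grains = list(pair)
    centers = [np.asarray(g.center) for g in grains]
    for _ in range(n_singles):
        for _try in range(4000):
            c = np.array([rng.uniform(a + 4, canvas[0] - a - 4),
                          rng.uniform(a + 4, canvas[1] - a - 4)])
            if all(np.hypot(*(c - pc)) >= 2 * a + 4 for pc in centers):
                break
        else:
            raise PlacementError(n_singles + 2, len(grains))
        grains.append(
            GrainTruth(center=(float(c[0]), float(c[1])), axes=(a, b),
                       orientation=float(rng.uniform(0, math.pi)), shape="ellipse")
        )
        centers.append(c)
    spec = GrainSpec("fixture", "ellipse", 12.0, 4.8, 70.0, 4.0)
    img, labels, gt_mask = _render(
        grains, canvas, rng, [spec] * len(grains),
        background_mean=245.0, background_sd=3.0, gradient_amplitude=4.0,
    )
    return SyntheticScene(
        image=img,
        truth=grains,
        N1=len(grains),
        adhesion_pairs=[(0, 1)],
        clusters=[[0, 1]] + [[i] for i in range(2, len(grains))],
        seed=seed,
        background_mean=245.0,
        truth_labels=labels,
        gt_mask=gt_mask,
        px_per_mm=10.0,
        preset_name="fixture",
    )
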