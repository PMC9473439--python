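"""Region topology, corner detection, the count formula, and orchestration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from graincount import (
    average_area_count,
    binarize,
    count_holes,
    count_image,
    detect_corners,
    is_linear_adhesion,
    label_regions,
    region_count_formula,
)
from graincount.counting import round_half_up

from conftest import disc_mask, ellipse_mask


class TestLabelRegions:
    def test_three_disjoint_squares(self, cfg):
        m = np.zeros((60, 120), bool)
        for k in range(3):
            m[20:35, 10 + 40 * k : 25 + 40 * k] = True
        regions = label_regions(m, cfg)
        assert len(regions) == 3
        assert all(r.holes == 0 for r in regions)
        assert all(r.area == 225 for r in regions)

    def test_ring_has_one_hole(self, cfg):
        m = disc_mask((80, 80), 40, 40, 25) & ~disc_mask((80, 80), 40, 40, 15)
        regions = label_regions(m, cfg)
        assert len(regions) == 1
        assert regions[0].holes == 1

    def test_scene_without_adhesion(self, wheat_scene_no_adhesion, cfg):
        m = binarize(wheat_scene_no_adhesion.image, cfg)
        assert len(label_regions(m, cfg)) == wheat_scene_no_adhesion.N1

    def test_noise_floor_drops_small_blobs(self, cfg):
        m = np.zeros((50, 50), bool)
        m[10:12, 10:12] = True  # 4 px < 9 px floor
        m[30:40, 30:40] = True
        assert len(label_regions(m, cfg)) == 1

    def test_centroid_within_bbox(self, wheat_scene_adhesion, cfg):
        m = binarize(wheat_scene_adhesion.image, cfg)
        for r in label_regions(m, cfg):
            r0, c0, h, w = r.bbox
            assert r0 <= r.centroid[0] <= r0 + h
            assert c0 <= r.centroid[1] <= c0 + w


class TestCountHoles:
    def test_solid_ellipse(self):
        assert count_holes(ellipse_mask((60, 80), 30, 40, 12, 25)) == 0

    def test_ring_of_touching_circles(self):
        m = np.zeros((120, 120), bool)
        for k in range(6):
            ang = k * np.pi / 3
            m |= disc_mask(m.shape, 60 + 38 * np.sin(ang), 60 + 38 * np.cos(ang), 20)
        assert count_holes(m) == 1

    def test_figure_eight(self):
        m = disc_mask((60, 100), 30, 30, 15) | disc_mask((60, 100), 30, 58, 15)
        m &= ~disc_mask((60, 100), 30, 30, 8)
        m &= ~disc_mask((60, 100), 30, 58, 8)
        assert count_holes(m) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((90, 90), bool)
        for _ in range(12):
            m |= disc_mask(m.shape, rng.integers(15, 75), rng.integers(15, 75),
                           rng.integers(5, 14))
        assert count_holes(m) == _flood_fill_hole_oracle(m)


def _flood_fill_hole_oracle(mask: np.ndarray) -> int:
    """BFS flood fill of the background from the border; remaining
    4-connected background components are the enclosed holes."""
    from collections import deque

    H, W = mask.shape
    seen = np.zeros((H, W), bool)
    q = deque()
    for r in range(H):
        for c in (0, W - 1):
            if not mask[r, c] and not seen[r, c]:
                seen[r, c] = True
                q.append((r, c))
    for c in range(W):
        for r in (0, H - 1):
            if not mask[r, c] and not seen[r, c]:
                seen[r, c] = True
                q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and not mask[rr, cc] and not seen[rr, cc]:
                seen[rr, cc] = True
                q.append((rr, cc))
    holes = 0
    visited = seen | mask
    for r in range(H):
        for c in range(W):
            if not visited[r, c]:
                holes += 1
                stack = [(r, c)]
                visited[r, c] = True
                while stack:
                    y, x = stack.pop()
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        yy, xx = y + dr, x + dc
                        if 0 <= yy < H and 0 <= xx < W and not visited[yy, xx]:
                            visited[yy, xx] = True
                            stack.append((yy, xx))
    return holes


class TestDetectCorners:
    def test_solid_circle_is_convex(self, cfg):
        m = disc_mask((100, 100), 50, 50, 30)
        region = label_regions(m, cfg)[0]
        assert detect_corners(region, m.shape, cfg) == []

    def test_overlapping_discs_two_neck_corners(self, cfg):
        m = disc_mask((80, 100), 40, 35, 15) | disc_mask((80, 100), 40, 59, 15)
        region = label_regions(m, cfg)[0]
        corners = detect_corners(region, m.shape, cfg)
        assert len(corners) == 2
        # both at the concave neck (column midway between the centres)
        for c in corners:
            assert abs(c.position[1] - 47) <= 3
            assert c.score > cfg.corner_fraction

    def test_straight_edge_no_corners(self, cfg):
        m = np.zeros((60, 60), bool)
        m[:, :30] = True
        region = label_regions(m, cfg)[0]
        assert detect_corners(region, m.shape, cfg) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, seed, cfg):
        rng = np.random.default_rng(seed)
        m = np.zeros((160, 180), bool)
        for _ in range(5):
            m |= disc_mask(m.shape, rng.integers(30, 130), rng.integers(30, 150),
                           rng.integers(10, 22))
        for region in label_regions(m, cfg):
            got = {c.position for c in detect_corners(region, m.shape, cfg)}
            assert got == _corner_oracle(region, m.shape, cfg)


def _corner_oracle(region, image_shape, cfg):
    """Exhaustive per-boundary-pixel fraction computation: no integral
    image, no vectorisation — direct window sums over the region mask."""
    H, W = image_shape
    full = np.zeros(image_shape, bool)
    r0, c0, h, w = region.bbox
    full[r0 : r0 + h, c0 : c0 + w] = region.mask_crop
    half = cfg.corner_window // 2
    boundary = []
    for r, c in np.argwhere(full):
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and not full[rr, cc]:
                boundary.append((int(r), int(c)))
                break
    scores = {}
    for r, c in boundary:
        t, b = max(0, r - half), min(H, r + half + 1)
        l, rt = max(0, c - half), min(W, c + half + 1)
        frac = full[t:b, l:rt].sum() / ((b - t) * (rt - l))
        if frac > cfg.corner_fraction:
            scores[(r, c)] = frac
    kept = set()
    cand = sorted(scores)  # scan order
    for i, p in enumerate(cand):
        ok = True
        for j, q in enumerate(cand):
            if p == q:
                continue
            if max(abs(p[0] - q[0]), abs(p[1] - q[1])) > cfg.corner_window:
                continue
            if scores[q] > scores[p] or (scores[q] == scores[p] and j < i):
                ok = False
                break
        if ok:
            kept.add(p)
    return kept


class TestCountFormula:
    @pytest.mark.parametrize(
        "corners,holes,expected",
        [(0, 0, 1.0), (1, 0, 1.5), (17, 0, 9.5), (12, 0, 7.0), (2, 1, 1.0)],
    )
    def test_values(self, corners, holes, expected):
        assert region_count_formula(corners, holes) == expected

    @given(c=st.integers(0, 40), h=st.integers(0, 5))
    def test_linearity(self, c, h):
        base = region_count_formula(c, h)
        assert region_count_formula(c + 2, h) == base + 1
        assert region_count_formula(c, h + 1) == base - 1

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            region_count_formula(-1, 0)
        with pytest.raises(ValueError):
            region_count_formula(0, -1)


class TestLinearAdhesion:
    def _strip_region(self, length, angle_deg=180.0):
        """A region whose skeleton is a bent strip with the given included
        angle (180 = straight)."""
        m = np.zeros((220, 220), bool)
        cy, cx = 110, 110
        half = length // 2
        turn = np.deg2rad(180.0 - angle_deg)
        for t in range(-half, half + 1):
            if t <= 0:
                r, c = cy, cx + t
            else:
                r = cy - int(round(t * np.sin(turn)))
                c = cx + int(round(t * np.cos(turn)))
            m[max(0, r - 4) : r + 5, max(0, c - 4) : c + 5] = True
        return label_regions(m)[0]

    def test_straight_double_length_fires(self, cfg):
        region = self._strip_region(160, angle_deg=180.0)
        assert is_linear_adhesion(region, mean_skeleton_length=80.0, cfg=cfg)

    def test_l_shape_rejected(self, cfg):
        region = self._strip_region(160, angle_deg=90.0)
        assert not is_linear_adhesion(region, mean_skeleton_length=80.0, cfg=cfg)

    def test_short_skeleton_rejected(self, cfg):
        region = self._strip_region(96, angle_deg=180.0)
        # 1.2x the mean: below the 1.5x length gate
        assert not is_linear_adhesion(region, mean_skeleton_length=80.0, cfg=cfg)


class TestAverageArea:
    @pytest.mark.parametrize(
        "area,mean,expected",
        [(200.0, 100.0, 2), (100.0, 100.0, 1), (240.0, 100.0, 2),
         (250.0, 100.0, 3), (40.0, 100.0, 1)],
    )
    def test_rounding_rule(self, area, mean, expected):
        assert average_area_count(area, mean) == expected

    def test_invalid_mean(self):
        with pytest.raises(ValueError):
            average_area_count(100.0, 0.0)

    @given(x=st.floats(-100, 100))
    def test_round_half_up(self, x):
        assert round_half_up(x) == int(np.floor(x + 0.5))


class TestCountImage:
    def test_scene_without_adhesion_counts_exactly(
        self, wheat_scene_no_adhesion, cfg
    ):
        m = binarize(wheat_scene_no_adhesion.image, cfg)
        result = count_image(m, cfg)
        assert result.total == wheat_scene_no_adhesion.N1
        assert all(r.method == "single" for r in result.regions)

    def test_total_is_sum_of_corrected(self, wheat_scene_adhesion, cfg):
        m = binarize(wheat_scene_adhesion.image, cfg)
        result = count_image(m, cfg)
        assert result.total == sum(r.corrected for r in result.regions)
        assert result.total >= len(result.regions)
        assert all(r.corrected >= 1 for r in result.regions)

    def test_concave_neck_pair_counts_two(self, cfg):
        # deep overlap the erosion cannot split: the two neck corners give
        # 2/2 - 0 + 1 = 2
        m = np.zeros((120, 160), bool)
        m |= disc_mask(m.shape, 60, 60, 22) | disc_mask(m.shape, 60, 92, 22)
        result = count_image(m, cfg)
        assert result.total == 2

    def test_empty_mask_warns_and_returns_zero(self, cfg):
        with pytest.warns(UserWarning, match="empty"):
            result = count_image(np.zeros((50, 50), bool), cfg)
        assert result.total == 0
        assert result.regions == []

    def test_rotation_invariance_of_total(self, cfg):
        from graincount import generate_scene

        scene = generate_scene(n=80, preset="soybean", adhesion_frac=0.25,
                               seed=7, px_per_mm=5.0, canvas=(960, 1280))
        totals = []
        for k in range(4):
            img = np.rot90(scene.image, k)
            totals.append(count_image(binarize(img, cfg), cfg).total)
        assert max(totals) - min(totals) <= 0.02 * scene.N1 + 1e-9
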