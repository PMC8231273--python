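"""Quartile binning, clump detection, alpha-hull borders, distance profiles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from lungmsi.ionmap import IonImage, TissueMask
from lungmsi.spatial import (
    BorderCurve,
    ClumpSet,
    QuartileMap,
    alpha_hull_border,
    clump_summary,
    colocalization_score,
    distance_profile,
    find_clumps,
    quartile_bin,
    zscore_section,
)

from lungmsi.ionmap import DEFAULT_TARGETS

BUD = DEFAULT_TARGETS["budesonide"]


def image_from(values, pitch=400.0):
    return IonImage(np.asarray(values, dtype=float), pitch, BUD)


def full_mask(shape):
    return TissueMask(np.ones(shape, dtype=bool))


def flood_fill_components(binary, connectivity):
    """Independent oracle: iterative flood fill over a boolean grid."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == "8-neighbor":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r in range(rows):
        for c in range(cols):
            if binary[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    rr, cc = stack.pop()
                    comp.add((cc, rr))  # (x, y) convention
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and binary[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def qmap_from_binary(binary):
    labels = np.where(binary, 4, 1).astype(np.int8)
    return QuartileMap(labels)


class TestZScore:
    def test_three_values(self):
        z = zscore_section(image_from([[1.0, 2.0, 3.0]]), full_mask((1, 3)))
        np.testing.assert_allclose(z.values, [[-1.0, 0.0, 1.0]], atol=1e-12)

    def test_output_standardized(self, rng):
        v = rng.lognormal(0, 1, (10, 12))
        z = zscore_section(image_from(v), full_mask((10, 12)))
        vals = z.values[np.isfinite(z.values)]
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-9)
        assert np.std(vals, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_section_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_section(image_from(np.full((3, 3), 2.0)), full_mask((3, 3)))

    def test_off_tissue_stays_missing(self):
        mask = TissueMask(np.array([[True, True, True, False]]))
        z = zscore_section(image_from([[1.0, 2.0, 3.0, 99.0]]), mask)
        assert np.isnan(z.values[0, 3])


class TestQuartileBin:
    def test_eight_ranked_values(self):
        q = quartile_bin(image_from([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]]), full_mask((1, 8)))
        np.testing.assert_array_equal(q.labels, [[1, 1, 2, 2, 3, 3, 4, 4]])

    def test_five_values_class_sizes(self):
        # enumerating the rank rule label = ceil(4 r / n) for n = 5 gives
        # labels 1,2,3,4,4 -> class sizes (1, 1, 1, 2)
        q = quartile_bin(image_from([[10.0, 20.0, 30.0, 40.0, 50.0]]), full_mask((1, 5)))
        np.testing.assert_array_equal(q.labels, [[1, 2, 3, 4, 4]])

    def test_all_tied_follow_row_major_order(self):
        q = quartile_bin(image_from(np.ones((2, 4))), full_mask((2, 4)))
        np.testing.assert_array_equal(q.labels, [[1, 1, 2, 2], [3, 3, 4, 4]])

    def test_partition_sizes_differ_by_at_most_one(self, rng):
        for n_cols in (4, 5, 6, 7, 11, 29):
            v = rng.normal(size=(3, n_cols))
            q = quartile_bin(image_from(v), full_mask((3, n_cols)))
            sizes = [(q.labels == k).sum() for k in (1, 2, 3, 4)]
            assert sum(sizes) == 3 * n_cols
            assert max(sizes) - min(sizes) <= 1

    def test_rank_invariance_under_monotone_transform(self, rng):
        v = rng.lognormal(0, 1, (6, 9))
        img = image_from(v)
        mask = full_mask((6, 9))
        q_raw = quartile_bin(img, mask)
        q_z = quartile_bin(zscore_section(img, mask), mask)
        q_log = quartile_bin(image_from(np.log(v)), mask)
        np.testing.assert_array_equal(q_raw.labels, q_z.labels)
        np.testing.assert_array_equal(q_raw.labels, q_log.labels)

    def test_too_few_pixels(self):
        with pytest.raises(ValueError, match=">= 4"):
            quartile_bin(image_from([[1.0, 2.0, 3.0]]), full_mask((1, 3)))


class TestFindClumps:
    def test_two_clumps_with_singleton(self):
        binary = np.zeros((6, 6), dtype=bool)
        binary[0, 0] = binary[0, 1] = binary[5, 5] = True
        cs = find_clumps(qmap_from_binary(binary))
        assert sorted(cs.sizes) == [1, 2]

    def test_diagonal_adjacency_depends_on_connectivity(self):
        binary = np.zeros((3, 3), dtype=bool)
        binary[0, 0] = binary[1, 1] = True
        assert len(find_clumps(qmap_from_binary(binary), "8-neighbor").clumps) == 1
        assert len(find_clumps(qmap_from_binary(binary), "4-neighbor").clumps) == 2

    def test_empty_quartile_gives_empty_set(self):
        cs = find_clumps(qmap_from_binary(np.zeros((3, 3), dtype=bool)))
        assert cs.clumps == [] and clump_summary(cs) == (0, None)

    @pytest.mark.parametrize("connectivity", ["4-neighbor", "8-neighbor"])
    def test_matches_flood_fill_oracle_on_random_grids(self, connectivity, rng):
        for _ in range(60):
            binary = rng.uniform(size=(12, 12)) < rng.uniform(0.2, 0.8)
            got = find_clumps(qmap_from_binary(binary), connectivity)
            expected = flood_fill_components(binary, connectivity)
            assert sorted(map(frozenset, got.clumps)) == sorted(map(frozenset, expected))

    def test_clump_sizes_sum_to_label4_count(self, rng):
        binary = rng.uniform(size=(20, 20)) < 0.4
        cs = find_clumps(qmap_from_binary(binary))
        assert sum(cs.sizes) == int(binary.sum())


class TestClumpSummary:
    @pytest.mark.parametrize(
        "sizes, expected",
        [([2, 1], (2, 1.5)), ([5], (1, 5.0)), ([3, 1, 7, 2], (4, 2.5))],
    )
    def test_count_and_median(self, sizes, expected):
        clumps = ClumpSet([{(i, j) for j in range(s)} for i, s in enumerate(sizes)])
        assert clump_summary(clumps) == expected


class TestAlphaHull:
    def test_large_alpha_equals_convex_hull(self, rng):
        mask = np.zeros((15, 25), dtype=bool)
        mask[rng.uniform(size=(15, 25)) < 0.3] = True
        mask[3, 4] = mask[11, 20] = mask[2, 18] = True  # guarantee area
        border = alpha_hull_border(TissueMask(mask), alpha_mm=1e6, pixel_pitch_um=400.0)
        ys, xs = np.nonzero(mask)
        pts = np.column_stack([xs, ys]) * 0.4
        hull = ConvexHull(pts)
        hull_vertices = {tuple(np.round(pts[v], 9)) for v in hull.vertices}
        ring_vertices = {tuple(np.round(v, 9)) for v in border.rings[0][:-1]}
        assert ring_vertices == hull_vertices

    def test_filled_rectangle_ring_is_outer_pixel_centers(self):
        mask = np.zeros((8, 10), dtype=bool)
        mask[2:6, 3:8] = True  # 4 x 5 block
        border = alpha_hull_border(TissueMask(mask), alpha_mm=1.2, pixel_pitch_um=400.0)
        assert len(border.rings) == 1
        ring = {tuple(np.round(v, 9)) for v in border.rings[0][:-1]}
        corners = {(3 * 0.4, 2 * 0.4), (7 * 0.4, 2 * 0.4), (7 * 0.4, 5 * 0.4), (3 * 0.4, 5 * 0.4)}
        assert ring == {tuple(np.round(c, 9)) for c in corners}

    def test_small_alpha_follows_concavity(self):
        # C-shape: the alpha hull should enter the notch, so its boundary is
        # longer than the convex hull's even though its area is smaller
        mask = np.zeros((11, 11), dtype=bool)
        mask[1:10, 1:4] = True
        mask[1:4, 1:10] = True
        mask[7:10, 1:10] = True
        tm = TissueMask(mask)
        concave = alpha_hull_border(tm, alpha_mm=0.8, pixel_pitch_um=400.0)  # 2 x pitch
        convex = alpha_hull_border(tm, alpha_mm=1e6, pixel_pitch_um=400.0)
        assert concave.total_length_mm() > convex.total_length_mm()

    def test_collinear_pixels_are_error(self):
        mask = np.zeros((1, 6), dtype=bool)
        mask[0, :] = True
        with pytest.raises(ValueError, match="collinear"):
            alpha_hull_border(TissueMask(mask), alpha_mm=10.0)

    def test_too_few_pixels(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        with pytest.raises(ValueError, match="at least 3"):
            alpha_hull_border(TissueMask(mask), alpha_mm=10.0)


class TestDistanceProfile:
    def square_border(self, n=25, pitch_um=400.0):
        mask = np.ones((n, n), dtype=bool)  # 25 px * 0.4 mm = 10 mm square
        return alpha_hull_border(TissueMask(mask), alpha_mm=1.2, pixel_pitch_um=pitch_um)

    def test_center_of_10mm_square_is_5mm_from_border(self):
        border = self.square_border()
        prof = distance_profile(np.array([[12, 12]]), border, 400.0)
        assert prof.per_pixel_mm[0] == pytest.approx(5.0, abs=0.2)  # +- pitch/2

    def test_pixel_on_ring_has_near_zero_distance(self):
        border = self.square_border()
        prof = distance_profile(np.array([[0, 0]]), border, 400.0)
        assert prof.per_pixel_mm[0] <= 0.4

    def test_half_open_binning(self):
        # 70 px * 0.4 mm = 28 mm square; pixels on the horizontal midline are
        # x*0.4 mm from the left edge (the nearest border) up to the center
        border = self.square_border(n=70)
        pixels = np.array([[1, 35], [9, 35], [16, 35], [25, 35]])
        prof = distance_profile(pixels, border, 400.0)  # 0.4, 3.6, 6.4, 10.0 mm
        np.testing.assert_array_equal(prof.bin_counts, [1, 1, 1, 1])
        assert prof.bin_fractions.sum() == pytest.approx(1.0)

    def test_empty_pixel_set(self):
        border = self.square_border()
        prof = distance_profile(np.empty((0, 2)), border, 400.0)
        assert prof.bin_counts.sum() == 0 and prof.per_pixel_mm.size == 0

    def test_translation_invariance(self):
        # same geometry shifted by 7 pixels: identical distances
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:20, 5:25] = True
        shifted = np.zeros((40, 40), dtype=bool)
        shifted[12:27, 12:32] = True
        b1 = alpha_hull_border(TissueMask(mask), 1.2, 400.0)
        b2 = alpha_hull_border(TissueMask(shifted), 1.2, 400.0)
        px = np.array([[10, 10], [15, 12], [24, 19]])
        p1 = distance_profile(px, b1, 400.0)
        p2 = distance_profile(px + 7, b2, 400.0)
        np.testing.assert_allclose(p1.per_pixel_mm, p2.per_pixel_mm, atol=1e-9)


class TestColocalization:
    def test_identical_images_score_one(self, rng):
        v = rng.lognormal(0, 1, (5, 5))
        a = image_from(v)
        assert colocalization_score(a, image_from(v.copy()), full_mask((5, 5))) == pytest.approx(1.0)

    def test_reversed_ranks_score_minus_one(self, rng):
        v = rng.uniform(1, 2, (4, 4))
        b = image_from(v.max() + v.min() - v)
        assert colocalization_score(image_from(v), b, full_mask((4, 4))) == pytest.approx(-1.0)

    def test_constant_channel_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            colocalization_score(
                image_from(np.ones((3, 3))), image_from(np.eye(3)), full_mask((3, 3))
            )
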