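import numpy as np
import pytest

import mmhisto as m
from mmhisto import features as F
from mmhisto.segmentation import LumenObject, NucleusObject, SegmentationResult

from conftest import disc_mask


def rotate90(mask):
    return np.rot90(mask).copy()


def lumen(mask):
    return F.lumen_from_mask(mask)


class TestRegistry:
    def test_default_counts(self):
        reg = F.default_registry()
        assert reg.counts() == {"total": 67, "global": 29, "local": 38, "categories": 17}

    def test_json_roundtrip(self, tmp_path):
        reg = F.default_registry()
        path = str(tmp_path / "registry.json")
        reg.to_json(path)
        loaded = F.FeatureRegistry.from_json(path)
        assert loaded.feature_ids == reg.feature_ids
        assert loaded.counts() == reg.counts()

    def test_invalid_entries_rejected(self):
        e = F.FeatureEntry("x", 1, "global", "AVG")
        with pytest.raises(ValueError, match="duplicate"):
            F.FeatureRegistry(entries=[e, e])
        with pytest.raises(ValueError, match="category"):
            F.FeatureRegistry(entries=[F.FeatureEntry("y", 99, "global", "AVG")])


class TestShapeDescriptors:
    @pytest.mark.parametrize("radius", [15, 30, 60])
    def test_disc_closed_forms(self, radius):
        l = lumen(disc_mask(radius))
        assert F.lumen_distortion(l) <= 0.05
        assert abs(F.lumen_convex_ratio(l) - 1) <= 0.03
        assert F.lumen_mbc_ratio(l) <= 1.1
        assert abs(F.lumen_roundness(l) * radius / (4 * np.pi) - 1) <= 0.10
        b, a = F.lumen_symmetry_indices(l)
        assert b <= 0.1 and a <= 0.05

    def test_square_mbc_ratio_is_half_pi(self):
        sq = np.zeros((60, 60), dtype=bool)
        sq[10:50, 10:50] = True
        assert F.lumen_mbc_ratio(lumen(sq)) == pytest.approx(np.pi / 2, rel=0.05)
        assert F.lumen_convex_ratio(lumen(sq)) == pytest.approx(1.0, rel=0.03)

    def test_square_rounder_than_disc_by_roundness(self):
        # equal-area square vs disc: the square has the longer perimeter,
        # hence the strictly larger roundness value
        sq = np.zeros((60, 60), dtype=bool)
        sq[12:48, 12:48] = True  # 36x36 = 1296 px
        d = disc_mask(20)        # ~1257 px
        r_sq = F.lumen_roundness(lumen(sq))
        r_disc = F.lumen_roundness(lumen(d))
        assert r_sq > r_disc

    def test_thin_bar_mbc_grows_linearly(self):
        for n in (40, 60):
            bar = np.zeros((9, n + 20), dtype=bool)
            bar[4, 10 : 10 + n] = True
            assert F.lumen_mbc_ratio(lumen(bar)) == pytest.approx(np.pi * n / 4, rel=0.1)

    def test_ellipse_distortion_matches_polar_radius_cv(self):
        n = 121
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        ell = ((rr - 60) / 40.0) ** 2 + ((cc - 60) / 20.0) ** 2 <= 1
        got = F.lumen_distortion(lumen(ell))
        # oracle: CV of the polar radius of the continuous 2:1 ellipse,
        # sampled uniformly in arc length along the boundary
        t = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
        x, y = 40 * np.cos(t), 20 * np.sin(t)
        seg = np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0]))
        w = seg / seg.sum()
        r = np.hypot(x, y)
        mean = (w * r).sum()
        cv = np.sqrt((w * (r - mean) ** 2).sum()) / mean
        assert got == pytest.approx(cv, abs=0.03)

    def test_concave_shape_convex_ratio_matches_hull_arithmetic(self):
        plus = np.zeros((30, 30), dtype=bool)
        plus[5:25, 13:17] = True
        plus[13:17, 5:25] = True
        got = F.lumen_convex_ratio(lumen(plus))
        # independent oracle: shoelace area of the hull octagon through the
        # extreme pixel centers, over the pixel count
        verts = np.array(
            [(5, 13), (5, 16), (13, 24), (16, 24), (24, 16), (24, 13), (16, 5), (13, 5)],
            dtype=float,
        )
        x, y = verts[:, 0], verts[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert got == pytest.approx(shoelace / plus.sum(), rel=1e-6)
        assert got > 1.0

    def test_mirror_image_has_identical_symmetry_indices(self):
        shape = np.zeros((40, 40), dtype=bool)
        shape[10:30, 15:20] = True
        shape[25:30, 20:28] = True  # mirror-asymmetric L
        l1 = lumen(shape)
        l2 = lumen(shape[:, ::-1].copy())
        assert F.lumen_symmetry_indices(l1) == pytest.approx(
            F.lumen_symmetry_indices(l2), abs=1e-9
        )
        b, a = F.lumen_symmetry_indices(l1)
        assert a > 0.1 or b > 0.1

    @pytest.mark.parametrize("shift", [(0, 0), (7, 3)])
    def test_translation_and_quarter_turn_invariance(self, shift):
        base = np.zeros((80, 80), dtype=bool)
        base[20:40, 25:45] = True
        base[35:50, 30:38] = True
        moved = np.roll(np.roll(base, shift[0], axis=0), shift[1], axis=1)
        rotated = rotate90(base)
        for fn in (F.lumen_distortion, F.lumen_mbc_ratio, F.lumen_convex_ratio, F.lumen_roundness):
            ref = fn(lumen(base))
            assert fn(lumen(moved)) == pytest.approx(ref, rel=1e-6)
            assert fn(lumen(rotated)) == pytest.approx(ref, rel=0.02)

    def test_bounding_circle_dominates_convex_hull(self, registered_benign):
        _, _, _, seg = registered_benign
        for l in seg.lumens:
            mbc = F.lumen_mbc_ratio(l)
            cvx = F.lumen_convex_ratio(l)
            assert cvx >= 1.0
            assert mbc >= cvx


class TestCytoplasmAssociation:
    def _setup(self, ring_color_top, ring_color_bottom):
        shape = (60, 60)
        lum = disc_mask(8, size=60)
        px = np.zeros(shape + (3,), dtype=np.uint8)
        px[:30] = ring_color_top
        px[30:] = ring_color_bottom
        px[lum] = (255, 255, 255)
        from scipy import ndimage as ndi
        from skimage import morphology

        epi = ndi.binary_dilation(lum, morphology.disk(5)) & ~lum
        return F.lumen_from_mask(lum), m.RgbImage(px), m.BinaryMask(epi)

    def test_all_pink_ring_scores_one(self):
        l, he, epi = self._setup((226, 152, 196), (226, 152, 196))
        assert F.lumen_cytoplasm_association(l, he, epi) == 1.0

    def test_all_blue_ring_scores_zero(self):
        l, he, epi = self._setup((72, 64, 150), (72, 64, 150))
        assert F.lumen_cytoplasm_association(l, he, epi) == 0.0

    def test_half_ring_scores_half(self):
        l, he, epi = self._setup((226, 152, 196), (72, 64, 150))
        assert F.lumen_cytoplasm_association(l, he, epi) == pytest.approx(0.5, abs=0.05)


class TestSpatialEntropy:
    def test_uniform_grid_maximal(self):
        tissue = np.ones((80, 80), dtype=bool)
        # one nucleus per cell of the 8x8 analysis grid
        pts = np.array([[5 + 10 * i, 5 + 10 * j] for i in range(8) for j in range(8)], dtype=float)
        assert F.spatial_entropy(pts, tissue, grid=8) == pytest.approx(1.0, abs=1e-9)

    def test_single_cluster_is_zero(self):
        tissue = np.ones((80, 80), dtype=bool)
        pts = np.full((30, 2), 5.0)
        assert F.spatial_entropy(pts, tissue, grid=8) == 0.0

    def test_no_points_is_zero(self):
        assert F.spatial_entropy(np.empty((0, 2)), np.ones((10, 10), bool), grid=4) == 0.0


def build_segmentation(shape, nuclei_specs, lumen_masks, epi_mask=None, tissue=None):
    nuclei = [
        NucleusObject(pixels=px, area_px=len(px),
                      centroid=tuple(px.mean(axis=0)), mean_intensity=0.0)
        for px in nuclei_specs
    ]
    lumens = [F.lumen_from_mask(lm) for lm in lumen_masks]
    tissue = np.ones(shape, dtype=bool) if tissue is None else tissue
    epi = np.ones(shape, dtype=bool) if epi_mask is None else epi_mask
    return SegmentationResult(
        lumens=lumens,
        nuclei=nuclei,
        epithelium_mask=m.BinaryMask(epi),
        tissue_mask=m.BinaryMask(tissue),
        tissue_circle=((shape[0] / 2, shape[1] / 2), shape[0] / 2),
    )


def block(r0, c0, n):
    """n pixels in a compact block starting at (r0, c0)."""
    out = []
    w = int(np.ceil(np.sqrt(n)))
    for k in range(n):
        out.append((r0 + k // w, c0 + k % w))
    return np.array(out)


class TestExtraction:
    def test_global_avg_and_tot_of_nucleus_sizes(self):
        shape = (200, 200)
        seg = build_segmentation(
            shape,
            [block(20, 20, 10), block(80, 80, 20), block(150, 150, 30)],
            [],
        )
        he = m.RgbImage(np.zeros(shape + (3,), dtype=np.uint8))
        vec = m.extract_features(seg, he)
        s = vec.to_series()
        assert s["G_AVG_nucleus_area"] == pytest.approx(20.0)
        assert s["G_TOT_nucleus_area"] == pytest.approx(60.0)
        assert s["G_TOT_nucleus_count"] == 3
        assert vec.missing_policy_applied  # no lumens in this fixture

    def test_nearest_lumen_distance_matches_brute_force(self):
        shape = (120, 120)
        lum = disc_mask(10, size=120)
        nucleus = block(20, 30, 16)
        seg = build_segmentation(shape, [nucleus], [lum])
        q = F.epithelium_quantities(seg)
        centroid = nucleus.mean(axis=0)
        boundary = F._boundary_pixels(np.argwhere(lum))
        expected = np.min(np.linalg.norm(boundary - centroid, axis=1))
        assert q["nucleus_lumen_dist"][0] == pytest.approx(expected, abs=1.0)

    def test_isolated_and_far_counts(self):
        shape = (300, 300)
        # two nuclei 10 px apart (not isolated), one 200 px away (isolated)
        seg = build_segmentation(
            shape,
            [block(100, 100, 9), block(100, 110, 9), block(280, 280, 9)],
            [disc_mask(10, size=300)],  # lumen near the image center
        )
        cfg = F.FeatureConfig(isolation_dist=30.0, far_dist=80.0)
        q = F.epithelium_quantities(seg, cfg)
        assert int(q["isolated_flags"].sum()) == 1
        assert int(q["far_flags"].sum()) == 1  # only the far corner nucleus

    def test_homogeneous_windows_have_zero_local_std(self):
        shape = (200, 200)
        # identical 4-nucleus patterns in each 100x100 quadrant
        nuclei = []
        for r0 in (0, 100):
            for c0 in (0, 100):
                for dr, dc in [(20, 20), (20, 70), (70, 20), (70, 70)]:
                    nuclei.append(block(r0 + dr, c0 + dc, 9))
        seg = build_segmentation(shape, nuclei, [])
        he = m.RgbImage(np.zeros(shape + (3,), dtype=np.uint8))
        cfg = F.FeatureConfig(window=100, stride=100)
        vec = m.extract_features(seg, he, cfg=cfg)
        s = vec.to_series()
        assert s["L_STD_TOT_nucleus_count"] == 0.0
        assert s["L_MAX_TOT_nucleus_count"] == 4.0
        assert s["L_MIN_TOT_nucleus_count"] == 4.0

    def test_partitioned_windows_conserve_the_global_count(self):
        shape = (200, 200)
        rng = np.random.default_rng(4)
        nuclei = [block(int(r), int(c), 9)
                  for r, c in zip(rng.uniform(5, 190, 23), rng.uniform(5, 190, 23))]
        seg = build_segmentation(shape, nuclei, [])
        cfg = F.FeatureConfig(window=100, stride=100, min_cover=0.0)
        epi_q = F.epithelium_quantities(seg, cfg)
        lum_q = F.lumen_quantities(seg, m.RgbImage(np.zeros(shape + (3,), np.uint8)), cfg)
        windows = F._window_positions(seg.tissue_mask.mask, 100, 100, 0.0)
        counts = [
            F._window_value(3, "TOT", (rs, cs, 100), epi_q, lum_q, seg, cfg)
            for rs, cs in windows
        ]
        assert sum(counts) == 23

    def test_feature_vector_has_no_nans_even_with_empty_sample(self):
        shape = (150, 150)
        seg = build_segmentation(shape, [], [])
        he = m.RgbImage(np.zeros(shape + (3,), dtype=np.uint8))
        vec = m.extract_features(seg, he)
        assert not np.isnan(vec.values).any()
        assert vec.missing_policy_applied

    def test_feature_table_layout(self, registered_benign):
        pair, _, _, seg = registered_benign
        vec = m.extract_features(seg, pair.he, sample_id="s1")
        df = m.feature_table([vec], labels=[0])
        assert df.shape == (1, 68)  # 67 features + label
        assert list(df.columns[:-1]) == F.default_registry().feature_ids
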