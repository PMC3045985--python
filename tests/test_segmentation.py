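import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import morphology

import mmhisto as m
from mmhisto import segmentation as S

from conftest import disc_mask, match_objects

PINK_STROMA = (238, 178, 208)
PINK_CYTO = (226, 152, 196)
BLUE_NUC = (72, 64, 150)


def he_canvas(shape, color=PINK_STROMA):
    px = np.zeros(shape + (3,), dtype=np.uint8)
    px[:] = color
    return px


def paint(px, mask, color):
    px[mask] = color
    return px


def offset_disc(shape, center, radius):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestCompleteLumens:
    def test_white_disc_ringed_by_epithelium(self):
        shape = (120, 120)
        lum = offset_disc(shape, (60, 60), 12)
        ring = ndi.binary_dilation(lum, morphology.disk(6)) & ~lum
        px = paint(he_canvas(shape), lum, (255, 255, 255))
        lumens = S.detect_complete_lumens(m.RgbImage(px), m.BinaryMask(ring))
        assert len(lumens) == 1 and lumens[0].complete
        assert lumens[0].area_px == int(lum.sum())

    def test_disc_ringed_by_stroma_only_is_rejected(self):
        shape = (120, 120)
        lum = offset_disc(shape, (60, 60), 12)
        px = paint(he_canvas(shape), lum, (255, 255, 255))
        no_epi = m.BinaryMask(np.zeros(shape, dtype=bool))
        assert S.detect_complete_lumens(m.RgbImage(px), no_epi) == []

    def test_subminimal_disc_filtered_by_area(self):
        shape = (120, 120)
        big = offset_disc(shape, (40, 60), 8)
        tiny = np.zeros(shape, dtype=bool)
        tiny[90:92, 60:62] = True  # 4 px, below the minimum lumen area
        px = paint(paint(he_canvas(shape), big, (255, 255, 255)), tiny, (255, 255, 255))
        epi = ndi.binary_dilation(big | tiny, morphology.disk(6)) & ~(big | tiny)
        lumens = S.detect_complete_lumens(m.RgbImage(px), m.BinaryMask(epi))
        assert len(lumens) == 1
        assert lumens[0].area_px == int(big.sum())


class TestIncompleteLumens:
    shape = (130, 130)

    def _tissue_disc(self, radius=45):
        return offset_disc(self.shape, (65, 65), radius)

    def test_edge_notch_with_epithelial_lining(self):
        tissue = self._tissue_disc()
        notch = offset_disc(self.shape, (20, 65), 11)  # centered on the boundary
        tissue_cut = tissue & ~notch
        ring = ndi.binary_dilation(notch, morphology.disk(6)) & tissue_cut
        px = he_canvas(self.shape, (255, 255, 255))
        paint(px, tissue_cut, PINK_STROMA)
        lumens = S.detect_incomplete_lumens(
            m.RgbImage(px), m.BinaryMask(tissue_cut), m.BinaryMask(ring)
        )
        assert len(lumens) == 1 and not lumens[0].complete

    def test_thin_crescent_rejected_even_with_epithelium(self):
        # flatten one side of the disc: the sliver between the chord and the
        # fitted circle is a fitting artifact, not a lumen
        tissue = self._tissue_disc()
        rr = np.arange(self.shape[0])[:, None]
        tissue_cut = tissue & (rr >= 24)  # shallow chord cut: gap to circle is thin
        band = tissue_cut & (rr < 30)     # epithelium along the chord
        px = he_canvas(self.shape, (255, 255, 255))
        paint(px, tissue_cut, PINK_STROMA)
        lumens = S.detect_incomplete_lumens(
            m.RgbImage(px), m.BinaryMask(tissue_cut), m.BinaryMask(band)
        )
        assert lumens == []

    def test_interior_and_edge_lumen_are_split_between_detectors(self):
        tissue = self._tissue_disc()
        interior = offset_disc(self.shape, (80, 65), 9)
        notch = offset_disc(self.shape, (20, 65), 11)
        tissue_cut = tissue & ~notch & ~interior
        epi = (
            ndi.binary_dilation(interior | notch, morphology.disk(6))
            & tissue_cut
        )
        px = he_canvas(self.shape, (255, 255, 255))
        paint(px, tissue_cut, PINK_STROMA)
        he = m.RgbImage(px)
        complete = S.detect_complete_lumens(he, m.BinaryMask(epi))
        incomplete = S.detect_incomplete_lumens(
            he, m.BinaryMask(tissue_cut), m.BinaryMask(epi)
        )
        assert len(complete) == 1 and complete[0].complete
        assert len(incomplete) == 1 and not incomplete[0].complete

    def test_degenerate_tissue_rejected(self):
        px = he_canvas((20, 20), (255, 255, 255))
        tiny = np.zeros((20, 20), dtype=bool)
        tiny[10, 10] = True
        with pytest.raises(ValueError, match="tissue"):
            S.detect_incomplete_lumens(
                m.RgbImage(px), m.BinaryMask(tiny), m.BinaryMask(tiny)
            )


def ellipse(shape, center, a, b, angle=0.0):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dy, dx = rr - center[0], cc - center[1]
    u = dy * np.cos(angle) + dx * np.sin(angle)
    v = -dy * np.sin(angle) + dx * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestNuclei:
    shape = (120, 120)

    def _epi(self):
        epi = np.zeros(self.shape, dtype=bool)
        epi[25:95, 25:95] = True
        return m.BinaryMask(epi)

    def test_single_ellipse_detected_at_its_center(self):
        nuc = ellipse(self.shape, (60, 60), 6, 4)
        px = paint(he_canvas(self.shape, PINK_CYTO), nuc, BLUE_NUC)
        found = S.detect_nuclei(m.RgbImage(px), self._epi())
        assert len(found) == 1
        assert np.hypot(found[0].centroid[0] - 60, found[0].centroid[1] - 60) <= 1.0

    def test_touching_ellipses_split_by_watershed(self):
        a = ellipse(self.shape, (60, 52), 6, 5)
        b = ellipse(self.shape, (60, 66), 6, 5)
        px = paint(he_canvas(self.shape, PINK_CYTO), a | b, BLUE_NUC)
        found = S.detect_nuclei(m.RgbImage(px), self._epi())
        assert len(found) == 2
        centers = sorted(f.centroid[1] for f in found)
        assert abs(centers[0] - 52) <= 3 and abs(centers[1] - 66) <= 3

    def test_blob_outside_epithelium_ignored(self):
        nuc = ellipse(self.shape, (12, 12), 6, 4)  # far from the epithelium box
        px = paint(he_canvas(self.shape, PINK_CYTO), nuc, BLUE_NUC)
        found = S.detect_nuclei(m.RgbImage(px), self._epi())
        assert found == []

    def test_areas_respect_configured_bounds(self, registered_benign):
        _, _, _, seg = registered_benign
        cfg = S.SegmentationConfig()
        for n in seg.nuclei:
            assert cfg.min_nuc_area <= n.area_px <= cfg.max_nuc_area
        for l in seg.lumens:
            assert cfg.min_lumen_area <= l.area_px <= cfg.max_lumen_area

    def test_no_nucleus_pixel_outside_dilated_epithelium(self, registered_benign):
        _, _, _, seg = registered_benign
        cfg = S.SegmentationConfig()
        allowed = ndi.binary_dilation(
            seg.epithelium_mask.mask, morphology.disk(cfg.epi_dilate_r)
        )
        for n in seg.nuclei:
            assert allowed[n.pixels[:, 0], n.pixels[:, 1]].all()


class TestEpitheliumMapping:
    def test_all_epithelium_identity_transform(self):
        ir = m.LabelImage(np.ones((10, 10), dtype=int))
        he = m.RgbImage(np.zeros((10, 10, 3), dtype=np.uint8))
        pair = m.SamplePair(he=he, ir=ir)
        reg = m.RegistrationResult(params=m.AffineParams(), objective=0.0, n_evaluations=0)
        out = S.epithelium_mask_from_ir(pair, reg)
        assert out.sum() == 100

    def test_all_stroma_gives_empty_mask(self):
        ir = m.LabelImage(np.full((10, 10), 2, dtype=int))
        he = m.RgbImage(np.zeros((10, 10, 3), dtype=np.uint8))
        pair = m.SamplePair(he=he, ir=ir)
        reg = m.RegistrationResult(params=m.AffineParams(), objective=0.0, n_evaluations=0)
        assert S.epithelium_mask_from_ir(pair, reg).sum() == 0

    def test_single_ir_pixel_maps_to_scaled_block(self):
        # one epithelial IR pixel at a pure 6x scale becomes a ~6x6 block
        # whose position follows the forward map (centroid-anchored)
        labels = np.full((9, 9), 2, dtype=int)
        labels[4, 4] = 1
        ir = m.LabelImage(labels)
        he = m.RgbImage(np.zeros((54, 54, 3), dtype=np.uint8))
        pair = m.SamplePair(he=he, ir=ir)
        tissue_c = np.argwhere(labels != 0).mean(axis=0)  # (4, 4)
        params = m.AffineParams(tx=23.0, ty=23.0, theta=0.0, s=6.0)
        reg = m.RegistrationResult(params=params, objective=0.0, n_evaluations=0)
        out = S.epithelium_mask_from_ir(pair, reg)
        assert 25 <= out.sum() <= 49  # a 6x-scaled pixel (boundary rounding aside)
        rows, cols = np.nonzero(out.mask)
        # forward map of the pixel center: c + t + s*(p - c) = (27, 27)
        assert abs(rows.mean() - 27) <= 1.5 and abs(cols.mean() - 27) <= 1.5


class TestRecoveryOnRenderedSample:
    def test_benign_sample_objects_recovered(self, registered_benign):
        pair, truth, _, seg = registered_benign
        nuc_recall, nuc_prec = match_objects(seg.nuclei, truth.nucleus_objects, pair.he.shape)
        lum_recall, _ = match_objects(seg.lumens, truth.lumen_objects, pair.he.shape)
        assert nuc_recall >= 0.9 and nuc_prec >= 0.9
        assert lum_recall == 1.0

    def test_serialization_helpers(self, registered_benign):
        pair, _, _, seg = registered_benign
        lab = S.objects_to_label_image(seg.lumens, pair.he.shape)
        assert lab.max() == len(seg.lumens)
        table = S.objects_to_table(seg.nuclei)
        assert len(table) == len(seg.nuclei)
        assert all({"id", "centroid", "area_px"} <= set(row) for row in table)
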