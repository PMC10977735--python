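"""Five-stage segmentation: band-pass, nuclei, cells, clusters."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import draw

from mitomorph.imgio import LabelMask
from mitomorph.segmentation import (
    SegmentationParams,
    bandpass,
    segment_cells,
    segment_field,
    segment_mito_clusters,
    segment_nuclei,
)


def _disk_image(shape, center, radius, fg, bg):
    img = np.full(shape, float(bg))
    rr, cc = draw.disk(center, radius, shape=shape)
    img[rr, cc] = fg
    return img


class TestBandpass:
    def test_constant_image_maps_to_zero(self):
        out = bandpass(np.full((64, 64), 37.0), 2.0, 8.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_impulse_matches_gaussian_difference(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = bandpass(img, 1.5, 6.0)
        expected = ndi.gaussian_filter(img, 1.5, mode="reflect") - ndi.gaussian_filter(
            img, 6.0, mode="reflect"
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_sigma_order_enforced(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((8, 8)), 4.0, 2.0)


class TestNuclei:
    params = SegmentationParams()

    def test_single_large_nucleus_detected(self):
        img = _disk_image((300, 300), (150, 150), 40, 3000, 20)  # ~5000 px
        mask = segment_nuclei(img, self.params)
        assert mask.n_objects == 1
        assert mask.is_compact()
        # dilation by 3 px grows the disk slightly
        assert mask.labels.sum() >= 5000

    def test_small_object_removed(self):
        img = _disk_image((300, 300), (150, 150), 20, 3000, 20)  # ~1250 px < 2000
        mask = segment_nuclei(img, self.params)
        assert mask.n_objects == 0

    def test_border_touching_nucleus_removed(self):
        img = _disk_image((300, 300), (10, 150), 40, 3000, 20)
        mask = segment_nuclei(img, self.params)
        assert mask.n_objects == 0

    def test_touching_pair_split(self):
        img = np.full((400, 400), 20.0)
        for c in ((200, 150), (200, 255)):
            rr, cc = draw.disk(c, 55, shape=img.shape)
            img[rr, cc] = 3000
        mask = segment_nuclei(img, self.params)
        assert mask.n_objects == 2

    def test_empty_image_yields_empty_mask(self):
        mask = segment_nuclei(np.full((128, 128), 10.0), self.params)
        assert mask.n_objects == 0


class TestCells:
    def test_single_cell_around_nucleus(self):
        shape = (300, 300)
        cell_img = _disk_image(shape, (150, 150), 120, 1500, 40)
        nuc = np.zeros(shape, dtype=np.int32)
        rr, cc = draw.disk((150, 150), 40, shape=shape)
        nuc[rr, cc] = 1
        cells = segment_cells(cell_img, LabelMask(nuc, kind="nuclei"))
        assert cells.n_objects == 1
        # cell covers most of the bright footprint and contains the nucleus
        assert (cells.labels[nuc > 0] == 1).all()
        bright = cell_img > 700
        overlap = (cells.labels > 0) & bright
        assert overlap.sum() / bright.sum() > 0.9

    def test_floor_above_max_shrinks_to_nucleus_core(self):
        shape = (200, 200)
        cell_img = _disk_image(shape, (100, 100), 80, 1500, 40)
        nuc = np.zeros(shape, dtype=np.int32)
        rr, cc = draw.disk((100, 100), 30, shape=shape)
        nuc[rr, cc] = 1
        params = SegmentationParams(cell_intensity_floor=1e6)
        cells = segment_cells(cell_img, LabelMask(nuc, kind="nuclei"), params)
        np.testing.assert_array_equal(cells.labels > 0, nuc > 0)

    def test_two_cells_partition_along_dim_ridge(self):
        shape = (200, 300)
        img = np.full(shape, 40.0)
        for c in ((100, 90), (100, 210)):
            rr, cc = draw.disk(c, 80, shape=shape)
            img[rr, cc] = 1500
        img[:, 148:152] = 200.0  # dim ridge between the two cells
        nuc = np.zeros(shape, dtype=np.int32)
        for k, c in enumerate(((100, 90), (100, 210)), start=1):
            rr, cc = draw.disk(c, 25, shape=shape)
            nuc[rr, cc] = k
        cells = segment_cells(img, LabelMask(nuc, kind="nuclei"))
        assert cells.n_objects == 2
        # left bright side -> cell 1, right bright side -> cell 2
        assert cells.labels[100, 60] == 1
        assert cells.labels[100, 240] == 2

    def test_no_nuclei_yields_empty(self):
        img = np.full((64, 64), 40.0)
        cells = segment_cells(img, LabelMask(np.zeros((64, 64), dtype=np.int32), kind="nuclei"))
        assert cells.n_objects == 0


class TestMitoClusters:
    def test_tubules_recovered_inside_cell(self):
        shape = (200, 200)
        cells = np.zeros(shape, dtype=np.int32)
        rr, cc = draw.disk((100, 100), 90, shape=shape)
        cells[rr, cc] = 1
        img = np.full(shape, 20.0)
        for row in (60, 80, 100, 120, 140):
            img[row : row + 3, 40:160] = 4000
        clusters, c2c = segment_mito_clusters(img, LabelMask(cells, kind="cells"))
        assert clusters.n_objects == 5
        assert set(c2c.values()) == {1}

    def test_speck_below_min_area_removed(self):
        shape = (128, 128)
        cells = np.ones(shape, dtype=np.int32)
        img = np.full(shape, 20.0)
        img[20:24, 10:110] = 4000.0  # large tubule, always detected
        img[80, 80] = 8000.0  # hot pixel: 9 px above threshold, < 10 px minimum
        clusters, _ = segment_mito_clusters(img, LabelMask(cells, kind="cells"))
        assert clusters.n_objects == 1
        assert clusters.labels[75:86, 75:86].max() == 0
        # a 3x3 block crosses the minimum area and is kept
        img[79:82, 79:82] = 4000.0
        clusters, _ = segment_mito_clusters(img, LabelMask(cells, kind="cells"))
        assert clusters.n_objects == 2

    def test_signal_outside_cells_clipped(self):
        shape = (128, 128)
        cells = np.zeros(shape, dtype=np.int32)
        cells[:, :64] = 1
        img = np.full(shape, 20.0)
        img[60:64, 90:120] = 4000  # bright object entirely outside the cell
        img[20:24, 10:40] = 4000  # and one inside
        clusters, c2c = segment_mito_clusters(img, LabelMask(cells, kind="cells"))
        assert clusters.n_objects == 1
        assert (clusters.labels[:, 64:] == 0).all()

    def test_straddling_component_split_per_cell(self):
        shape = (64, 128)
        cells = np.zeros(shape, dtype=np.int32)
        cells[:, :64] = 1
        cells[:, 64:] = 2
        img = np.full(shape, 20.0)
        img[30:34, 30:100] = 4000  # crosses the cell boundary
        clusters, c2c = segment_mito_clusters(img, LabelMask(cells, kind="cells"))
        assert clusters.n_objects == 2
        assert sorted(c2c.values()) == [1, 2]


class TestFieldCascade:
    def test_synthetic_field_recovers_all_cells(self, synth_field):
        fld, truth = synth_field
        seg = segment_field(fld)
        assert seg.nuclei.n_objects == truth.nuclei.n_objects
        assert seg.cells.n_objects == truth.cells.n_objects
        # every cluster belongs to exactly one cell
        for cid, cell in seg.cluster_to_cell.items():
            owner = np.unique(seg.cells.labels[seg.clusters.labels == cid])
            assert list(owner) == [cell]
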