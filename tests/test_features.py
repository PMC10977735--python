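"""Shape descriptors, skeleton/localization features and aggregation rules."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage import draw

from mitomorph.features import (
    FEATURE_NAMES,
    SUMMED_FEATURES,
    CellFeatureRecord,
    aggregate_objects,
    localization_features,
    records_to_frame,
    shape_descriptors,
    skeleton_features,
)


def _disk_mask(radius=20, pad=5):
    side = 2 * (radius + pad)
    mask = np.zeros((side, side), dtype=bool)
    rr, cc = draw.disk((side // 2, side // 2), radius)
    mask[rr, cc] = True
    return mask


class TestShapeDescriptors:
    def test_disk(self):
        d = shape_descriptors(_disk_mask(20))
        assert d["area"] == pytest.approx(math.pi * 20**2, rel=0.02)
        assert d["perimeter"] == pytest.approx(2 * math.pi * 20, rel=0.05)
        assert d["compaction"] == pytest.approx(1.0, abs=0.03)
        assert d["elongation"] == pytest.approx(1.0, abs=0.03)
        # roundness = eq_diam / (perimeter/pi); for a circle eq_diam = 2R,
        # perimeter = 2*pi*R -> roundness = 1
        assert d["roundness"] == pytest.approx(1.0, abs=0.05)
        assert d["euler"] == 1
        # convex hull of a disk is the disk itself
        assert d["solidity"] == pytest.approx(1.0, abs=0.05)

    def test_two_to_one_ellipse(self):
        mask = np.zeros((100, 160), dtype=bool)
        rr, cc = draw.ellipse(50, 80, 20, 40)
        mask[rr, cc] = True
        d = shape_descriptors(mask)
        assert d["elongation"] == pytest.approx(2.0, rel=0.05)
        assert d["compaction"] == pytest.approx(0.5, rel=0.05)
        assert d["roundness"] < 1.0

    def test_annulus_euler_zero(self):
        mask = _disk_mask(20)
        inner = np.zeros_like(mask)
        rr, cc = draw.disk((mask.shape[0] // 2, mask.shape[1] // 2), 10)
        inner[rr, cc] = True
        d = shape_descriptors(mask & ~inner)
        assert d["euler"] == 0
        # hull perimeter (outer circle) < object perimeter (outer + inner)
        assert d["solidity"] < 1.0

    def test_single_pixel_degenerate(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        d = shape_descriptors(mask)
        assert d["area"] == 1.0 and d["roundness"] == 1.0 and d["elongation"] == 1.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            shape_descriptors(np.zeros((4, 4), dtype=bool))


class TestSkeletonFeatures:
    def test_bar_width(self, bar_mask):
        # 100x5 bar: area 500, skeleton length ~95 -> width ~5
        f = skeleton_features(95.0, 0, 2, float(bar_mask.sum()))
        assert f["Skel_Width"] == pytest.approx(5.0, rel=0.11)
        assert f["Skel_BranchPointsEndPointsRatio"] == 0.0

    def test_cross_ratio(self):
        f = skeleton_features(120.0, 1, 4, 360.0)
        assert f["Skel_BranchPointsEndPointsRatio"] == pytest.approx(1 / 5)
        assert f["Skel_BranchPointsCount"] == 1.0
        assert f["Skel_EndPointsCount"] == 4.0

    def test_degenerate_point_skeleton(self):
        f = skeleton_features(0.0, 0, 1, 4.0)
        assert f["Skel_Width"] == 4.0  # length floored at 1
        assert f["Skel_BranchPointsEndPointsRatio"] == 0.0


class TestLocalizationFeatures:
    def test_skeleton_at_nucleus_border(self):
        cell = np.zeros((50, 50), dtype=bool)
        cell[5:45, 5:45] = True
        nuc = np.zeros_like(cell)
        nuc[20:30, 20:30] = True
        skel = np.zeros_like(cell)
        skel[25, 30] = True  # just outside the nucleus edge
        f = localization_features(skel, cell, nuc)
        assert f["DistToNuclei"] <= 1.5
        assert f["RatioDistMemb0Nucl1"] < 0.2

    def test_skeleton_at_membrane(self):
        cell = np.zeros((50, 50), dtype=bool)
        cell[5:45, 5:45] = True
        nuc = np.zeros_like(cell)
        nuc[20:30, 20:30] = True
        skel = np.zeros_like(cell)
        skel[6, 25] = True  # hugging the cell border
        f = localization_features(skel, cell, nuc)
        assert f["DistToMembrane"] <= 2.5
        assert f["RatioDistMemb0Nucl1"] > 0.8

    def test_midpoint_ratio_half(self):
        cell = np.zeros((41, 41), dtype=bool)
        cell[5:36, 5:36] = True
        nuc = np.zeros_like(cell)
        nuc[19:22, 19:22] = True
        skel = np.zeros_like(cell)
        skel[20, 12] = True  # ~halfway between nucleus edge and left border
        f = localization_features(skel, cell, nuc)
        assert f["RatioDistMemb0Nucl1"] == pytest.approx(0.5, abs=0.1)

    def test_empty_skeleton_is_nan(self):
        cell = np.ones((10, 10), dtype=bool)
        f = localization_features(np.zeros_like(cell), cell, np.zeros_like(cell))
        assert all(np.isnan(v) for v in f.values())


class TestAggregation:
    def test_sum_vs_mean_on_two_objects(self):
        per_object = pd.DataFrame(
            {
                "MitoCluster_Area": [10.0, 5.0],
                "MitoCluster_Roundness": [0.8, 0.4],
                "Mito_Length": [7.0, 3.0],
                "MitoCluster_Perimeter": [12.0, 8.0],
            }
        )
        out = aggregate_objects(
            per_object,
            ["MitoCluster_Area", "MitoCluster_Roundness", "Mito_Length", "MitoCluster_Perimeter"],
        )
        assert out["MitoCluster_Area"] == 15.0  # areas are summed
        assert out["Mito_Length"] == 10.0  # lengths are summed
        assert out["MitoCluster_Roundness"] == pytest.approx(0.6)  # shape: mean
        assert out["MitoCluster_Perimeter"] == pytest.approx(10.0)  # perimeter: mean

    def test_summed_set_is_exactly_areas_and_lengths(self):
        assert SUMMED_FEATURES == {"MitoCluster_Area", "Skel_Length", "Mito_Length"}

    def test_empty_frame_gives_nan(self):
        out = aggregate_objects(pd.DataFrame(), ["MitoCluster_Area", "Mito_Roundness"])
        assert all(np.isnan(v) for v in out.values())


class TestRecordSchema:
    def test_record_requires_all_31_features(self):
        feats = {n: 0.0 for n in FEATURE_NAMES}
        rec = CellFeatureRecord(condition="c", field_id="f", cell_id=1, features=feats)
        row = rec.as_row()
        assert list(row)[:3] == ["condition", "field_id", "cell_id"]
        del feats[FEATURE_NAMES[0]]
        with pytest.raises(ValueError, match="schema"):
            CellFeatureRecord(condition="c", field_id="f", cell_id=1, features=feats)

    def test_frame_column_order(self):
        feats = {n: 1.0 for n in FEATURE_NAMES}
        rec = CellFeatureRecord(condition="c", field_id="f", cell_id=1, features=feats)
        df = records_to_frame([rec])
        assert list(df.columns) == ["condition", "field_id", "cell_id"] + FEATURE_NAMES
        assert len(FEATURE_NAMES) == 31
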