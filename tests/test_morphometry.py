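"""The per-structure parameter catalogue and its invariants."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from spheroscreen.morphometry import (
    PARAMETER_CATALOGUE,
    RESULT_COLUMNS,
    appendage_features,
    assemble_records,
    channel_features,
    geometry,
    neighbor_features,
    parameter_catalogue,
    shape_features,
)
from spheroscreen.segmentation import (
    SegmentationConfig,
    extract_body_appendages,
    segment_cells,
)

from conftest import as_structure, rasterize_disk


class TestGeometry:
    def test_single_pixel_structure(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        geom = geometry(as_structure(mask))
        assert geom.center == (2.0, 2.0)
        assert geom.radius == 0.0
        np.testing.assert_array_equal(geom.distances, [0.0])

    def test_disk_quantile_radius(self):
        geom = geometry(as_structure(rasterize_disk(50)), m=0.25)
        assert 48 <= geom.radius <= 50

    def test_square_max_distance_matches_brute_force(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True  # 10x10 square
        geom = geometry(as_structure(mask))
        # brute force: distances from the centroid to all edge pixels
        center = (6.5, 6.5)
        edges = []
        for i in range(2, 12):
            for j in range(2, 12):
                neighbors = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
                if any(not mask[a, b] for a, b in neighbors):
                    edges.append(np.hypot(i - center[0], j - center[1]))
        assert len(edges) == len(geom.distances) == 36
        assert np.isclose(max(geom.distances), max(edges))
        np.testing.assert_allclose(sorted(geom.distances), sorted(edges))

    def test_radius_bounded_by_distance_extremes(self):
        geom = geometry(as_structure(rasterize_disk(17)), m=0.25)
        assert geom.distances.min() <= geom.radius <= geom.distances.max()


class TestShapeFeatures:
    def test_disk_is_round_and_smooth(self, config):
        s = as_structure(rasterize_disk(50))
        extract_body_appendages(s, config)
        f = shape_features(s, geometry(s))
        assert f["Roundness"] >= 95
        assert f["Roughness"] <= 2
        assert abs(f["RoundDiff"]) < 2

    def test_elongated_rectangle_much_less_round(self, config):
        rect = np.zeros((20, 110), dtype=bool)
        rect[5:15, 5:105] = True  # 100 x 10
        s = as_structure(rect)
        f_rect = shape_features(s, geometry(s))
        disk = as_structure(rasterize_disk(50))
        f_disk = shape_features(disk, geometry(disk))
        assert f_disk["Roundness"] - f_rect["Roundness"] >= 20

    def test_appendages_make_body_rounder_than_whole(self, config):
        from test_segmentation import TestBodyAppendages

        s = TestBodyAppendages().planted([40, 35, 30])
        extract_body_appendages(s, config)
        f = shape_features(s, geometry(s))
        assert f["RoundDiff"] > 0


class TestAppendageFeatures:
    def test_perfect_disk_all_zero(self, config):
        s = as_structure(rasterize_disk(40))
        body, apps = extract_body_appendages(s, config)
        f = appendage_features(s, body, apps)
        assert f == {"AppIndex": 0.0, "MaxApp": 0.0, "MedApp": 0.0, "AppNumber": 0.0}

    def test_planted_lengths_recovered_within_kernel_tolerance(self, config):
        from test_segmentation import TestBodyAppendages

        s = TestBodyAppendages().planted([20, 30, 40])
        body, apps = extract_body_appendages(s, config)
        f = appendage_features(s, body, apps)
        assert f["AppNumber"] == 3
        assert 36 <= f["MaxApp"] <= 44
        assert 27 <= f["MedApp"] <= 33

    def test_app_index_is_area_ratio(self):
        body = np.zeros((100, 100), dtype=bool)
        body[:30, :100] = True  # 3000 px body
        appendage = np.zeros_like(body)
        appendage[30:36, :100] = True  # 600 px appendage
        f = appendage_features(as_structure(body | appendage), body, [appendage])
        assert np.isclose(f["AppIndex"], 0.2)


class TestNeighborFeatures:
    def test_two_disks_center_distance(self):
        labels = np.zeros((200, 260), dtype=np.int32)
        yy, xx = np.mgrid[0:200, 0:260]
        labels[(yy - 100) ** 2 + (xx - 60) ** 2 <= 25**2] = 1
        labels[(yy - 100) ** 2 + (xx - 180) ** 2 <= 25**2] = 2
        per, _ = neighbor_features(labels)
        assert abs(per[1]["Closest"] - 120) <= 1
        assert abs(per[2]["Closest"] - 120) <= 1
        assert per[1]["Neighbors"] == 0 and per[1]["SharedBound"] == 0

    def test_single_structure_sentinel(self):
        labels = rasterize_disk(10).astype(np.int32)
        per, _ = neighbor_features(labels)
        assert per[1] == {"Closest": -1.0, "Neighbors": 0.0, "SharedBound": 0.0}

    def test_touching_structures_share_boundary(self):
        labels = np.zeros((20, 40), dtype=np.int32)
        labels[5:15, 5:20] = 1
        labels[5:15, 20:35] = 2
        per, _ = neighbor_features(labels)
        assert per[1]["Neighbors"] == 1 and per[2]["Neighbors"] == 1
        assert per[1]["SharedBound"] >= 10

    def test_cell_ratio_arithmetic(self):
        labels = np.zeros((512, 672), dtype=np.int32)
        labels[0:10, 0:10] = 1  # 100 px structure in the full field
        _, cell_ratio = neighbor_features(labels)
        assert np.isclose(cell_ratio, 100 * 100 / (512 * 672))


class TestChannelFeatures:
    def test_constant_intensity(self, config):
        s = as_structure(rasterize_disk(20))
        img = np.where(s.mask, 123.0, 0.0)
        f = channel_features(s, geometry(s), img, np.zeros(s.mask.shape, np.int32))
        assert np.isclose(f["Density"], 123.0)
        assert np.isclose(f["Deviation"], 0.0)
        assert f["CellNumber"] == 0 and f["AveArea"] == 0

    def test_planted_dots_give_exact_counts_and_areas(self, config):
        # dots of exactly 21 px (radius 2.5) in a 1976-px structure
        s = as_structure(rasterize_disk(25))
        assert s.area == 1961
        img = np.where(s.mask, 20.0, 0.0)
        c = s.mask.shape[0] // 2
        yy, xx = np.mgrid[0 : s.mask.shape[0], 0 : s.mask.shape[1]]
        dot_area = None
        for k in range(5):
            cy, cx = c + (k % 2) * 12 - 6, c + (k // 2) * 12 - 12
            dot = (yy - cy) ** 2 + (xx - cx) ** 2 <= 2.5**2
            img[dot] = 220.0
            dot_area = int(dot.sum())
        cells = segment_cells(s, img, config)
        f = channel_features(s, geometry(s), img, cells)
        assert f["CellNumber"] == 5
        assert np.isclose(f["AveArea"], dot_area)
        assert np.isclose(f["AreaRatio"], 100 * 5 * dot_area / s.area)

    def test_annulus_hollow_disk_not(self, config):
        s = as_structure(rasterize_disk(30))
        geom = geometry(s)
        c = s.mask.shape[0] // 2
        yy, xx = np.mgrid[0 : s.mask.shape[0], 0 : s.mask.shape[1]]
        rr = np.hypot(yy - c, xx - c)
        annulus_img = np.where(rr <= 15, 10.0, np.where(s.mask, 200.0, 0.0))  # lumen = half radius
        filled_img = np.where(s.mask, 200.0, 0.0)
        zeros = np.zeros(s.mask.shape, np.int32)
        hollow = channel_features(s, geom, annulus_img, zeros)["Hollowness"]
        solid = channel_features(s, geom, filled_img, zeros)["Hollowness"]
        assert hollow >= 80
        assert solid <= 1


class TestRecords:
    def test_catalogue_has_19_named_parameters(self):
        assert len(parameter_catalogue()) == 19
        assert len(set(PARAMETER_CATALOGUE)) == 19

    def test_one_row_per_structure_with_fixed_columns(self, default_field):
        _, truth, result = default_field
        assert len(result.records) == len(truth.structures)
        assert list(result.records.columns) == list(RESULT_COLUMNS)

    def test_structure_without_red_signal_has_zero_red_features(self, matched_records):
        no_dot = [row for s, row in matched_records if s.dot_count == 0]
        assert no_dot, "fixture should contain at least one dot-free structure"
        for row in no_dot:
            assert row["CellNumber_R"] == 0
            assert row["AveArea_R"] == 0
            assert row["AreaRatio_R"] == 0


class TestInvariants:
    PERCENT = ["Roundness", "FiltRound", "Roughness", "CellRatio",
               "AreaRatio_R", "Hollowness_R", "AreaRatio_G", "Hollowness_G"]

    def test_percentage_features_bounded(self, default_field):
        _, _, result = default_field
        for col in self.PERCENT:
            vals = result.records[col]
            assert ((vals >= 0) & (vals <= 100)).all(), col

    def test_rotation_invariance_under_90_degrees(self, config):
        from test_segmentation import TestBodyAppendages

        s0 = TestBodyAppendages().planted([25, 35])
        results = []
        for k in range(4):
            s = as_structure(np.rot90(s0.mask, k))
            body, apps = extract_body_appendages(s, config)
            f = shape_features(s, geometry(s))
            f.update(appendage_features(s, body, apps))
            results.append(f)
        base = results[0]
        for f in results[1:]:
            assert abs(f["Roundness"] - base["Roundness"]) <= 3
            assert abs(f["Roughness"] - base["Roughness"]) <= 3
            assert abs(f["AppIndex"] - base["AppIndex"]) <= 0.05 * max(base["AppIndex"], 1)

    def test_scale_covariance_under_upsampling(self, config):
        from test_segmentation import TestBodyAppendages

        s0 = TestBodyAppendages().planted([30])
        up = as_structure(np.kron(s0.mask, np.ones((2, 2), dtype=bool)))
        f0 = shape_features(s0, geometry(s0))
        g0, g2 = geometry(s0), geometry(up)
        f2 = shape_features(up, geometry(up))
        assert abs(f2["Area"] / f0["Area"] - 4) <= 0.2
        assert abs(g2.radius / g0.radius - 2) <= 0.1
        assert abs(f2["Roundness"] - f0["Roundness"]) <= 3

    def test_planted_dead_cell_fraction_recovered(self, matched_records):
        for s, row in matched_records:
            truth_pct = 100 * s.dot_area / s.area
            assert abs(row["AreaRatio_R"] - truth_pct) <= 2
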