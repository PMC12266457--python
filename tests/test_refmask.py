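"""Reference-mask workflow: sampling, range extraction, thresholding."""

import numpy as np
import pandas as pd
import pytest

from burntseg import Scene
from burntseg.refmask import (BandRange, SampleSet, extract_band_ranges,
                              sample_raster_values, threshold_mask)
from burntseg.raster import BAND_NAMES

FULL_RANGE = BandRange({b: (0.0, 1.0) for b in BAND_NAMES})


class TestSampleRasterValues:
    def test_point_lookup_returns_pixel_values(self):
        bands = np.zeros((2, 2, 4), dtype=np.float32)
        bands[0, 1] = [0.2, 0.1, 0.1, 0.05]
        scene = Scene(bands=bands)
        table = sample_raster_values(scene, SampleSet(points=[(0, 1, "burnt")]))
        assert table.iloc[0][list(BAND_NAMES)].tolist() == pytest.approx(
            [0.2, 0.1, 0.1, 0.05])

    def test_degenerate_polygon_equals_point(self, tiny_scene):
        pt = sample_raster_values(tiny_scene, SampleSet(points=[(1, 1, "burnt")]))
        ring = [(1, 1), (1, 1), (1, 1)]
        poly = sample_raster_values(tiny_scene,
                                    SampleSet(polygons=[(ring, "burnt")]))
        assert pt[list(BAND_NAMES)].values.tolist() == poly[list(BAND_NAMES)].values.tolist()

    def test_three_points_match_manual_lookup(self, tiny_scene):
        pts = [(0, 0, "burnt"), (1, 2, "unburnt"), (2, 1, "burnt")]
        table = sample_raster_values(tiny_scene, SampleSet(points=pts))
        for (r, c, label), (_, row) in zip(pts, table.iterrows()):
            assert row["label"] == label
            np.testing.assert_allclose(row[list(BAND_NAMES)].astype(float).to_numpy(),
                                       tiny_scene.bands[r, c], rtol=1e-6)

    def test_out_of_bounds_point_names_the_sample(self, tiny_scene):
        with pytest.raises(IndexError, match="#1"):
            sample_raster_values(tiny_scene,
                                 SampleSet(points=[(0, 0, "burnt"), (5, 0, "burnt")]))

    def test_polygon_covers_interior_pixels(self, small_scene):
        scene, _ = small_scene
        ring = [(10, 10), (10, 20), (20, 20), (20, 10)]
        table = sample_raster_values(scene, SampleSet(polygons=[(ring, "burnt")]))
        assert len(table) > 50  # interior of a 10x10 square


class TestExtractBandRanges:
    def test_single_sample_min_equals_max(self, tiny_scene):
        table = sample_raster_values(tiny_scene, SampleSet(points=[(1, 1, "burnt")]))
        br = extract_band_ranges(table)
        for b in BAND_NAMES:
            lo, hi = br.ranges[b]
            assert lo == hi

    def test_two_samples_order_statistics(self):
        table = pd.DataFrame({"row": [0, 0], "col": [0, 1],
                              "label": ["burnt", "burnt"],
                              "nir": [0.1, 0.3], "red": [0.2, 0.1],
                              "green": [0.0, 0.5], "blue": [0.4, 0.4]})
        br = extract_band_ranges(table)
        assert br.ranges["nir"] == (0.1, 0.3)
        assert br.ranges["red"] == (0.1, 0.2)

    def test_matches_brute_force_min_max(self, small_scene, rng):
        scene, _ = small_scene
        pts = [(int(r), int(c), "burnt")
               for r, c in rng.integers(0, 128, size=(10, 2))]
        table = sample_raster_values(scene, SampleSet(points=pts))
        br = extract_band_ranges(table)
        for bi, b in enumerate(BAND_NAMES):
            vals = [scene.bands[r, c, bi] for r, c, _ in pts]
            assert br.ranges[b] == (pytest.approx(min(vals)), pytest.approx(max(vals)))

    def test_no_burnt_samples_rejected(self, tiny_scene):
        table = sample_raster_values(tiny_scene, SampleSet(points=[(0, 0, "unburnt")]))
        with pytest.raises(ValueError):
            extract_band_ranges(table)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            BandRange({"nir": (0.5, 0.1), "red": (0, 1), "green": (0, 1),
                       "blue": (0, 1)})


class TestThresholdMask:
    def test_full_range_all_forest_marks_everything(self, tiny_scene):
        mask = threshold_mask(tiny_scene, FULL_RANGE, np.ones((3, 3), np.uint8))
        assert mask.all()

    def test_empty_intersection_marks_nothing(self, tiny_scene):
        br = BandRange({b: (2.0, 3.0) for b in BAND_NAMES})
        assert not threshold_mask(tiny_scene, br,
                                  np.ones((3, 3), np.uint8)).any()

    def test_matches_per_pixel_brute_force(self, rng):
        bands = rng.random((4, 4, 4)).astype(np.float32)
        scene = Scene(bands=bands)
        br = BandRange({b: (0.2, 0.7) for b in BAND_NAMES})
        forest = (rng.random((4, 4)) > 0.3).astype(np.uint8)
        mask = threshold_mask(scene, br, forest)
        for r in range(4):
            for c in range(4):
                expect = forest[r, c] == 1 and all(
                    0.2 <= bands[r, c, i] <= 0.7 for i in range(4))
                assert bool(mask[r, c]) == expect

    def test_forest_constraint_is_absolute(self, tiny_scene):
        mask = threshold_mask(tiny_scene, FULL_RANGE, np.zeros((3, 3), np.uint8))
        assert not mask.any()

    def test_widening_a_band_never_removes_pixels(self, small_scene, rng):
        scene, truth = small_scene
        br = BandRange({b: (0.05, 0.4) for b in BAND_NAMES})
        base = threshold_mask(scene, br, truth.forest_mask)
        wide = BandRange({b: ((0.0, 0.5) if b == "nir" else (0.05, 0.4))
                          for b in BAND_NAMES})
        grown = threshold_mask(scene, wide, truth.forest_mask)
        assert np.all(grown[base == 1] == 1)

    def test_closure_ranges_reselect_their_samples(self, small_scene, rng):
        """Every burnt-labelled sample pixel is burnt in the derived mask."""
        scene, truth = small_scene
        burnt_px = np.argwhere((truth.burnt == 1))
        take = burnt_px[rng.choice(len(burnt_px), size=25, replace=False)]
        pts = [(int(r), int(c), "burnt") for r, c in take]
        table = sample_raster_values(scene, SampleSet(points=pts))
        br = extract_band_ranges(table)
        mask = threshold_mask(scene, br, truth.forest_mask)
        for r, c, _ in pts:
            assert mask[r, c] == 1

    def test_shape_mismatch_rejected(self, tiny_scene):
        with pytest.raises(ValueError):
            threshold_mask(tiny_scene, FULL_RANGE, np.ones((2, 2), np.uint8))


class TestGeoJsonIO:
    def test_roundtrip_points_and_polygons(self, tmp_path):
        import json
        doc = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {"class": "burnt"},
             "geometry": {"type": "Point", "coordinates": [2, 1]}},
            {"type": "Feature", "properties": {"class": "unburnt"},
             "geometry": {"type": "Polygon",
                          "coordinates": [[[0, 0], [2, 0], [2, 2], [0, 2], [0, 0]]]}},
        ]}
        path = tmp_path / "samples.geojson"
        path.write_text(json.dumps(doc))
        ss = SampleSet.from_geojson(path)
        assert ss.points == [(1, 2, "burnt")]
        assert ss.polygons[0][1] == "unburnt"
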