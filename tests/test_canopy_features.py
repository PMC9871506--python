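import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopydx import (
    build_mask,
    compute_index,
    extract_features,
    generate_scene,
    train_pixel_classifier,
)
from canopydx.bands import BAND_NAMES
from canopydx.canopy_features import FEATURE_COLUMNS, VI_NAMES
from canopydx.synthetic_data import SampleRegion


def bandset(B=0.05, G=0.1, R=0.06, RE=0.3, NIR=0.5):
    return {"B": B, "G": G, "R": R, "RE": RE, "NIR": NIR}


class TestComputeIndex:
    @pytest.mark.parametrize(
        "name, bands, expected",
        [
            ("NDVI", bandset(NIR=0.4, R=0.4), 0.0),
            ("NDVI", bandset(NIR=0.8, R=0.2), 0.6),
            ("GRVI", bandset(NIR=0.6, G=0.15), 4.0),
            ("BRVI", bandset(R=0.12, B=0.06), 2.0),
            ("RVI", bandset(NIR=0.6, R=0.2), 3.0),
            ("DVI", bandset(NIR=0.6, R=0.2), 0.4),
            ("SAVI", bandset(NIR=0.6, R=0.2), 1.5 * 0.4 / 1.3),
            ("OSAVI", bandset(NIR=0.6, R=0.2), 0.4 / 0.96),
            ("EVI", bandset(NIR=0.6, R=0.2, B=0.08), 2.5 * 0.4 / (0.6 + 1.2 - 0.6 + 1)),
            ("GNDVI", bandset(NIR=0.6, G=0.2), 0.5),
            ("NDRE", bandset(NIR=0.6, RE=0.2), 0.5),
            ("LCI", bandset(NIR=0.6, RE=0.3, R=0.2), 0.75),
            ("NDWI", bandset(NIR=0.6, G=0.2), -0.5),
            ("BNDVI", bandset(NIR=0.6, B=0.2), 0.5),
            ("BVI", bandset(NIR=0.6, B=0.2), 3.0),
            ("RDVI", bandset(NIR=0.61, R=0.25), np.sqrt(0.36)),
        ],
    )
    def test_printed_formulas(self, name, bands, expected):
        assert compute_index(name, bands) == pytest.approx(expected, rel=1e-12)

    def test_rdvi_literature_variant(self):
        b = bandset(NIR=0.61, R=0.25)
        lit = compute_index("RDVI", b, rdvi_form="literature")
        assert lit == pytest.approx(0.36 / np.sqrt(0.86), rel=1e-12)
        assert lit != compute_index("RDVI", b)

    def test_zero_denominator_propagates_nan(self):
        assert np.isnan(compute_index("GRVI", bandset(G=0.0)))
        assert np.isnan(compute_index("LCI", bandset(NIR=0.3, R=0.3)))
        assert np.isnan(compute_index("RDVI", bandset(NIR=0.2, R=0.3)))

    def test_unknown_index_rejected(self):
        with pytest.raises(KeyError):
            compute_index("XYZ", bandset())

    def test_array_inputs_vectorize(self):
        nir = np.array([0.8, 0.6])
        r = np.array([0.2, 0.2])
        out = compute_index("NDVI", bandset(NIR=nir, R=r))
        np.testing.assert_allclose(out, [0.6, 0.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=5, max_size=5))
    def test_normalized_difference_bounds(self, vals):
        bands = dict(zip(BAND_NAMES, vals))
        for name in ("NDVI", "GNDVI", "NDRE", "NDWI", "BNDVI"):
            v = compute_index(name, bands)
            assert np.isnan(v) or -1.0 <= v <= 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=5, max_size=5))
    def test_ndwi_is_negated_gndvi(self, vals):
        bands = dict(zip(BAND_NAMES, vals))
        assert compute_index("NDWI", bands) == pytest.approx(
            -compute_index("GNDVI", bands), rel=1e-12
        )


class TestPixelClassifier:
    def test_separable_spectra_perfect_holdout(self):
        rng = np.random.default_rng(0)
        canopy = np.tile([0.05, 0.1, 0.06, 0.3, 0.5], (200, 1))
        soil = np.tile([0.14, 0.2, 0.24, 0.28, 0.32], (200, 1))
        X = np.vstack([canopy, soil])
        y = np.r_[np.ones(200, bool), np.zeros(200, bool)]
        clf = train_pixel_classifier(X + rng.normal(0, 1e-6, X.shape), y, seed=0)
        assert clf.holdout_accuracy == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(1000, 5))
        y = rng.random(1000) < 0.5
        clf = train_pixel_classifier(X, y, seed=1)
        assert abs(clf.holdout_accuracy - 0.5) < 0.12

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).uniform(size=(100, 5))
        with pytest.raises(ValueError):
            train_pixel_classifier(X, np.ones(100, bool))

    def test_default_scene_accuracy_and_mask_f1(self, small_scene):
        scene, truth = small_scene
        rng = np.random.default_rng(3)
        canopy = np.argwhere(truth.cover_fraction >= 1.0)
        soil = np.argwhere(truth.cover_fraction == 0.0)
        ci = canopy[rng.choice(len(canopy), 500, replace=False)]
        si = soil[rng.choice(len(soil), 500, replace=False)]
        X = np.vstack([
            scene.bands[:, ci[:, 0], ci[:, 1]].T,
            scene.bands[:, si[:, 0], si[:, 1]].T,
        ])
        y = np.r_[np.ones(500, bool), np.zeros(500, bool)]
        clf = train_pixel_classifier(X, y, seed=3)
        assert clf.holdout_accuracy > 0.95

        mask = build_mask(scene, clf)
        tp = (mask.mask & truth.mask).sum()
        precision = tp / mask.mask.sum()
        recall = tp / truth.mask.sum()
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 > 0.95
        assert mask.provenance["classifier_id"] == "linear-svm"


class TestExtractFeatures:
    def _uniform_scene(self, value=0.4):
        from canopydx.synthetic_data import MultispectralScene

        bands = np.full((5, 8, 8), value, np.float32)
        regions = [SampleRegion("s0", "CK", 0, 0, 8, 8)]
        return MultispectralScene(bands, "reflectance", 1, 5.0, 0.265, regions, [])

    def test_uniform_region_means_equal_pixel_value(self):
        scene = self._uniform_scene(0.4)
        table = extract_features(scene, np.ones((8, 8), bool), min_pixels=1)
        row = table.iloc[0]
        for b in BAND_NAMES:
            assert row[b] == pytest.approx(0.4)
        assert row["NDVI"] == pytest.approx(0.0)
        assert row["GRVI"] == pytest.approx(1.0)

    def test_checkerboard_mean_is_average(self):
        scene = self._uniform_scene(0.0)
        checker = np.indices((8, 8)).sum(axis=0) % 2 == 0
        scene.bands[:, checker] = 0.2
        scene.bands[:, ~checker] = 0.6
        table = extract_features(scene, np.ones((8, 8), bool), min_pixels=1)
        for b in BAND_NAMES:
            assert table.iloc[0][b] == pytest.approx(0.4)

    def test_matches_bruteforce_pixel_loop(self, small_scene):
        scene, truth = small_scene
        region = scene.regions[0]
        table = extract_features(scene, truth.mask, layout=[region])
        rmask = truth.mask[region.slices]
        row = table.iloc[0]
        for j, b in enumerate(BAND_NAMES):
            acc = [float(scene.bands[j][region.row0 + r, region.col0 + c])
                   for r in range(region.row1 - region.row0)
                   for c in range(region.col1 - region.col0)
                   if rmask[r, c]]
            assert row[b] == sum(acc) / len(acc)
        # pixel-wise NDVI then average, straight loop
        nir, red = scene.bands[4][region.slices], scene.bands[2][region.slices]
        vals = [(float(nir[r, c]) - float(red[r, c])) / (float(nir[r, c]) + float(red[r, c]))
                for r in range(rmask.shape[0]) for c in range(rmask.shape[1]) if rmask[r, c]]
        assert row["NDVI"] == pytest.approx(sum(vals) / len(vals), abs=1e-12)

    def test_empty_mask_flags_rows(self, small_scene):
        scene, _ = small_scene
        table = extract_features(scene, np.zeros(scene.shape, bool))
        assert table["flagged"].all()
        assert table[list(FEATURE_COLUMNS)].isna().all().all()

    def test_sparse_mask_below_minimum_flagged(self, small_scene):
        scene, truth = small_scene
        sparse = truth.mask.copy()
        keep = np.argwhere(sparse)[:10]
        sparse[:] = False
        sparse[keep[:, 0], keep[:, 1]] = True
        table = extract_features(scene, sparse, min_pixels=30)
        assert table["flagged"].all()

    def test_shape_mismatch_rejected(self, small_scene):
        scene, _ = small_scene
        with pytest.raises(ValueError):
            extract_features(scene, np.ones((3, 3), bool))

    def test_vi_of_means_variant_differs(self, small_scene):
        scene, truth = small_scene
        pw = extract_features(scene, truth.mask, pixelwise=True)
        vm = extract_features(scene, truth.mask, pixelwise=False)
        # ratio indices have Jensen bias: variants agree only approximately
        assert np.allclose(pw["GRVI"], vm["GRVI"], atol=0.5)
        assert not np.array_equal(pw["GRVI"], vm["GRVI"])

    def test_extracted_means_track_ground_truth(self, small_scene):
        scene, truth = small_scene
        table = extract_features(scene, truth.cover_fraction >= 1.0)
        for _, row in table.iterrows():
            want = truth.true_band_means[row["sample_id"]]
            for j, b in enumerate(BAND_NAMES):
                se = 0.01 / np.sqrt(row["n_pixels"])  # pixel noise sd 0.01
                assert abs(row[b] - want[j]) < 6 * se + 1e-3
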