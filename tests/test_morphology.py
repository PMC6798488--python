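"""Per-nucleus shape descriptors and GLCM texture features."""

import numpy as np
import pytest
from skimage.feature import graycoprops

from nucmorph import label_and_measure, shape_descriptors, shape_feature_block
from nucmorph.morphology import (
    HARALICK_FEATURE_NAMES,
    SHAPE_FEATURE_NAMES,
    haralick_feature_block,
    nucleus_glcm,
)
from nucmorph._stats import haralick_stats


def disk_mask(radius, size=None, intensity=None):
    size = size or (2 * radius + 11)
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    mask = ((xx - c) ** 2 + (yy - c) ** 2 <= radius**2).astype(np.uint8)
    img = mask.astype(float) * (intensity if intensity is not None else 100.0)
    return mask, img


def measure_single(mask, img):
    (rec,) = label_and_measure(mask, img)
    return rec


class TestShapeDescriptors:
    def test_circle_is_round_smooth_and_fills_its_circumcircle(self):
        mask, img = disk_mask(20)
        d = shape_descriptors(measure_single(mask, img))
        for i in range(1, 11):
            assert d[f"fd{i}"] < 0.02
        assert d["smoothness"] < 0.05
        assert d["area_ratio"] > 0.95
        assert d["dist_ratio"] > 0.95

    def test_hu_moments_invariant_to_rotation_and_translation(self):
        # an L-shaped blob, rotated 90 degrees exactly and translated
        mask = np.zeros((60, 60), dtype=np.uint8)
        mask[10:40, 10:20] = 1
        mask[30:40, 10:35] = 1
        rotated = np.zeros((80, 80), dtype=np.uint8)
        rotated[15:15 + 25, 20:20 + 30] = np.rot90(mask[10:40, 10:35])
        da = shape_descriptors(measure_single(mask, mask * 90.0))
        db = shape_descriptors(measure_single(rotated, rotated * 90.0))
        for i in range(1, 8):
            a, b = da[f"hu{i}"], db[f"hu{i}"]
            assert b == pytest.approx(a, rel=1e-6, abs=1e-12), f"hu{i}"

    def test_two_to_one_ellipse_eccentricity(self):
        yy, xx = np.mgrid[0:101, 0:101]
        mask = ((((xx - 50) / 40.0) ** 2 + ((yy - 50) / 20.0) ** 2) <= 1).astype(np.uint8)
        d = shape_descriptors(measure_single(mask, mask * 100.0))
        assert d["eccentricity"] == pytest.approx(np.sqrt(1 - 1 / 4), abs=0.02)

    def test_degenerate_boundary_rejected(self, small_nuclei):
        rec = small_nuclei[0]
        rec_short = type(rec)(
            id=rec.id, centroid=rec.centroid, area=rec.area,
            boundary=rec.boundary[:5], orientation=rec.orientation,
            mean_intensity=rec.mean_intensity, pixels=rec.pixels,
        )
        with pytest.raises(ValueError):
            shape_descriptors(rec_short)


class TestShapeBlock:
    def test_cardinality_and_unique_names(self):
        assert len(SHAPE_FEATURE_NAMES) == 100
        assert len(set(SHAPE_FEATURE_NAMES)) == 100

    def test_identical_nuclei_have_degenerate_aggregates(self):
        mask = np.zeros((40, 120), dtype=np.uint8)
        for k in range(3):
            mask[10:30, 10 + 40 * k:30 + 40 * k] = k + 1
        recs = label_and_measure(mask, mask.astype(float) * 10)
        feats = shape_feature_block(recs)
        for name in SHAPE_FEATURE_NAMES:
            if name.endswith("_sd"):
                assert feats[name] == pytest.approx(0.0, abs=1e-9), name
            if name.endswith("_minmax_ratio"):
                assert feats[name] == pytest.approx(1.0, abs=1e-9), name

    def test_aggregates_match_per_nucleus_recomputation(self, small_nuclei):
        subset = small_nuclei[:12]
        feats = shape_feature_block(subset)
        per = [shape_descriptors(n) for n in subset]
        col = np.array([p["area_ratio"] for p in per])
        assert feats["shape_area_ratio_mean"] == pytest.approx(col.mean())
        assert feats["shape_area_ratio_sd"] == pytest.approx(col.std())
        assert feats["shape_area_ratio_median"] == pytest.approx(np.median(col))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            shape_feature_block([])


class TestHaralick:
    def test_cardinality_and_unique_names(self):
        assert len(HARALICK_FEATURE_NAMES) == 26
        assert len(set(HARALICK_FEATURE_NAMES)) == 26

    def test_constant_nuclei_are_perfectly_ordered(self):
        mask, img = disk_mask(10)
        feats = haralick_feature_block(img, [measure_single(mask, img)])
        assert feats["har_energy_mean"] == 1.0
        assert feats["har_entropy_mean"] == 0.0
        assert feats["har_contrast_energy_mean"] == 0.0
        assert feats["har_energy_sd"] == 0.0

    def test_checkerboard_maximizes_contrast(self):
        """Among {constant, smooth gradient, checkerboard} the checkerboard
        has the largest contrast energy and less energy than constant."""
        size = 21
        yy, xx = np.mgrid[0:size, 0:size]
        mask = np.ones((size, size), dtype=np.uint8)
        patterns = {
            "constant": np.full((size, size), 100.0),
            "gradient": xx * 4.0,
            "checker": ((xx + yy) % 2) * 255.0,
        }
        ce, en = {}, {}
        for name, img in patterns.items():
            rec = measure_single(mask, img)
            stats = haralick_stats(nucleus_glcm(rec))
            ce[name], en[name] = stats["contrast_energy"], stats["energy"]
        assert ce["checker"] == max(ce.values())
        assert en["checker"] < en["constant"]

    def test_checkerboard_glcm_matches_direct_count(self):
        """On a tiny printed pattern the GLCM equals a hand count: every
        horizontal/vertical neighbor pair alternates levels, diagonal
        pairs repeat them."""
        img = np.array([[0, 255, 0], [255, 0, 255], [0, 255, 0]], dtype=float)
        mask = np.ones((3, 3), dtype=np.uint8)
        rec = None
        # pad so min-pixel filter passes: tile the pattern
        big = np.tile(img, (3, 3))
        mask = np.ones(big.shape, dtype=np.uint8)
        rec = measure_single(mask, big)
        p = nucleus_glcm(rec, levels=2)
        # off-diagonal mass comes from axial neighbors, diagonal from diagonals
        assert p[0, 1] == p[1, 0]
        assert p.sum() == pytest.approx(1.0)
        assert p[0, 1] + p[1, 0] > 0.5  # axial adjacencies dominate

    def test_matches_skimage_graycoprops_on_shared_statistics(self, rng):
        """Dual route: contrast and homogeneity of a random texture agree
        with skimage's graycoprops on the same normalized GLCM."""
        size = 25
        img = rng.integers(0, 256, size=(size, size)).astype(float)
        mask = np.ones((size, size), dtype=np.uint8)
        rec = measure_single(mask, img)
        p = nucleus_glcm(rec)
        stats = haralick_stats(p)
        p4 = p[:, :, None, None]
        assert stats["contrast_energy"] == pytest.approx(
            float(graycoprops(p4, "contrast")[0, 0])
        )
        assert stats["contrast_inverse_moment"] == pytest.approx(
            float(graycoprops(p4, "homogeneity")[0, 0])
        )
        assert stats["energy"] == pytest.approx(
            float(graycoprops(p4, "ASM")[0, 0])
        )
        assert stats["correlation"] == pytest.approx(
            float(graycoprops(p4, "correlation")[0, 0]), abs=1e-8
        )

    def test_small_nuclei_skipped_and_empty_rejected(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[0:3, 0:3] = 1  # 9 px < 16
        recs = label_and_measure(mask, mask.astype(float), min_area=1)
        with pytest.raises(ValueError):
            haralick_feature_block(mask.astype(float), recs)
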