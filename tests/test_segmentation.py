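"""ROI segmentation: Otsu, Harris, morphology, Canny, projections, layout."""

import numpy as np
import pytest

from thermasym import segmentation as seg
from thermasym.errors import (
    DegenerateHistogramError,
    LandmarkError,
    ThermasymError,
)
from thermasym.segmentation import (
    SegmentationConfig,
    canny_edge_map,
    corner_peaks,
    gray_projection,
    harris_corner_map,
    morph_clean,
    otsu_face_mask,
    segment,
)
from thermasym.synthgen import FacePhantomConfig, generate_face
from thermasym.thermal_io import GrayImage, ThermalImage, normalize_gray

KEYPOINT_NAMES = [
    "nostril_l", "nostril_r", "pupil_l", "pupil_r",
    "mouth_corner_l", "mouth_corner_r", "canthus_inner_l", "canthus_inner_r",
    "eyebrow_l", "eyebrow_r",
]


def keypoint_errors(found, truth):
    return {
        n: max(abs(a - b) for a, b in zip(getattr(found, n), getattr(truth, n)))
        for n in KEYPOINT_NAMES
    }


def brute_force_otsu(levels, L):
    """Exhaustive between-class variance maximization over all thresholds."""
    flat = levels.ravel()
    best_t, best_v = None, -1.0
    for t in range(L - 1):
        lo, hi = flat[flat <= t], flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_separable_bimodal_blob(self):
        levels = np.full((40, 40), 2)
        levels[10:30, 10:30] = 12
        g = GrayImage(levels, 16, 0.0, 16.0)
        mask = otsu_face_mask(g)
        assert mask.mask[20, 20] and not mask.mask[0, 0]
        assert mask.bbox == (10, 30, 10, 30)

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 16, size=(16, 16))
        if np.unique(levels).size < 2:
            pytest.skip("degenerate draw")
        from skimage.filters import threshold_otsu

        t = threshold_otsu(levels, nbins=16)
        assert brute_force_otsu(levels, 16) == t

    def test_single_level_image_rejected(self):
        g = GrayImage(np.zeros((16, 16), dtype=int), 16, 0.0, 16.0)
        with pytest.raises(DegenerateHistogramError):
            otsu_face_mask(g)

    def test_phantom_bbox_close_to_truth(self, phantom):
        img, truth = phantom
        gray = normalize_gray(img, 256)
        mask = otsu_face_mask(gray)
        assert all(abs(a - b) <= 3 for a, b in zip(mask.bbox, truth.face_bbox))


class TestHarris:
    def test_constant_image_no_response(self):
        g = GrayImage(np.full((20, 20), 5), 16, 0.0, 16.0)
        r = harris_corner_map(g)
        assert np.allclose(r, 0.0)
        assert corner_peaks(r).shape[0] == 0

    def test_bright_square_yields_four_corners(self):
        levels = np.zeros((64, 64), dtype=int)
        levels[20:44, 20:44] = 15
        g = GrayImage(levels, 16, 0.0, 16.0)
        peaks = corner_peaks(harris_corner_map(g), quantile=0.95, min_distance=5)
        corners = {(20, 20), (20, 43), (43, 20), (43, 43)}
        assert len(peaks) >= 4
        for cr, cc in corners:
            assert min(np.hypot(peaks[:, 0] - cr, peaks[:, 1] - cc)) <= 2.0

    def test_straight_edge_suppressed(self):
        levels = np.zeros((64, 64), dtype=int)
        levels[:, 32:] = 15
        g = GrayImage(levels, 16, 0.0, 16.0)
        r = harris_corner_map(g)
        # rank-1 structure tensor along the edge: no interior peak survives
        # the detection threshold (border junctions excluded)
        interior = r[5:-5, 5:-5]
        assert interior.max() < 0.01 * abs(interior.min())
        peaks = corner_peaks(r, quantile=0.99)
        for pr, pc in peaks:
            assert min(pr, pc, 63 - pr, 63 - pc) < 5


class TestMorphClean:
    def test_erosion_of_ones_leaves_interior(self):
        out = morph_clean(np.ones((10, 10), dtype=bool), 1, 0)
        assert out[1:-1, 1:-1].all() and not out[0].any() and not out[-1].any()

    def test_isolated_pixel_erased(self):
        b = np.zeros((9, 9), dtype=bool)
        b[4, 4] = True
        assert not morph_clean(b, 1, 0).any()

    def test_matches_sliding_window_min_max_oracle(self, rng):
        from skimage.morphology import disk

        b = rng.random((20, 20)) > 0.5
        footprint = disk(2).astype(bool)
        out = morph_clean(b, 2, 0)
        pad = np.pad(b, 2, constant_values=False)
        expected = np.zeros_like(b)
        for i in range(20):
            for j in range(20):
                expected[i, j] = pad[i:i + 5, j:j + 5][footprint].all()
        np.testing.assert_array_equal(out, expected)


class TestCanny:
    def test_constant_image_no_edges(self):
        g = GrayImage(np.full((32, 32), 5), 16, 0.0, 16.0)
        assert not canny_edge_map(g).any()

    def test_vertical_step_single_line(self):
        levels = np.zeros((32, 32), dtype=int)
        levels[:, 16:] = 255
        g = GrayImage(levels, 256, 0.0, 256.0)
        edges = canny_edge_map(g, sigma=1.0)
        cols = np.unique(np.nonzero(edges)[1])
        assert 1 <= len(cols) <= 2 and all(14 <= c <= 17 for c in cols)

    def test_mouth_band_is_edge_dense_vs_cheeks(self, phantom):
        img, truth = phantom
        gray = normalize_gray(img, 256)
        mask = otsu_face_mask(gray)
        inner = morph_clean(mask.mask, 6, 0)
        edges = canny_edge_map(gray, mask=inner)
        kp = truth.keypoints
        r = kp.mouth_corner_l[0]
        band = edges[r - 10:r + 10, kp.mouth_corner_r[1]:kp.mouth_corner_l[1]]
        cheek_l = edges[kp.nostril_l[0] - 10:kp.nostril_l[0] + 10,
                        kp.mouth_corner_l[1] + 5:kp.mouth_corner_l[1] + 45]
        assert band.sum() >= 2 * max(cheek_l.sum(), 1)


class TestGrayProjection:
    def test_flat_window(self):
        g = GrayImage(np.ones((10, 10), dtype=int), 4, 0.0, 4.0)
        profile, _, _ = gray_projection(g, "cols", (0, 10, 0, 10))
        np.testing.assert_array_equal(profile, np.ones(10))

    def test_dark_column_is_global_minimum(self):
        levels = np.full((10, 20), 10)
        levels[:, 7] = 1
        g = GrayImage(levels, 16, 0.0, 16.0)
        profile, minima, _ = gray_projection(g, "cols", (0, 10, 0, 20))
        assert int(np.argmin(profile)) == 7 and 7 in minima

    def test_nostril_columns_found_on_phantom(self, phantom):
        img, truth = phantom
        gray = normalize_gray(img, 256)
        kp = truth.keypoints
        r0 = kp.nostril_l[0] - 10
        profile, minima, _ = gray_projection(
            gray, "cols", (r0, r0 + 21, kp.nostril_r[1] - 15, kp.nostril_l[1] + 16))
        offset = kp.nostril_r[1] - 15
        deepest = sorted(minima, key=lambda i: profile[i])[:2]
        found = sorted(offset + i for i in deepest)
        want = sorted([kp.nostril_r[1], kp.nostril_l[1]])
        assert all(abs(a - b) <= 2 for a, b in zip(found, want))


class TestSegmentEndToEnd:
    def test_phantom_keypoints_within_3px(self, phantom):
        img, truth = phantom
        rois = segment(img)
        errs = keypoint_errors(rois.keypoints, truth.keypoints)
        assert max(errs.values()) <= 3, errs

    def test_multi_seed_recovery(self):
        ok = 0
        for s in range(15):
            img, truth = generate_face(seed=1000 + s)
            rois = segment(img)
            if max(keypoint_errors(rois.keypoints, truth.keypoints).values()) <= 3:
                ok += 1
        assert ok >= 14

    def test_mirror_symmetric_phantom_gives_mirrored_keypoints(self, noise_free_phantom):
        img, _ = noise_free_phantom
        kp = segment(img).keypoints
        for lname, rname in kp.PAIRS:
            l, r = getattr(kp, lname), getattr(kp, rname)
            assert abs(l[0] - r[0]) <= 1
            assert abs((l[1] - kp.midline_col) - (kp.midline_col - r[1])) <= 1

    def test_missing_nostrils_raise_named_landmark_error(self):
        from thermasym.synthgen import Organ

        cfg = FacePhantomConfig()
        cfg.organs = dict(cfg.organs)
        cfg.organs["nostril"] = Organ(0.575, 0.055, 0.0, 2.5, 2.5)  # no cold blobs
        img, _ = generate_face(cfg, seed=0)
        with pytest.raises(LandmarkError) as err:
            segment(img)
        assert "nostril" in str(err.value)

    def test_deterministic(self, phantom):
        img, _ = phantom
        a, b = segment(img), segment(img)
        assert a.to_json() == b.to_json()

    def test_invariant_to_constant_temperature_offset(self, phantom):
        img, _ = phantom
        shifted = ThermalImage(img.values + 2.0, dict(img.meta))
        assert segment(img).to_json() == segment(shifted).to_json()

    def test_background_only_image_fails_loudly(self, rng):
        noise = 24.5 + 0.05 * rng.standard_normal((256, 336))
        with pytest.raises(ThermasymError):
            segment(ThermalImage(noise))


class TestROILayout:
    def test_roi_set_invariants_hold(self, phantom):
        img, _ = phantom
        rois = segment(img)
        rois.validate(shape=img.values.shape)  # count, pairing, mirror, overlap
        assert len(rois.rois) == 10 and len(rois.pairs) == 5

    def test_forehead_above_eyebrows_and_mouth_below_nostrils(self, phantom):
        img, _ = phantom
        rois = segment(img)
        kp = rois.keypoints
        brow = min(kp.eyebrow_l[0], kp.eyebrow_r[0])
        nostril = max(kp.nostril_l[0], kp.nostril_r[0])
        assert rois.rois["R1.L"].rect[1] <= brow
        assert rois.rois["R5.L"].rect[0] > nostril

    def test_translation_equivariance(self, phantom):
        img, _ = phantom
        shift = 5
        rolled = ThermalImage(np.roll(img.values, shift, axis=1), dict(img.meta))
        a, b = segment(img), segment(rolled)
        for label in a.rois:
            ra, rb = a.rois[label].rect, b.rois[label].rect
            assert (rb[0], rb[1]) == (ra[0], ra[1])
            assert rb[2] - ra[2] == shift and rb[3] - ra[3] == shift

    def test_json_roundtrip(self, phantom, tmp_path):
        img, _ = phantom
        rois = segment(img)
        p = tmp_path / "rois.json"
        rois.to_json(p)
        back = seg.FacialROISet.from_json(p)
        assert back.midline_col == rois.midline_col
        assert {k: v.rect for k, v in back.rois.items()} == \
               {k: v.rect for k, v in rois.rois.items()}
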