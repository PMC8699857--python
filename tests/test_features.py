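"""Temperature features and GLCM texture statistics."""

import numpy as np
import pytest

from thermasym.errors import SizeError
from thermasym.features import (
    DELTAS,
    GRAY_LEVELS,
    THETAS,
    THETA_OFFSETS,
    GLCMParams,
    all_texture_features,
    compute_glcm,
    param_grid,
    quantize_roi,
    temperature_features,
    texture_stats,
)
from thermasym.thermal_io import normalize_gray


def brute_force_glcm(levels, delta, theta, g):
    """Exhaustive double loop over all ordered pixel pairs."""
    dr, dc = (o * delta for o in THETA_OFFSETS[theta])
    counts = np.zeros((g, g))
    rows, cols = levels.shape
    for r in range(rows):
        for c in range(cols):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                counts[levels[r, c], levels[rr, cc]] += 1
    return counts / counts.sum()


class TestTemperatureFeatures:
    def test_1_to_20_forced_by_definition(self):
        f = temperature_features(np.arange(1.0, 21.0))
        assert (f.t_mean, f.t_max, f.t_min, f.m) == (10.5, 20.0, 1.0, 1)

    def test_constant_roi(self):
        f = temperature_features(np.full(40, 33.0))
        assert f.t_mean == f.t_max == f.t_min == 33.0

    def test_matches_sort_and_slice_oracle(self, rng):
        values = rng.uniform(25, 35, size=40)
        f = temperature_features(values)
        srt = sorted(values)
        m = int(np.ceil(0.05 * 40))
        assert f.t_min == pytest.approx(np.mean(srt[:m]))
        assert f.t_max == pytest.approx(np.mean(srt[-m:]))
        assert f.t_mean == pytest.approx(np.mean(values))

    def test_pixel_order_invariant(self, rng):
        values = rng.uniform(25, 35, size=64)
        a = temperature_features(values)
        b = temperature_features(values[rng.permutation(64)])
        assert (a.t_mean, a.t_max, a.t_min) == (b.t_mean, b.t_max, b.t_min)

    def test_tail_size_is_ceil_of_5_percent(self):
        assert temperature_features(np.arange(21.0, 41.0)).m == 1
        assert temperature_features(np.arange(1.0, 42.0)).m == 3  # ceil(2.05)

    def test_too_small_roi_rejected(self):
        with pytest.raises(SizeError):
            temperature_features(np.arange(10.0))

    def test_ordering_invariant_fuzz(self, rng):
        for _ in range(200):
            f = temperature_features(rng.uniform(20, 40, size=rng.integers(20, 100)))
            assert f.t_min <= f.t_mean <= f.t_max


class TestQuantizeROI:
    def test_ramp_spans_levels(self, rng):
        roi = np.linspace(30, 34, 64).reshape(8, 8)
        g = quantize_roi(roi, 16)
        assert g.levels.min() == 0 and g.levels.max() == 15

    def test_constant_roi_degenerate(self):
        g = quantize_roi(np.full((8, 8), 33.0), 16)
        assert g.degenerate and not g.levels.any()

    def test_equals_normalize_gray_on_roi_range(self, rng):
        roi = rng.uniform(29, 35, size=(12, 12))
        a = quantize_roi(roi, 32)
        b = normalize_gray(roi, 32, (roi.min(), roi.max()))
        np.testing.assert_array_equal(a.levels, b.levels)


class TestGLCM:
    def test_constant_roi_all_mass_on_one_cell(self):
        g = quantize_roi(np.full((10, 10), 31.0), 16)
        glcm = compute_glcm(g, GLCMParams(2, 0, 16))
        assert glcm.p[0, 0] == 1.0 and glcm.p.sum() == 1.0

    def test_checkerboard_period2_diagonal(self):
        levels = np.indices((10, 10)).sum(axis=0) % 2
        from thermasym.thermal_io import GrayImage

        g = GrayImage(levels, 2, 0.0, 1.0)
        glcm = compute_glcm(g, GLCMParams(2, 0, 2))
        assert glcm.p[0, 0] + glcm.p[1, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_pair_count_all_grid_members(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 8, size=(8, 8))
        from thermasym.thermal_io import GrayImage

        g = GrayImage(levels, 8, 0.0, 8.0)
        for delta in DELTAS:
            for theta in THETAS:
                glcm = compute_glcm(g, GLCMParams(delta, theta, 8))
                np.testing.assert_allclose(
                    glcm.p, brute_force_glcm(levels, delta, theta, 8), atol=1e-12)

    def test_matches_skimage_graycomatrix(self, rng):
        """Independent library cross-check.  skimage's angle runs the row
        offset the other way (our theta maps to -theta) and its distance is
        Euclidean along the offset, so diagonal directions need d*sqrt(2)
        to land on the same (delta, delta) pixel offset."""
        from skimage.feature import graycomatrix

        from thermasym.thermal_io import GrayImage

        levels = rng.integers(0, 16, size=(12, 12))
        g = GrayImage(levels, 16, 0.0, 16.0)
        for theta in THETAS:
            ours = compute_glcm(g, GLCMParams(2, theta, 16))
            d = 2 * np.sqrt(2) if theta in (45, 135) else 2
            ref = graycomatrix(levels.astype(np.uint8), [d],
                               [-np.deg2rad(theta)], levels=16, normed=True)
            np.testing.assert_allclose(ours.p, ref[:, :, 0, 0], atol=1e-12)

    def test_mass_is_one_fuzz(self, rng):
        from thermasym.thermal_io import GrayImage

        for _ in range(300):
            levels = rng.integers(0, 16, size=(8, 8))
            params = GLCMParams(int(rng.choice(DELTAS)), int(rng.choice(THETAS)),
                                16)
            glcm = compute_glcm(GrayImage(levels, 16, 0.0, 16.0), params)
            assert glcm.p.sum() == pytest.approx(1.0, abs=1e-9)
            assert (glcm.p >= 0).all()

    def test_roi_smaller_than_offset_rejected(self):
        g = quantize_roi(np.linspace(30, 31, 16).reshape(4, 4), 16)
        with pytest.raises(SizeError):
            compute_glcm(g, GLCMParams(5, 0, 16))


class TestTextureStats:
    def test_single_entry_glcm(self):
        from thermasym.features import GLCM

        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        t = texture_stats(GLCM(p, 10, GLCMParams(2, 0, 4)))
        assert (t.energy, t.contrast, t.homogeneity, t.correlation) == (1.0, 0.0, 1.0, 0.0)

    def test_two_entry_antidiagonal_closed_form(self):
        from thermasym.features import GLCM

        p = np.zeros((2, 2))
        p[0, 1] = p[1, 0] = 0.5
        t = texture_stats(GLCM(p, 10, GLCMParams(2, 0, 2)))
        assert t.contrast == pytest.approx(1.0)
        assert t.energy == pytest.approx(0.5)
        assert t.homogeneity == pytest.approx(0.5)
        assert t.correlation == pytest.approx(-1.0)

    def test_matches_direct_summation_oracle(self, rng):
        from thermasym.features import GLCM

        raw = rng.random((8, 8))
        p = raw / raw.sum()
        t = texture_stats(GLCM(p, 100, GLCMParams(2, 0, 8)))
        contrast = sum((i - j) ** 2 * p[i, j] for i in range(8) for j in range(8))
        energy = sum(p[i, j] ** 2 for i in range(8) for j in range(8))
        homog = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(8) for j in range(8))
        mx = sum(i * p[i, j] for i in range(8) for j in range(8))
        my = sum(j * p[i, j] for i in range(8) for j in range(8))
        sx = np.sqrt(sum((i - mx) ** 2 * p[i, j] for i in range(8) for j in range(8)))
        sy = np.sqrt(sum((j - my) ** 2 * p[i, j] for i in range(8) for j in range(8)))
        corr = (sum(i * j * p[i, j] for i in range(8) for j in range(8)) - mx * my) / (sx * sy)
        assert t.contrast == pytest.approx(contrast, abs=1e-12)
        assert t.energy == pytest.approx(energy, abs=1e-12)
        assert t.homogeneity == pytest.approx(homog, abs=1e-12)
        assert t.correlation == pytest.approx(corr, abs=1e-12)

    def test_matches_skimage_graycoprops(self, rng):
        """Cross-check against the library's texture properties (its
        'energy' is sqrt(ASM), hence the square)."""
        from skimage.feature import graycomatrix, graycoprops

        levels = rng.integers(0, 8, size=(10, 10)).astype(np.uint8)
        ref = graycomatrix(levels, [1], [0.0], levels=8, normed=True)
        from thermasym.features import GLCM

        t = texture_stats(GLCM(ref[:, :, 0, 0], 90, GLCMParams(1, 0, 8)))
        assert t.contrast == pytest.approx(graycoprops(ref, "contrast")[0, 0])
        assert t.energy == pytest.approx(graycoprops(ref, "energy")[0, 0] ** 2)
        assert t.homogeneity == pytest.approx(graycoprops(ref, "homogeneity")[0, 0])
        assert t.correlation == pytest.approx(graycoprops(ref, "correlation")[0, 0])


class TestAllTextureFeatures:
    def test_exactly_16_grid_members_in_order(self, rng):
        roi = rng.uniform(29, 35, size=(16, 16))
        feats = all_texture_features(roi)
        assert len(feats) == 16
        assert [f.params for f in feats] == param_grid()
        assert len(param_grid()) == len(DELTAS) * len(GRAY_LEVELS) * len(THETAS)

    def test_constant_roi_energy_one_contrast_zero(self):
        feats = all_texture_features(np.full((16, 16), 33.0))
        assert all(f.energy == 1.0 and f.contrast == 0.0 for f in feats)

    def test_transpose_direction_mapping(self, rng):
        """Transposing the ROI maps the ordered-offset directions as
        0 <-> 90 (GLCMs transpose into each other) while 45 and 135 map to
        themselves (their pair sets reverse or are preserved); since all
        four statistics are transpose-invariant, the per-direction values
        follow that mapping exactly."""
        roi = rng.uniform(29, 35, size=(14, 14))
        a = {(f.params.delta, f.params.g, f.params.theta): f
             for f in all_texture_features(roi)}
        b = {(f.params.delta, f.params.g, f.params.theta): f
             for f in all_texture_features(roi.T)}
        mapping = {0: 90, 90: 0, 45: 45, 135: 135}
        for (d, g, t), fa in a.items():
            fb = b[(d, g, mapping[t])]
            assert fa.contrast == pytest.approx(fb.contrast, abs=1e-9)
            assert fa.energy == pytest.approx(fb.energy, abs=1e-9)
            assert fa.homogeneity == pytest.approx(fb.homogeneity, abs=1e-9)
            assert fa.correlation == pytest.approx(fb.correlation, abs=1e-9)

    def test_constant_shift_leaves_texture_unchanged(self, rng):
        roi = rng.uniform(29, 35, size=(16, 16))
        a = all_texture_features(roi)
        b = all_texture_features(roi + 1.75)
        for fa, fb in zip(a, b):
            assert fa.energy == pytest.approx(fb.energy, abs=1e-12)
            assert fa.contrast == pytest.approx(fb.contrast, abs=1e-12)
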