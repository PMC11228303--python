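"""Radiomics tests: quantization, first-order/gradient statistics, and the
GLCM/GLRLM/GLSZM builders against independent brute-force oracles."""

import numpy as np
import pytest

from fusionrad import radiomics as rad
from fusionrad.synthetic import PhantomSpec, generate_phantoms

from conftest import random_quantized
from _oracles import glcm_bruteforce, glrlm_bruteforce, glszm_bruteforce


class TestQuantize:
    def test_equal_width_forced(self):
        img = np.array([[0.0, 1.0], [2.0, 3.0]])
        q = rad.quantize(img, np.ones_like(img, bool), 4)
        np.testing.assert_array_equal(q.levels, [[1, 2], [3, 4]])

    def test_constant_roi_warns(self):
        img = np.full((3, 3), 2.0)
        with pytest.warns(UserWarning):
            q = rad.quantize(img, np.ones_like(img, bool), 8)
        assert (q.levels == 1).all()

    def test_affine_invariance(self, rng):
        img = rng.normal(size=(6, 6))
        roi = rng.random((6, 6)) < 0.8
        roi[0, 0] = True
        a = rad.quantize(img, roi, 8).levels
        b = rad.quantize(2 * img + 5, roi, 8).levels
        np.testing.assert_array_equal(a, b)

    def test_monotone(self, rng):
        img = rng.normal(size=(8, 8))
        roi = np.ones((8, 8), bool)
        q = rad.quantize(img, roi, 5)
        order = np.argsort(img.ravel())
        assert (np.diff(q.levels.ravel()[order]) >= 0).all()

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            rad.quantize(np.zeros((3, 3)), np.zeros((3, 3), bool), 4)


class TestFirstOrder:
    def test_symmetric_skewness_zero(self):
        feats, _ = rad.first_order_features([0, 0, 1, 1])
        assert feats["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_kurtosis_hand_value(self):
        # adjusted Fisher-Pearson with n=4 and z = +/- (1/2)/sqrt(1/3):
        # n(n+1)/((n-1)(n-2)(n-3)) * sum z^4 - 3(n-1)^2/((n-2)(n-3)) = -6
        feats, _ = rad.first_order_features([0, 0, 1, 1])
        assert feats["kurtosis"] == pytest.approx(-6.0, abs=1e-12)

    def test_uniform_histogram_entropy(self):
        ng = 8
        values = np.repeat(np.arange(1, ng + 1), 5)
        feats, _ = rad.first_order_features(values, n_bins=ng)
        assert feats["entropy"] == pytest.approx(np.log2(ng), abs=1e-12)
        assert feats["energy"] == pytest.approx(1.0 / ng, abs=1e-12)

    def test_constant_input_imputed(self):
        feats, flags = rad.first_order_features([3.0, 3.0, 3.0, 3.0])
        assert feats["skewness"] == 0.0 and feats["kurtosis"] == 0.0
        assert "skewness" in flags and "kurtosis" in flags
        assert feats["energy"] == 1.0 and feats["entropy"] == 0.0

    def test_basic_statistics(self, rng):
        v = rng.normal(size=200)
        feats, _ = rad.first_order_features(v)
        assert feats["mean"] == pytest.approx(v.mean())
        assert feats["variance"] == pytest.approx(v.var(ddof=1))
        assert feats["p50"] == pytest.approx(np.percentile(v, 50))


class TestGradient:
    def test_constant_image_zero(self):
        img = np.full((5, 5), 2.0)
        feats, flags = rad.gradient_features(img, np.ones((5, 5), bool))
        assert feats["mean"] == 0.0 and feats["variance"] == 0.0
        assert feats["skewness"] == 0.0 and feats["kurtosis"] == 0.0
        assert flags  # degenerate flagged

    def test_ramp_gradient_one(self):
        img = np.tile(np.arange(5.0), (5, 1))
        feats, _ = rad.gradient_features(img, np.ones((5, 5), bool))
        assert feats["mean"] == pytest.approx(1.0)
        assert feats["variance"] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_rougher_than_smoothed(self):
        from scipy.ndimage import median_filter
        board = np.indices((12, 12)).sum(axis=0) % 2 * 1.0
        smooth = median_filter(board, size=3)
        roi = np.ones((12, 12), bool)
        rough, _ = rad.gradient_features(board, roi)
        smoothed, _ = rad.gradient_features(smooth, roi)
        assert rough["mean"] > smoothed["mean"]


class TestGLCM:
    def test_tiny_example(self):
        q = rad.QuantizedImage(levels=np.array([[1, 1], [1, 2]]), ng=2,
                               roi=np.ones((2, 2), bool),
                               original=np.array([[1.0, 1.0], [1.0, 2.0]]))
        m = rad.glcm(q, distance=1, direction=(0, 1), symmetric=True)
        assert m.counts[0, 0] == 2 and m.counts[0, 1] == 1 and m.counts[1, 0] == 1
        assert m.counts.sum() == 4

    def test_constant_image_diagonal(self, rng):
        with pytest.warns(UserWarning):
            q = rad.quantize(np.full((4, 4), 1.0), np.ones((4, 4), bool), 4)
        m = rad.glcm(q)
        nz = np.nonzero(m.counts)
        assert nz[0].tolist() == [0] and nz[1].tolist() == [0]

    @pytest.mark.parametrize("direction", rad.DIRECTIONS_2D)
    def test_matches_bruteforce_all_angles(self, rng, direction):
        for _ in range(50):
            q = random_quantized(rng, shape=(8, 8), ng=4,
                                 roi_prob=float(rng.uniform(0.5, 1.0)))
            m = rad.glcm(q, distance=1, direction=direction)
            np.testing.assert_array_equal(
                m.counts, glcm_bruteforce(q.levels, 4, direction))

    def test_symmetric_and_normalized(self, rng):
        q = random_quantized(rng, shape=(10, 10), ng=5)
        m = rad.glcm(q).normalize()
        np.testing.assert_array_equal(m.counts, m.counts.T)
        assert m.counts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_skimage(self, rng):
        # independent cross-check against scikit-image's implementation
        from skimage.feature import graycomatrix
        img = rng.integers(0, 4, size=(12, 12)).astype(np.uint8)
        q = rad.QuantizedImage(levels=img + 1, ng=4,
                               roi=np.ones(img.shape, bool),
                               original=img.astype(float))
        mine = rad.glcm(q, distance=1, direction=(0, 1), symmetric=True)
        theirs = graycomatrix(img, [1], [0], levels=4, symmetric=True)[:, :, 0, 0]
        np.testing.assert_array_equal(mine.counts, theirs)


class TestGLCMFeatures:
    def test_constant_image(self, rng):
        with pytest.warns(UserWarning):
            q = rad.quantize(np.full((5, 5), 3.0), np.ones((5, 5), bool), 4)
        f = rad.glcm_features(rad.glcm(q).normalize())
        assert f["contrast"] == 0.0 and f["energy"] == 1.0 and f["entropy"] == 0.0

    def test_uniform_distribution_entropy(self):
        ng = 4
        m = rad.TextureMatrix(kind="GLCM", counts=np.full((ng, ng), 1.0 / ng**2),
                              normalized=True)
        assert rad.glcm_features(m)["entropy"] == pytest.approx(2 * np.log2(ng))

    def test_checkerboard_contrast_one(self):
        board = (np.indices((8, 8)).sum(axis=0) % 2) + 1
        q = rad.QuantizedImage(levels=board, ng=2, roi=np.ones((8, 8), bool),
                               original=board.astype(float))
        f = rad.glcm_features(rad.glcm(q, direction=(0, 1)).normalize())
        assert f["contrast"] == pytest.approx(1.0)

    def test_unnormalized_rejected(self, rng):
        q = random_quantized(rng)
        with pytest.raises(ValueError):
            rad.glcm_features(rad.glcm(q))


class TestGLRLM:
    def test_row_example(self):
        levels = np.array([[1, 1, 2, 2, 2]])
        q = rad.QuantizedImage(levels=levels, ng=2, roi=levels > 0,
                               original=levels.astype(float))
        m = rad.glrlm(q, direction=(0, 1))
        assert m.counts[0, 1] == 1  # level 1, length 2
        assert m.counts[1, 2] == 1  # level 2, length 3
        assert m.counts.sum() == 2

    @pytest.mark.parametrize("direction", rad.DIRECTIONS_2D)
    def test_matches_bruteforce(self, rng, direction):
        for _ in range(50):
            q = random_quantized(rng, shape=(8, 8), ng=4,
                                 roi_prob=float(rng.uniform(0.5, 1.0)))
            m = rad.glrlm(q, direction=direction)
            expected = glrlm_bruteforce(q.levels, 4, direction)
            got = {(i + 1, l + 1): int(c) for (i, l), c in np.ndenumerate(m.counts)
                   if c > 0}
            assert got == expected

    def test_voxel_conservation(self, rng):
        for direction in rad.DIRECTIONS_2D:
            q = random_quantized(rng, shape=(9, 9), ng=3, roi_prob=0.7)
            m = rad.glrlm(q, direction=direction)
            lengths = np.arange(1, m.counts.shape[1] + 1)
            assert (m.counts * lengths).sum() == q.n_roi


class TestGLRLMFeatures:
    def test_all_runs_length_one(self):
        counts = np.zeros((2, 1))
        counts[0, 0], counts[1, 0] = 3, 2
        m = rad.TextureMatrix(kind="GLRLM", counts=counts)
        f = rad.glrlm_features(m, n_voxels=5)
        assert f["sre"] == 1.0 and f["run_fraction"] == 1.0

    def test_single_long_run(self):
        counts = np.zeros((1, 7))
        counts[0, 6] = 1
        f = rad.glrlm_features(rad.TextureMatrix(kind="GLRLM", counts=counts),
                               n_voxels=7)
        assert f["lre"] == 49.0

    def test_sre_lre_bounds(self, rng):
        for _ in range(100):
            q = random_quantized(rng, shape=(7, 7),
                                 ng=int(rng.integers(2, 6)))
            f = rad.glrlm_features(rad.glrlm(q, direction=(1, 0)), q.n_roi)
            assert f["sre"] <= 1.0 + 1e-12
            assert f["lre"] >= 1.0 - 1e-12


class TestGLSZM:
    def test_tiny_example(self):
        levels = np.array([[1, 1], [1, 2]])
        q = rad.QuantizedImage(levels=levels, ng=2, roi=levels > 0,
                               original=levels.astype(float))
        m = rad.glszm(q)
        assert m.counts[0, 2] == 1  # level 1, size 3
        assert m.counts[1, 0] == 1  # level 2, size 1

    def test_diagonal_single_zone(self):
        levels = np.diag([2, 2, 2, 2])
        q = rad.QuantizedImage(levels=levels, ng=2, roi=levels > 0,
                               original=levels.astype(float))
        m = rad.glszm(q)
        assert m.counts[1, 3] == 1 and m.counts.sum() == 1

    def test_matches_bruteforce(self, rng):
        for _ in range(50):
            q = random_quantized(rng, shape=(8, 8), ng=4,
                                 roi_prob=float(rng.uniform(0.5, 1.0)))
            m = rad.glszm(q)
            got = {(i + 1, s + 1): int(c) for (i, s), c in np.ndenumerate(m.counts)
                   if c > 0}
            assert got == glszm_bruteforce(q.levels)

    def test_voxel_conservation(self, rng):
        q = random_quantized(rng, shape=(10, 10), ng=4, roi_prob=0.6)
        m = rad.glszm(q)
        sizes = np.arange(1, m.counts.shape[1] + 1)
        assert (m.counts * sizes).sum() == q.n_roi

    def test_features_from_oracle_matrix(self, rng):
        for _ in range(50):
            q = random_quantized(rng, shape=(6, 6), ng=3)
            zones = glszm_bruteforce(q.levels)
            smax = max(s for _, s in zones)
            counts = np.zeros((3, smax))
            for (lev, s), c in zones.items():
                counts[lev - 1, s - 1] = c
            f_oracle = rad.glszm_features(
                rad.TextureMatrix(kind="GLSZM", counts=counts), q.n_roi)
            f_mine = rad.glszm_features(rad.glszm(q), q.n_roi)
            assert f_mine == pytest.approx(f_oracle)

    def test_all_zones_size_one(self):
        levels = np.array([[1, 2], [2, 1]])
        q = rad.QuantizedImage(levels=levels, ng=2, roi=levels > 0,
                               original=levels.astype(float))
        # 8-connectivity joins the two 1s and the two 2s diagonally: zones of
        # size 2, so zone percentage is 2/4
        f = rad.glszm_features(rad.glszm(q), 4)
        assert f["zone_percentage"] == pytest.approx(0.5)


class TestExtraction:
    def test_deterministic_and_fixed_length(self, phantoms_2d):
        s = phantoms_2d[0]
        v1 = rad.extract_radiomics(s)
        v2 = rad.extract_radiomics(s)
        np.testing.assert_array_equal(v1.values, v2.values)
        assert len(v1.names) == len(v1.values) == 29 * s.image.shape[0]

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        img = np.zeros((16, 16))
        patch = rng.normal(size=(6, 6))
        roi = np.zeros((16, 16), bool)

        class S:
            pass

        vecs = []
        for (r, c) in [(2, 2), (7, 6)]:
            img2, roi2 = np.zeros_like(img), np.zeros_like(roi)
            img2[r:r + 6, c:c + 6] = patch
            roi2[r:r + 6, c:c + 6] = True
            s = S()
            s.image, s.mask = img2[None], roi2
            vecs.append(rad.extract_radiomics(s, rad.RadiomicsConfig(ng=8)).values)
        np.testing.assert_allclose(vecs[0], vecs[1])

    def test_rotation_invariance_direction_averaged(self):
        rng = np.random.default_rng(4)
        patch = rng.normal(size=(10, 10))

        class S:
            pass

        vecs = []
        for k in (0, 1):
            s = S()
            s.image = np.rot90(patch, k=k).copy()[None]
            s.mask = np.ones((10, 10), bool)
            v = rad.extract_radiomics(s, rad.RadiomicsConfig(ng=8))
            vecs.append(dict(zip(v.names, v.values)))
        # direction-averaged texture features are 90-degree rotation invariant
        for key in vecs[0]:
            if "glcm" in key or "glrlm" in key or "glszm" in key:
                assert vecs[0][key] == pytest.approx(vecs[1][key]), key

    def test_classes_differ_in_glcm_contrast(self):
        from scipy.stats import mannwhitneyu
        spec = PhantomSpec(n_samples=100, shape=(32, 32), n_channels=1,
                           separability=1.0, seed=21)
        samples = generate_phantoms(spec)
        table = rad.radiomics_table(samples, rad.RadiomicsConfig(ng=16))
        c0 = table.loc[table.label == 0, "ch0_glcm_contrast"]
        c1 = table.loc[table.label == 1, "ch0_glcm_contrast"]
        assert mannwhitneyu(c0, c1).pvalue < 0.01

    def test_extractor_sklearn_protocol(self, phantoms_2d):
        ext = rad.RadiomicsExtractor(ng=8)
        assert ext.get_params()["ng"] == 8
        X = ext.fit_transform(phantoms_2d)
        assert X.shape == (len(phantoms_2d), len(ext.feature_names_))
        ext.set_params(ng=16)
        assert ext.get_params()["ng"] == 16

    def test_3d_mode(self, phantoms_3d):
        v = rad.extract_radiomics(phantoms_3d[0], rad.RadiomicsConfig(ng=8, mode="3d"))
        assert np.isfinite(v.values).all()
        assert len(v.values) == 29 * 4
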