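import math

import numpy as np
import pytest

import stroketex as st
from stroketex.glcm import FEATURE_REGISTRY
from stroketex.preprocess import ValidationError


def qimg(arr, levels):
    """Quantized GrayImage from a raw integer-level array (bypasses size floor)."""
    img = st.GrayImage.__new__(st.GrayImage)
    img.pixels = np.asarray(arr, dtype=np.int64)
    img.levels = levels
    return img


class TestQuantize:
    def test_constant_half_lands_in_middle_bin(self):
        img = st.GrayImage(np.full((8, 8), 0.5))
        q = st.quantize(img, 8)
        assert q.levels == 8
        assert np.all(q.pixels == 4)

    def test_endpoints_map_to_extreme_bins(self):
        arr = np.zeros((8, 8))
        arr[:, 4:] = 1.0
        q = st.quantize(st.GrayImage(arr), 2)
        assert set(np.unique(q.pixels)) == {0, 1}

    def test_linear_ramp_fills_bins_evenly(self):
        ramp = np.linspace(0, 1, 64).reshape(8, 8)
        q = st.quantize(st.GrayImage(ramp), 8)
        counts = np.bincount(q.pixels.ravel(), minlength=8)
        assert list(counts) == [8] * 8


class TestGLCMMatrix:
    def test_constant_image_point_mass(self):
        q = st.quantize(st.GrayImage(np.full((8, 8), 0.5)), 8)
        M = st.glcm_matrix(q)
        assert M.P[4, 4] == pytest.approx(1.0)
        assert M.P.sum() == pytest.approx(1.0)

    def test_two_column_fixture_by_hand(self):
        # [[0,1],[0,1]]: two horizontal pairs (0,1); symmetric counts split 50/50
        q = qimg([[0, 1], [0, 1]], 2)
        M = st.glcm_matrix(q, distance=1, angles=(0,))
        assert M.P[0, 1] == pytest.approx(0.5)
        assert M.P[1, 0] == pytest.approx(0.5)
        assert M.P[0, 0] == M.P[1, 1] == 0.0

    def test_normalization_and_symmetry(self, noise_image):
        q = st.quantize(noise_image, 8)
        M = st.glcm_matrix(q)
        assert abs(M.P.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(M.P, M.P.T, atol=1e-15)

    def test_continuous_image_rejected(self, noise_image):
        with pytest.raises(ValidationError):
            st.glcm_matrix(noise_image)


def brute_force_features(P):
    """Independent plain-loop evaluation of the co-occurrence features."""
    L = len(P)
    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    py = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mux = sum(i * px[i] for i in range(L))
    muy = sum(j * py[j] for j in range(L))
    psum = [0.0] * (2 * L - 1)
    pdiff = [0.0] * L
    for i in range(L):
        for j in range(L):
            psum[i + j] += P[i][j]
            pdiff[abs(i - j)] += P[i][j]

    def H(dist):
        return -sum(p * math.log(p) for p in dist if p > 0)

    out = {}
    out["autocorrelation"] = sum(i * j * P[i][j] for i in range(L) for j in range(L))
    out["max_probability"] = max(P[i][j] for i in range(L) for j in range(L))
    out["dissimilarity"] = sum(abs(i - j) * P[i][j] for i in range(L) for j in range(L))
    out["entropy"] = H([P[i][j] for i in range(L) for j in range(L)])
    out["cluster_shade"] = sum((i + j - mux - muy) ** 3 * P[i][j]
                               for i in range(L) for j in range(L))
    out["cluster_prominence"] = sum((i + j - mux - muy) ** 4 * P[i][j]
                                    for i in range(L) for j in range(L))
    out["homogeneity"] = sum(P[i][j] / (1 + (i - j) ** 2)
                             for i in range(L) for j in range(L))
    out["contrast"] = sum((i - j) ** 2 * P[i][j] for i in range(L) for j in range(L))
    out["sum_average"] = sum(k * psum[k] for k in range(2 * L - 1))
    se = H(psum)
    out["sum_entropy"] = se
    out["sum_variance"] = sum((k - se) ** 2 * psum[k] for k in range(2 * L - 1))
    mud = sum(k * pdiff[k] for k in range(L))
    out["difference_variance"] = sum((k - mud) ** 2 * pdiff[k] for k in range(L))
    out["difference_entropy"] = H(pdiff)
    hxy = out["entropy"]
    hxy1 = -sum(P[i][j] * math.log(px[i] * py[j])
                for i in range(L) for j in range(L)
                if P[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = H([px[i] * py[j] for i in range(L) for j in range(L)])
    hx, hy = H(px), H(py)
    out["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    return out


class TestGLCMFeatures:
    def test_point_mass_distribution(self):
        c = 3
        P = np.zeros((8, 8))
        P[c, c] = 1.0
        M = st.GLCMatrix(P, 8, ((0, 1),))
        feats = st.glcm_feature_set(M, feature_set=tuple(FEATURE_REGISTRY)).as_dict()
        assert feats["glcm_max_probability"] == pytest.approx(1.0)
        assert feats["glcm_entropy"] == pytest.approx(0.0)
        assert feats["glcm_dissimilarity"] == pytest.approx(0.0)
        assert feats["glcm_contrast"] == pytest.approx(0.0)
        assert feats["glcm_homogeneity"] == pytest.approx(1.0)
        assert feats["glcm_autocorrelation"] == pytest.approx(c * c)

    def test_uniform_two_level_matrix_closed_form(self):
        M = st.GLCMatrix(np.full((2, 2), 0.25), 2, ((0, 1),))
        feats = st.glcm_feature_set(M).as_dict()
        assert feats["glcm_entropy"] == pytest.approx(2 * math.log(2), abs=1e-12)
        assert feats["glcm_max_probability"] == pytest.approx(0.25)

    def test_two_column_fixture_hand_values(self):
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.5
        M = st.GLCMatrix(P, 2, ((0, 1),))
        feats = st.glcm_feature_set(M, feature_set=tuple(FEATURE_REGISTRY)).as_dict()
        assert feats["glcm_dissimilarity"] == pytest.approx(1.0)
        assert feats["glcm_contrast"] == pytest.approx(1.0)
        assert np.isfinite(feats["glcm_imc1"])
        assert np.isfinite(feats["glcm_imc2"])

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(10):
            arr = rng.integers(0, 4, size=(6, 6))
            M = st.glcm_matrix(qimg(arr, 4))
            feats = st.glcm_feature_set(M, feature_set=tuple(FEATURE_REGISTRY)).as_dict()
            oracle = brute_force_features(M.P.tolist())
            for name, expected in oracle.items():
                assert feats[f"glcm_{name}"] == pytest.approx(expected, abs=1e-10), name

    def test_default_set_is_fourteen_with_stable_names(self, noise_image):
        q = st.quantize(noise_image, 8)
        blk = st.glcm_feature_set(st.glcm_matrix(q))
        assert len(blk.names) == 14
        assert blk.names == list(st.glcm_feature_set(st.glcm_matrix(q)).names)

    def test_feature_ranges(self, rng):
        for _ in range(5):
            arr = rng.integers(0, 8, size=(12, 12))
            feats = st.glcm_feature_set(st.glcm_matrix(qimg(arr, 8))).as_dict()
            assert feats["glcm_entropy"] >= 0
            assert feats["glcm_sum_entropy"] >= 0
            assert feats["glcm_difference_entropy"] >= 0
            assert 0 < feats["glcm_max_probability"] <= 1
            assert 0 <= feats["glcm_imc2"] <= 1
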