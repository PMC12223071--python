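"""GLCM texture, first-order statistics, pooling and fusion."""

import numpy as np
import pytest
from scipy import stats as sps

from fedcaps.features import (
    GLCM,
    FeatureVector,
    compute_glcm,
    extract_handcrafted,
    first_order_stats,
    fuse_features,
    gap_pool,
    glcm_contrast,
    glcm_correlation,
    glcm_energy,
    glcm_homogeneity,
    quantize_roi,
)


def brute_force_glcm(image, roi, levels, offset, symmetric):
    """Pair-enumeration oracle: explicit double loop over all pixels."""
    q = quantize_roi(image, roi, levels)
    dr, dc = offset
    H, W = q.shape
    counts = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and q[r, c] >= 0 and q[r2, c2] >= 0:
                counts[q[r, c], q[r2, c2]] += 1
                if symmetric:
                    counts[q[r2, c2], q[r, c]] += 1
    return counts / counts.sum()


def brute_force_features(P):
    """Scalar texture features by explicit summation."""
    n = P.shape[0]
    contrast = sum(P[i, j] * (i - j) ** 2 for i in range(n) for j in range(n))
    energy = sum(P[i, j] ** 2 for i in range(n) for j in range(n))
    homog = sum(P[i, j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    mu_i = sum(P[i, j] * i for i in range(n) for j in range(n))
    mu_j = sum(P[i, j] * j for i in range(n) for j in range(n))
    si = np.sqrt(sum(P[i, j] * (i - mu_i) ** 2 for i in range(n) for j in range(n)))
    sj = np.sqrt(sum(P[i, j] * (j - mu_j) ** 2 for i in range(n) for j in range(n)))
    corr = sum(
        P[i, j] * (i - mu_i) * (j - mu_j) for i in range(n) for j in range(n)
    ) / (si * sj)
    return contrast, energy, homog, corr


def toy_glcm(entries, levels=2):
    P = np.zeros((levels, levels))
    for (i, j), v in entries.items():
        P[i, j] = v
    g = GLCM(P=P, levels=levels, offset=(0, 1))
    g.validate()
    return g


class TestComputeGLCM:
    def test_horizontal_pairs_on_two_rows(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        g = compute_glcm(img, levels=2, offset=(0, 1), symmetric=False)
        assert g.P[0, 0] == pytest.approx(0.5)
        assert g.P[1, 1] == pytest.approx(0.5)

    def test_vertical_stripes_all_cross_pairs(self):
        img = np.array([[0.0, 1.0], [0.0, 1.0]])
        g = compute_glcm(img, levels=2, offset=(0, 1), symmetric=False)
        assert g.P[0, 1] == pytest.approx(1.0)

    def test_constant_roi_single_entry(self):
        img = np.full((4, 4), 0.3)
        g = compute_glcm(img, levels=4, offset=(0, 1), symmetric=False)
        assert g.P[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("symmetric", [False, True])
    @pytest.mark.parametrize("offset", [(0, 1), (1, 0), (1, 1)])
    def test_matches_pair_enumeration_oracle(self, rng, offset, symmetric):
        for _ in range(5):
            img = rng.uniform(size=(16, 16))
            roi = rng.uniform(size=(16, 16)) > 0.3
            P = compute_glcm(img, roi, levels=8, offset=offset,
                             symmetric=symmetric).P
            expected = brute_force_glcm(img, roi, 8, offset, symmetric)
            assert np.allclose(P, expected)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestGLCMFeatures:
    def test_diagonal_glcm(self):
        g = toy_glcm({(0, 0): 0.5, (1, 1): 0.5})
        assert glcm_contrast(g) == 0.0
        assert glcm_energy(g) == pytest.approx(0.5)
        assert glcm_homogeneity(g) == pytest.approx(1.0)
        assert glcm_correlation(g) == pytest.approx(1.0)

    def test_single_offdiagonal_entry(self):
        g = toy_glcm({(0, 1): 1.0})
        assert glcm_contrast(g) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            glcm_correlation(g)  # zero marginal variance
        assert glcm_homogeneity(g) == pytest.approx(0.5)
        assert glcm_energy(g) == pytest.approx(1.0)

    def test_antidiagonal_correlation_minus_one(self):
        g = toy_glcm({(0, 1): 0.5, (1, 0): 0.5})
        assert glcm_correlation(g) == pytest.approx(-1.0)

    def test_uniform_glcm_energy(self):
        n = 4
        g = GLCM(P=np.full((n, n), 1 / n**2), levels=n, offset=(0, 1))
        assert glcm_energy(g) == pytest.approx(1 / n**2)

    def test_features_match_oracle_on_random_images(self, rng):
        for _ in range(5):
            img = rng.uniform(size=(16, 16))
            g = compute_glcm(img, levels=8, offset=(0, 1))
            c, e, h, r = brute_force_features(g.P)
            assert glcm_contrast(g) == pytest.approx(c, abs=1e-12)
            assert glcm_energy(g) == pytest.approx(e, abs=1e-12)
            assert glcm_homogeneity(g) == pytest.approx(h, abs=1e-12)
            assert glcm_correlation(g) == pytest.approx(r, abs=1e-10)

    def test_shift_invariance_via_quantization(self, rng):
        img = rng.uniform(size=(16, 16))
        g1 = compute_glcm(img, levels=8, offset=(0, 1))
        g2 = compute_glcm(img + 5.0, levels=8, offset=(0, 1))
        assert np.allclose(g1.P, g2.P)


class TestFirstOrderStats:
    def test_hand_example_1234(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        s = first_order_stats(img)
        assert s.mean == pytest.approx(2.5)
        assert s.sd == pytest.approx(np.sqrt(1.25))
        assert s.skewness == pytest.approx(0.0, abs=1e-12)
        assert s.kurtosis == pytest.approx(1.64)
        assert s.n_pixels == 4

    def test_symmetric_values_zero_skew(self, rng):
        vals = rng.normal(size=500)
        img = np.concatenate([vals, -vals]).reshape(10, 100)
        assert first_order_stats(img).skewness == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_kurtosis_near_three(self):
        rng = np.random.default_rng(42)
        img = rng.normal(size=(100, 1000))
        assert first_order_stats(img).kurtosis == pytest.approx(3.0, abs=0.1)

    def test_population_moments_match_scipy(self, rng):
        img = rng.uniform(size=(16, 16))
        roi = rng.uniform(size=(16, 16)) > 0.4
        s = first_order_stats(img, roi)
        vals = img[roi]
        assert s.mean == pytest.approx(vals.mean(), abs=1e-12)
        assert s.sd == pytest.approx(vals.std(ddof=0), abs=1e-12)
        assert s.skewness == pytest.approx(sps.skew(vals, bias=True), abs=1e-10)
        assert s.kurtosis == pytest.approx(
            sps.kurtosis(vals, fisher=False, bias=True), abs=1e-10
        )

    def test_constant_roi_rejected(self):
        with pytest.raises(ValueError):
            first_order_stats(np.full((4, 4), 0.5))


class TestPoolingAndFusion:
    def test_constant_channel_pools_to_itself(self):
        maps = np.stack([np.full((4, 4), 0.7), np.full((4, 4), -1.2)])
        assert np.allclose(gap_pool(maps), [0.7, -1.2])

    def test_mean_example(self):
        maps = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert gap_pool(maps)[0] == pytest.approx(2.5)

    def test_spatial_permutation_invariance(self, rng):
        ch = rng.uniform(size=(1, 4, 4))
        perm = ch.ravel().copy()
        rng.shuffle(perm)
        assert gap_pool(ch)[0] == pytest.approx(
            gap_pool(perm.reshape(1, 4, 4))[0]
        )

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            gap_pool(np.zeros((0, 4, 4)))

    def test_fusion_scales_blocks(self):
        fv = fuse_features(np.array([2.0]), np.array([4.0]), alpha=0.5, beta=0.25)
        assert np.allclose(fv.values, [1.0, 1.0])
        assert fv.provenance == "fused"

    def test_alpha_beta_one_is_concatenation(self, rng):
        d, h = rng.uniform(size=3), rng.uniform(size=5)
        fv = fuse_features(d, h)
        assert np.allclose(fv.values, np.concatenate([d, h]))
        assert all(n.startswith(("deep:", "hc:")) for n in fv.names)

    def test_beta_zero_zeroes_handcrafted_block(self, rng):
        fv = fuse_features(rng.uniform(size=3), rng.uniform(size=4), alpha=1, beta=0)
        assert np.allclose(fv.values[3:], 0.0)

    def test_sum_mode_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            fuse_features(np.ones(3), np.ones(4), mode="sum")
        fv = fuse_features(np.ones(3), 2 * np.ones(3), mode="sum")
        assert np.allclose(fv.values, 3.0)

    def test_extract_handcrafted_names_align(self, noisy_phantom):
        fv = extract_handcrafted(noisy_phantom.image, noisy_phantom.brain_mask)
        assert len(fv.names) == fv.values.size == 8
        assert np.all(np.isfinite(fv.values))
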