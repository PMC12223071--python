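"""Morphology, diffusion, normalization, MI registration, quality gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedcaps.preprocessing import (
    DiffusionParams,
    RigidTransform,
    StructuringElement,
    anisotropic_diffusion,
    apply_rigid,
    dilate,
    erode,
    minmax_normalize,
    mutual_information,
    quality_gate,
    register_rigid,
    skull_strip,
)
from fedcaps.synthetic_data import PhantomSpec, generate_phantom, make_pseudo_modality


def brute_force_erode(mask: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Set-definition oracle: keep z where the translated footprint fits."""
    H, W = mask.shape
    fh, fw = fp.shape
    cy, cx = fh // 2, fw // 2
    out = np.zeros_like(mask)
    for r in range(H):
        for c in range(W):
            ok = True
            for i in range(fh):
                for j in range(fw):
                    if fp[i, j]:
                        rr, cc = r + i - cy, c + j - cx
                        if not (0 <= rr < H and 0 <= cc < W) or not mask[rr, cc]:
                            ok = False
                            break
                if not ok:
                    break
            out[r, c] = ok
    return out


class TestMorphology:
    def test_erode_square_with_disk_radius_1(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True  # 5x5 square
        out = erode(mask, StructuringElement(1))
        expected = np.zeros_like(mask)
        expected[3:6, 3:6] = True  # 3x3 survives
        assert np.array_equal(out, expected)

    def test_dilate_single_pixel_is_footprint(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        se = StructuringElement(2)
        out = dilate(mask, se)
        fp = se.footprint
        assert np.array_equal(out[2:7, 2:7], fp)
        assert out.sum() == fp.sum()

    def test_dilate_empty_is_empty(self):
        assert not dilate(np.zeros((5, 5), bool), StructuringElement(1)).any()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_erosion_matches_set_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(8, 8)) > 0.5
        se = StructuringElement(1)
        assert np.array_equal(erode(mask, se), brute_force_erode(mask, se.footprint))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_duality_and_closing_extensivity(self, seed):
        # random 8x8 pattern embedded in zero padding wide enough that the
        # footprint never pokes past the array edge: set identities are then
        # free of boundary-convention effects on the central window
        rng = np.random.default_rng(seed)
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:10, 2:10] = rng.uniform(size=(8, 8)) > 0.5
        se = StructuringElement(1)
        center = (slice(2, 10), slice(2, 10))
        # duality on complements for a symmetric footprint
        assert np.array_equal(
            erode(mask, se)[center], (~dilate(~mask, se))[center]
        )
        # anti-extensivity / closing extensivity
        assert not np.any(erode(mask, se) & ~mask)
        closed = erode(dilate(mask, se), se)
        assert np.all(closed[mask])


class TestSkullStrip:
    def test_recovers_brain_and_excludes_skull(self, noisy_phantom):
        mask = skull_strip(noisy_phantom.image)
        brain = noisy_phantom.brain_mask
        skull = (noisy_phantom.image > 0.85) & ~brain
        coverage = (mask & brain).sum() / brain.sum()
        leakage = (mask & skull).sum() / max(skull.sum(), 1)
        assert coverage >= 0.90
        assert leakage <= 0.05

    def test_blank_image_gives_empty_mask(self):
        assert not skull_strip(np.zeros((32, 32))).any()

    def test_single_connected_component(self, noisy_phantom):
        from scipy import ndimage

        mask = skull_strip(noisy_phantom.image)
        _, n = ndimage.label(mask)
        assert n == 1


class TestDiffusion:
    def test_constant_image_is_fixed_point(self):
        img = np.full((16, 16), 0.4)
        out = anisotropic_diffusion(img, DiffusionParams(n_iter=25))
        assert np.allclose(out, img)

    def test_global_mean_conserved(self, noisy_phantom):
        out = anisotropic_diffusion(noisy_phantom.image, DiffusionParams(n_iter=10))
        assert abs(out.mean() - noisy_phantom.image.mean()) < 1e-6

    def test_variance_strictly_decreases_on_noisy_input(self, noisy_phantom):
        img = noisy_phantom.image
        prev_var = img.var()
        for _ in range(20):
            img = anisotropic_diffusion(img, DiffusionParams(n_iter=1))
            assert img.var() < prev_var
            prev_var = img.var()

    def test_iteration_composition(self, noisy_phantom):
        p = lambda k: DiffusionParams(n_iter=k, kappa=0.15, lam=0.2)
        once = anisotropic_diffusion(noisy_phantom.image, p(7))
        composed = anisotropic_diffusion(
            anisotropic_diffusion(noisy_phantom.image, p(4)), p(3)
        )
        assert np.allclose(once, composed)

    def test_zero_iterations_is_identity(self, noisy_phantom):
        out = anisotropic_diffusion(noisy_phantom.image, DiffusionParams(n_iter=0))
        assert np.array_equal(out, noisy_phantom.image)

    @pytest.mark.parametrize("lam", [0.0, 0.3, -0.1])
    def test_unstable_step_rejected(self, lam):
        with pytest.raises(ValueError):
            DiffusionParams(lam=lam)


class TestMinMax:
    def test_hand_example(self):
        out = minmax_normalize(np.array([2.0, 4.0, 10.0]))
        assert np.allclose(out, [0.0, 0.25, 1.0])

    def test_identity_when_already_spanning(self):
        x = np.array([0.0, 0.3, 1.0])
        assert np.allclose(minmax_normalize(x), x)

    def test_idempotent_and_rank_preserving(self, rng):
        x = rng.uniform(size=50)
        once = minmax_normalize(x, 0, 1)
        twice = minmax_normalize(once, 0, 1)
        assert np.allclose(once, twice)
        assert np.array_equal(np.argsort(once), np.argsort(x))

    def test_output_attains_new_bounds(self, rng):
        out = minmax_normalize(rng.normal(size=100), -2.0, 3.0)
        assert out.min() == -2.0 and out.max() == 3.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(np.full(10, 0.7))


class TestMutualInformation:
    def test_self_information_equals_entropy(self, noisy_phantom):
        x = noisy_phantom.image
        mi = mutual_information(x, x, bins=16)
        counts, _ = np.histogram(x.ravel(), bins=16)
        p = counts / counts.sum()
        p = p[p > 0]
        h = -(p * np.log2(p)).sum()
        assert mi == pytest.approx(h, abs=1e-10)

    def test_independent_noise_near_zero(self, rng):
        a = rng.uniform(size=(64, 64))
        b = rng.uniform(size=(64, 64))
        assert mutual_information(a, b, bins=16) < 0.05

    def test_invariant_under_monotone_relabeling(self, noisy_phantom):
        x = noisy_phantom.image
        assert mutual_information(x, 1.0 - x, bins=16) == pytest.approx(
            mutual_information(x, x, bins=16), abs=1e-10
        )

    def test_non_negative(self, rng):
        a, b = rng.uniform(size=(32, 32)), rng.uniform(size=(32, 32))
        assert mutual_information(a, b) >= -1e-12


class TestRegistration:
    def test_identity_pair_recovers_identity(self, noisy_phantom):
        t, _, _ = register_rigid(
            noisy_phantom.image, noisy_phantom.image, max_shift=4
        )
        assert abs(t.dy) <= 0.5 and abs(t.dx) <= 0.5 and abs(t.theta) <= 0.5

    def test_known_shift_recovered_within_one_pixel(self, noisy_phantom):
        fixed = noisy_phantom.image
        moving = apply_rigid(fixed, RigidTransform(dy=-5, dx=3))
        t, _, _ = register_rigid(moving, fixed, max_shift=8)
        assert abs(t.dy - 5) <= 1 and abs(t.dx - (-3)) <= 1

    def test_cross_modality_shift_recovered(self, noisy_phantom):
        fixed = noisy_phantom.image
        pseudo = make_pseudo_modality(noisy_phantom).image
        moving = apply_rigid(pseudo, RigidTransform(dy=-5, dx=3))
        t, _, _ = register_rigid(moving, fixed, max_shift=8)
        assert abs(t.dy - 5) <= 1 and abs(t.dx - (-3)) <= 1

    def test_score_at_optimum_at_least_identity(self, noisy_phantom):
        fixed = noisy_phantom.image
        moving = apply_rigid(fixed, RigidTransform(dy=2, dx=-1))
        _, _, score = register_rigid(moving, fixed, max_shift=4)
        assert score >= mutual_information(moving, fixed) - 1e-12


class TestQualityGate:
    def test_identical_images_accepted_with_ssim_one(self, noisy_phantom):
        ok, ssim, psnr = quality_gate(noisy_phantom.image, noisy_phantom.image)
        assert ok and ssim == pytest.approx(1.0) and np.isinf(psnr)

    def test_psnr_matches_noise_level(self, rng):
        ref = rng.uniform(0.2, 0.8, size=(64, 64))
        noisy = ref + rng.normal(0, 0.1, size=ref.shape)
        _, _, psnr = quality_gate(noisy, ref, ssim_min=0.0, psnr_min=0.0)
        # PSNR = 20 log10(1/RMSE), RMSE ~= 0.1 -> ~20 dB
        assert psnr == pytest.approx(20.0, abs=1.0)

    def test_strict_gate_rejects_blurred(self, noisy_phantom):
        from scipy import ndimage

        blurred = ndimage.gaussian_filter(noisy_phantom.image, 2.0)
        ok, _, _ = quality_gate(
            blurred, noisy_phantom.image, ssim_min=0.99, psnr_min=60.0
        )
        assert not ok

    def test_flat_reference_rejected(self):
        with pytest.raises(ValueError):
            quality_gate(np.zeros((8, 8)), np.zeros((8, 8)))
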