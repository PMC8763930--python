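"""PET metrics and the shape / first-order / GLCM feature families."""

import math

import numpy as np
import pytest

import thyropet as tp
from thyropet.features import (
    FIRST_ORDER_FEATURE_NAMES,
    GLCM_DIRECTIONS,
    GLCM_FEATURE_NAMES,
    SHAPE_FEATURE_NAMES,
    first_order_features,
    glcm_features,
    glcm_matrix,
    pet_metrics,
    resample_and_discretize,
    shape_features,
)


def _volume(data, spacing=(1.0, 1.0, 1.0)):
    return tp.PetVolume(np.asarray(data, dtype=float), spacing)


def _mask(mask, spacing=(1.0, 1.0, 1.0)):
    return tp.LesionMask(np.asarray(mask, dtype=bool), spacing)


class TestPetMetrics:
    def test_constant_lesion(self):
        # 5 mL lesion at SUV 4: 5 voxels of 10x10x10 mm
        data = np.zeros((5, 1, 1))
        data[:] = 4.0
        m = pet_metrics(_volume(data, (10, 10, 10)), _mask(np.ones((5, 1, 1)), (10, 10, 10)))
        assert m.suv_max == 4.0 and m.suv_mean == 4.0
        assert m.mtv_ml == pytest.approx(5.0)
        assert m.tlg == pytest.approx(20.0)

    def test_two_voxel_lesion(self):
        data = np.array([[[2.0, 6.0]]])
        m = pet_metrics(_volume(data), _mask(np.ones((1, 1, 2))))
        assert m.suv_max == 6.0 and m.suv_mean == 4.0

    def test_tlg_identity_to_machine_precision(self, noisy_phantom):
        m = pet_metrics(noisy_phantom.volume, noisy_phantom.truth_mask)
        assert m.tlg == m.suv_mean * m.mtv_ml  # exact product, not recomputed
        assert m.tlg / m.suv_mean == pytest.approx(m.mtv_ml, rel=1e-15)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            pet_metrics(_volume(np.ones((2, 2, 2))), _mask(np.zeros((2, 2, 2))))


class TestResampleAndDiscretize:
    def test_isotropic_input_passthrough(self):
        data = np.random.default_rng(0).uniform(1, 5, (6, 6, 6))
        vol = _volume(data, (2.0, 2.0, 2.0))
        spec = tp.PreprocessSpec(resample_spacing=2.0, discretization="fixed_bin_width",
                                 bin_parameter=0.5)
        levels, msk, ng = resample_and_discretize(vol, _mask(np.ones((6, 6, 6)), (2, 2, 2)), spec)
        assert msk.shape == data.shape and msk.all()
        # mapping rule: floor((x - min)/width) + 1
        expected = np.floor((data - data.min()) / 0.5).astype(int) + 1
        assert np.array_equal(levels, expected)

    def test_constant_lesion_single_level(self):
        vol = _volume(np.full((4, 4, 4), 3.3), (2, 2, 2))
        spec = tp.PreprocessSpec()
        levels, msk, ng = resample_and_discretize(vol, _mask(np.ones((4, 4, 4)), (2, 2, 2)), spec)
        assert ng == 1 and set(levels[msk]) == {1}

    def test_fixed_bin_count_uniform_split(self):
        data = np.arange(64, dtype=float).reshape(4, 4, 4)
        vol = _volume(data, (2, 2, 2))
        spec = tp.PreprocessSpec(discretization="fixed_bin_count", bin_parameter=4)
        levels, msk, ng = resample_and_discretize(vol, _mask(np.ones((4, 4, 4)), (2, 2, 2)), spec)
        assert ng == 4
        counts = np.bincount(levels[msk])[1:]
        assert counts.tolist() == [16, 16, 16, 16]

    def test_anisotropic_resampled_to_isotropic(self, noisy_phantom):
        vol = tp.PetVolume(noisy_phantom.volume.data, (2.0, 2.0, 4.0))
        mask = tp.LesionMask(noisy_phantom.truth_mask.mask, (2.0, 2.0, 4.0))
        levels, msk, ng = resample_and_discretize(vol, mask, tp.PreprocessSpec())
        assert msk.shape[2] == pytest.approx(2 * vol.data.shape[2], abs=1)


class TestShapeFeatures:
    def test_digital_sphere_sphericity_near_one(self, digital_sphere_mask):
        f = shape_features(digital_sphere_mask)
        assert f["shape_Sphericity"] == pytest.approx(1.0, abs=0.03)
        true_v = 4 / 3 * math.pi * 10**3
        assert f["shape_MeshVolume"] == pytest.approx(true_v, rel=0.05)
        assert f["shape_Maximum3DDiameter"] == pytest.approx(20.0, abs=1.5)

    def test_cube_sphericity_closed_form(self):
        s = 80
        cube = np.zeros((s + 6,) * 3, bool)
        cube[3:3 + s, 3:3 + s, 3:3 + s] = True
        f = shape_features(_mask(cube))
        assert f["shape_Sphericity"] == pytest.approx((36 * math.pi) ** (1 / 3) / 6, abs=0.02)
        assert f["shape_VoxelVolume"] == s**3

    def test_returns_all_14_features_finite(self, noisy_phantom):
        f = shape_features(noisy_phantom.truth_mask)
        assert set(f) == set(SHAPE_FEATURE_NAMES)
        assert all(np.isfinite(v) for v in f.values())
        assert 0 < f["shape_Sphericity"] <= 1.0

    def test_intensity_invariance(self, noisy_phantom):
        # shape depends only on the mask: identical for any image content
        assert shape_features(noisy_phantom.truth_mask) == shape_features(
            tp.LesionMask(noisy_phantom.truth_mask.mask.copy(), noisy_phantom.truth_mask.spacing)
        )

    def test_elongated_mask_low_flatness(self):
        bar = np.zeros((30, 10, 10), bool)
        bar[2:28, 3:7, 3:7] = True
        f = shape_features(_mask(bar))
        assert f["shape_Flatness"] < 0.5
        assert f["shape_MajorAxisLength"] > f["shape_LeastAxisLength"]

    def test_single_voxel_analytic_fallback(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        f = shape_features(_mask(m, (2.0, 2.0, 2.0)))
        assert f["shape_MeshVolume"] == pytest.approx(8.0)
        assert f["shape_SurfaceArea"] == pytest.approx(24.0)
        assert all(np.isfinite(v) for v in f.values())


class TestFirstOrder:
    def test_constant_lesion(self):
        f = first_order_features(np.full(50, 2.5), np.ones(50, dtype=int))
        assert f["firstorder_Variance"] == 0.0
        assert f["firstorder_Entropy"] == 0.0
        assert f["firstorder_Uniformity"] == 1.0

    def test_small_sample_statistics(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["firstorder_Mean"] == 2.5
        assert f["firstorder_Range"] == 3.0
        assert f["firstorder_Median"] == 2.5

    def test_symmetric_sample_zero_skewness(self):
        x = np.concatenate([np.arange(10.0), -np.arange(10.0)])
        assert abs(first_order_features(x)["firstorder_Skewness"]) < 1e-12

    def test_gaussian_kurtosis_near_three(self):
        x = np.random.default_rng(3).normal(size=20000)
        assert first_order_features(x)["firstorder_Kurtosis"] == pytest.approx(3.0, abs=0.15)

    def test_all_18_present(self):
        f = first_order_features(np.arange(10.0))
        assert set(f) == set(FIRST_ORDER_FEATURE_NAMES)


class TestGlcm:
    def test_constant_lesion_autocorrelation_one(self):
        levels = np.ones((4, 4, 4), dtype=int)
        f = glcm_features(levels, np.ones((4, 4, 4), bool))
        assert f["glcm_Autocorrelation"] == 1.0
        assert f["glcm_MaximumProbability"] == 1.0

    def test_alternating_stripe_hand_computed_matrix(self):
        """1D stripe 1,2,1,2,... at distance 1 along the stripe axis:
        p(1,2) = p(2,1) = 0.5, so Autocorrelation = 2."""
        levels = np.zeros((1, 1, 16), dtype=int)
        levels[0, 0, :] = [1, 2] * 8
        mask = np.ones((1, 1, 16), bool)
        counts = glcm_matrix(levels, mask, (0, 0, 1), 2, symmetric=True)
        p = counts / counts.sum()
        assert p[0, 1] == 0.5 and p[1, 0] == 0.5 and p[0, 0] == 0.0
        assert (p * np.array([[1, 2], [2, 4]])).sum() == 2.0

    def test_every_direction_matrix_symmetric_and_normalised(self, noisy_phantom):
        spec = tp.PreprocessSpec()
        levels, msk, ng = resample_and_discretize(
            noisy_phantom.volume, noisy_phantom.truth_mask, spec
        )
        for direction in GLCM_DIRECTIONS:
            counts = glcm_matrix(levels, msk, direction, ng, symmetric=True)
            if counts.sum() == 0:
                continue
            p = counts / counts.sum()
            assert np.allclose(p, p.T)
            assert p.sum() == pytest.approx(1.0)

    def test_all_24_features_finite(self, noisy_phantom):
        f = tp.extract_all_features(noisy_phantom.volume, noisy_phantom.truth_mask)
        glcm = {k: v for k, v in f.items() if k.startswith("glcm_")}
        assert set(glcm) == set(GLCM_FEATURE_NAMES)
        assert all(np.isfinite(v) for v in glcm.values())

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        block = (rng.integers(1, 5, size=(5, 5, 5))).astype(int)
        grid1 = np.zeros((12, 12, 12), dtype=int)
        grid2 = np.zeros((12, 12, 12), dtype=int)
        grid1[1:6, 1:6, 1:6] = block
        grid2[5:10, 5:10, 5:10] = block
        m1, m2 = grid1 > 0, grid2 > 0
        assert glcm_features(grid1, m1) == glcm_features(grid2, m2)

    def test_coarse_texture_has_higher_autocorrelation(self):
        """Spatially smoother uptake co-occurs at similar (often high) levels."""
        means = {}
        for coarseness in (0.1, 0.9):
            vals = []
            for seed in range(20):
                spec = tp.PhantomSpec(
                    lesion_volume_ml=10.0, texture_coarseness=coarseness,
                    noise_sd=0.05, seed=seed,
                )
                ph = tp.generate_phantom(spec)
                f = tp.extract_all_features(ph.volume, ph.truth_mask)
                vals.append(f["glcm_Autocorrelation"])
            means[coarseness] = np.mean(vals)
        assert means[0.9] > means[0.1]

    def test_no_pairs_raises(self):
        levels = np.ones((1, 1, 1), dtype=int)
        with pytest.raises(ValueError, match="pair"):
            glcm_features(levels, np.ones((1, 1, 1), bool))
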