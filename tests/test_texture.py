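import numpy as np
import pytest

import oracles
from fetrad.features import (
    DiscretizationConfig,
    FEATURE_CLASSES,
    all_feature_names,
    discretize,
    extract_all,
)
from fetrad.features.matrices import (
    DIRECTIONS_13,
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_stats,
)
from fetrad.features.texture import (
    _glcm_features_single,
    gldm_features_from_matrix,
    ngtdm_features_from_stats,
    texture_features,
)


def _random_voi(rng, side=6, n_levels=4, p_mask=0.8):
    shape = (side, side, side)
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < p_mask
    if mask.sum() < 2:
        mask[0, 0, 0] = mask[0, 0, 1] = True
    levels[~mask] = 0
    return levels


class TestMatrixOracles:
    """Vectorized builders vs. naive scalar-loop constructions, 1e-9 agreement."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_five_matrix_families_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        side = int(rng.integers(4, 9))  # VOIs up to 8^3
        n_levels = int(rng.integers(2, 7))
        levels = _random_voi(rng, side, n_levels, p_mask=float(rng.uniform(0.4, 1.0)))

        np.testing.assert_allclose(
            glcm_matrices(levels, n_levels), oracles.naive_glcm(levels, n_levels), atol=1e-9
        )
        np.testing.assert_allclose(
            glrlm_matrices(levels, n_levels)[..., : max(levels.shape)],
            oracles.naive_glrlm(levels, n_levels),
            atol=1e-9,
        )
        np.testing.assert_allclose(
            glszm_matrix(levels, n_levels), oracles.naive_glszm(levels, n_levels), atol=1e-9
        )
        np.testing.assert_allclose(
            gldm_matrix(levels, n_levels), oracles.naive_gldm(levels, n_levels), atol=1e-9
        )
        s, n = ngtdm_stats(levels, n_levels)
        s_ref, n_ref = oracles.naive_ngtdm(levels, n_levels)
        np.testing.assert_allclose(s, s_ref, atol=1e-9)
        np.testing.assert_allclose(n, n_ref, atol=1e-9)

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_features_from_oracle_matrices_match(self, seed):
        """Full texture features agree with values derived from naive matrices."""
        rng = np.random.default_rng(seed)
        levels = _random_voi(rng, 6, 5)
        n_levels = 5
        n_vox = int(np.count_nonzero(levels))
        from fetrad.features.texture import _sized_matrix_features
        from fetrad.features.texture import (
            glcm_features,
            gldm_features,
            glrlm_features,
            glszm_features,
            ngtdm_features,
        )

        # GLCM / GLRLM via per-direction oracle matrices
        ref_glcm = [
            _glcm_features_single(m, n_levels) for m in oracles.naive_glcm(levels, n_levels)
        ]
        got = glcm_features(levels, n_levels)
        for name in got:
            ref = np.mean([f[name] for f in ref_glcm if f is not None])
            assert got[name] == pytest.approx(ref, rel=1e-9, abs=1e-12), name

        ref_glrlm = [
            _sized_matrix_features(m, n_vox, "glrlm")
            for m in oracles.naive_glrlm(levels, n_levels)
        ]
        got = glrlm_features(levels, n_levels)
        for name in got:
            ref = np.mean([f[name] for f in ref_glrlm])
            assert got[name] == pytest.approx(ref, rel=1e-9, abs=1e-12), name

        got = glszm_features(levels, n_levels)
        ref = _sized_matrix_features(oracles.naive_glszm(levels, n_levels), n_vox, "glszm")
        for name in got:
            assert got[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name

        got = gldm_features(levels, n_levels)
        ref = gldm_features_from_matrix(oracles.naive_gldm(levels, n_levels))
        for name in got:
            assert got[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name

        got = ngtdm_features(levels, n_levels)
        s_ref, n_ref = oracles.naive_ngtdm(levels, n_levels)
        ref = ngtdm_features_from_stats(s_ref, n_ref, n_levels)
        for name in got:
            assert got[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name


class TestHandComputedCases:
    def test_glcm_single_direction_by_hand(self):
        """2x2x1 checkerboard-ish toy array, direction (1,0,0) enumerated by hand."""
        levels = np.array([[[1], [2]], [[1], [2]]], dtype=np.int32)
        mats = glcm_matrices(levels, 2)
        k = DIRECTIONS_13.index((1, 0, 0))
        # pairs along x: (1,1) at y=0 and (2,2) at y=1, symmetrized -> 2 each
        expected = np.array([[2.0, 0.0], [0.0, 2.0]])
        np.testing.assert_allclose(mats[k], expected)
        f = _glcm_features_single(mats[k], 2)
        assert f["MaximumProbability"] == pytest.approx(0.5)
        assert f["Contrast"] == 0.0

    def test_constant_voi_degenerate_conventions(self):
        img = np.full((4, 4, 4), 2.0)
        mask = np.ones(img.shape, dtype=bool)
        vals, flags = texture_features(img, mask)
        assert vals["glcm_JointEnergy"] == pytest.approx(1.0)
        assert vals["glcm_Contrast"] == 0.0
        assert vals["glcm_Correlation"] == 1.0
        assert vals["glcm_MCC"] == 1.0
        # single connected zone of the single gray level
        assert vals["glszm_SizeZoneNonUniformity"] == pytest.approx(1.0)
        assert len(flags) == 75

    def test_glszm_zone_sizes_partition_voi(self):
        rng = np.random.default_rng(2)
        levels = _random_voi(rng, 6, 3)
        mat = glszm_matrix(levels, 3)
        sizes = np.arange(1, mat.shape[1] + 1)
        assert (mat * sizes).sum() == np.count_nonzero(levels)


class TestExtractAll:
    def test_93_features_with_class_partition(self, noisefree_patient):
        from fetrad.maps import compute_parametric_maps

        maps = compute_parametric_maps(
            noisefree_patient.dynamic_image, noisefree_patient.voi_set.crescent_mask
        )
        fv = extract_all(maps["TBR_20_40"].voxels, noisefree_patient.voi_set.tumor_mask)
        assert len(fv) == 93
        counts = {cls: len(names) for cls, names in FEATURE_CLASSES.items()}
        assert counts == {
            "firstorder": 18,
            "glcm": 24,
            "glrlm": 16,
            "glszm": 16,
            "gldm": 14,
            "ngtdm": 5,
        }
        assert sum(counts.values()) == 93

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        img = rng.random((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        a = extract_all(img, mask).as_array()
        b = extract_all(img, mask).as_array()
        assert np.array_equal(a, b)

    def test_rescaling_invariance_in_count_mode(self):
        """Multiplying the image by k>0 leaves histogram/texture features unchanged."""
        rng = np.random.default_rng(5)
        img = rng.random((6, 6, 6)) + 1.0
        mask = rng.random((6, 6, 6)) > 0.2
        a = extract_all(img, mask)
        b = extract_all(3.7 * img, mask)
        intensity_scaled = {
            "firstorder_Energy",
            "firstorder_TotalEnergy",
            "firstorder_Minimum",
            "firstorder_10Percentile",
            "firstorder_90Percentile",
            "firstorder_Maximum",
            "firstorder_Mean",
            "firstorder_Median",
            "firstorder_InterquartileRange",
            "firstorder_Range",
            "firstorder_MeanAbsoluteDeviation",
            "firstorder_RobustMeanAbsoluteDeviation",
            "firstorder_RootMeanSquared",
            "firstorder_Variance",
        }
        for name in all_feature_names():
            if name in intensity_scaled:
                assert a.values[name] != pytest.approx(b.values[name], rel=1e-3) or (
                    a.values[name] == 0
                )
            else:
                assert a.values[name] == pytest.approx(b.values[name], rel=1e-9), name

    @pytest.mark.parametrize("transform", ["flip0", "flip1", "flip2", "rot01", "rot12"])
    def test_flip_and_rotation_invariance(self, transform):
        rng = np.random.default_rng(6)
        img = rng.random((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        ops = {
            "flip0": lambda a: np.flip(a, 0),
            "flip1": lambda a: np.flip(a, 1),
            "flip2": lambda a: np.flip(a, 2),
            "rot01": lambda a: np.rot90(a, axes=(0, 1)),
            "rot12": lambda a: np.rot90(a, axes=(1, 2)),
        }
        op = ops[transform]
        a = extract_all(img, mask)
        b = extract_all(op(img).copy(), op(mask).copy())
        for name in all_feature_names():
            assert a.values[name] == pytest.approx(b.values[name], rel=1e-9), name
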