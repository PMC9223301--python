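"""Tests for GLCM construction and Haralick features, including a
cross-check against scikit-image and an independent loop-based
recomputation of the 3-D averaging."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from colorfuzen import (ColorImage, GLCM, GLCMConfig, averaged_haralick,
                        glcm_2d, glcm_3d, haralick, quantize)
from colorfuzen.cooccurrence import ORIENTATIONS_2D, ORIENTATIONS_3D


class TestQuantize:
    def test_eight_levels_one_value_each(self):
        out = quantize(np.arange(8.0).reshape(2, 4), 8)
        assert sorted(out.ravel()) == list(range(1, 9))

    def test_constant_maps_to_bin_one(self):
        assert np.all(quantize(np.full((3, 3), 5.0), 8) == 1)

    def test_midpoint_split(self):
        out = quantize(np.array([[0.0, 0.49], [0.51, 1.0]]), 2)
        np.testing.assert_array_equal(out, [[1, 1], [2, 2]])


class TestGLCM2D:
    def test_constant_plane_all_mass_at_origin(self):
        g = glcm_2d(np.ones((5, 5), dtype=int), (0, 1), 1, 8, True)
        assert g.P[0, 0] == 1.0
        f = haralick(g)
        assert (f.energy, f.contrast, f.entropy) == (1.0, 0.0, 0.0)

    def test_vertical_stripes_along_rows(self):
        # columns alternate levels 1, 2: 12 horizontal pairs, all (1,2)/(2,1)
        stripes = np.tile([1, 2], (4, 2))
        g = glcm_2d(stripes, (0, 1), 1, 2, True)
        assert g.valid_pairs == 12
        np.testing.assert_allclose(g.P, [[0.0, 0.5], [0.5, 0.0]])
        assert haralick(g).contrast == pytest.approx(1.0)

    def test_vertical_stripes_along_columns(self):
        stripes = np.tile([1, 2], (4, 2))
        g = glcm_2d(stripes, (-1, 0), 1, 2, True)
        np.testing.assert_allclose(g.P, [[0.5, 0.0], [0.0, 0.5]])
        assert haralick(g).contrast == pytest.approx(0.0)

    def test_matches_scikit_image(self, rng):
        """Dual route: our accumulator vs skimage.feature.graycomatrix.

        skimage measures angles clockwise in image coordinates, so its
        45 deg is the antiparallel of ours; under symmetric counting the
        45/135 matrices swap.  Diagonals are compared at d=1 only:
        skimage rounds sin/cos * d, so its diagonal offset at d>1 is
        shorter than d steps along the direction vector.
        """
        q = rng.integers(1, 9, (15, 13))
        pairs = [((0, 1), 0.0, (1, 2, 4)), ((-1, 1), 3 * np.pi / 4, (1,)),
                 ((-1, 0), np.pi / 2, (1, 2, 4)), ((-1, -1), np.pi / 4, (1,))]
        for orient, angle, distances in pairs:
            for d in distances:
                ref = graycomatrix((q - 1).astype(np.uint8), [d], [angle],
                                   levels=8, symmetric=True, normed=True)
                np.testing.assert_allclose(glcm_2d(q, orient, d, 8, True).P,
                                           ref[:, :, 0, 0], atol=1e-12)

    def test_symmetric_matrix(self, rng):
        q = rng.integers(1, 5, (10, 10))
        g = glcm_2d(q, (-1, 1), 2, 4, True)
        np.testing.assert_allclose(g.P, g.P.T)
        assert g.P.sum() == pytest.approx(1.0)


class TestGLCM3D:
    def test_constant_volume(self):
        g = glcm_3d(np.ones((4, 4, 3), dtype=int), (0, 0, 1), 1, 8, True)
        assert g.P[0, 0] == 1.0

    def test_depth_displacement_out_of_bounds_is_empty(self):
        g = glcm_3d(np.ones((2, 2, 3), dtype=int), (0, 0, 1), 4, 8, True)
        assert g.empty
        with pytest.raises(ValueError):
            haralick(g)

    def test_layered_volume_mass_on_adjacent_levels(self):
        vol = np.ones((3, 3, 3), dtype=int) * np.array([1, 2, 3])
        g = glcm_3d(vol, (0, 0, 1), 1, 3, True)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 0.25
        expected[1, 2] = expected[2, 1] = 0.25
        np.testing.assert_allclose(g.P, expected)

    def test_thirteen_directions_non_antiparallel(self):
        dirs = set(ORIENTATIONS_3D)
        assert len(dirs) == 13
        for d in dirs:
            assert tuple(-x for x in d) not in dirs


class TestHaralick:
    def test_two_by_two_offdiagonal(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = haralick(GLCM(P, (0, 1), 1, 4))
        assert f.energy == pytest.approx(0.5)
        assert f.contrast == pytest.approx(1.0)
        assert f.correlation == pytest.approx(-1.0)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.entropy == pytest.approx(np.log(2))
        assert f.variance == pytest.approx(0.25)

    def test_uniform_matrix_maximum_entropy(self):
        P = np.full((8, 8), 1 / 64)
        f = haralick(GLCM(P, (0, 1), 1, 64))
        assert f.energy == pytest.approx(1 / 64)
        assert f.entropy == pytest.approx(np.log(64))

    def test_base2_entropy(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = haralick(GLCM(P, (0, 1), 1, 4), log_base="2")
        assert f.entropy == pytest.approx(1.0)

    def test_variance_identity_on_random_matrices(self, rng):
        """For symmetric P the variance equals the row-marginal moment."""
        for _ in range(10):
            raw = rng.random((6, 6))
            P = (raw + raw.T)
            P /= P.sum()
            f = haralick(GLCM(P, (0, 1), 1, 36))
            lev = np.arange(1, 7)
            px = P.sum(axis=1)
            mu = (lev * px).sum()
            assert f.variance == pytest.approx(((lev - mu) ** 2 * px).sum())

    def test_feature_bounds_on_random_matrices(self, rng):
        for _ in range(10):
            raw = rng.random((8, 8))
            P = raw + raw.T
            P /= P.sum()
            f = haralick(GLCM(P, (0, 1), 1, 64))
            assert 0 < f.energy <= 1
            assert f.contrast >= 0
            assert -1 <= f.correlation <= 1
            assert 0 < f.homogeneity <= 1
            assert f.entropy >= 0


class TestAveragedHaralick:
    def test_constant_image_degenerate_features(self):
        img = ColorImage(np.full((8, 8, 3), 0.5))
        for feats in averaged_haralick(img, GLCMConfig(), "per_channel_2d"):
            assert feats.as_tuple() == (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

    def test_rotation_isotropy(self, rng):
        """The 4-orientation average is invariant under 90-deg rotation."""
        plane = rng.random((12, 12))
        img = ColorImage(plane[:, :, None])
        rot = ColorImage(np.rot90(plane)[:, :, None])
        config = GLCMConfig(distances=(1, 2))
        a = averaged_haralick(img, config, "per_channel_2d")[0]
        b = averaged_haralick(rot, config, "per_channel_2d")[0]
        np.testing.assert_allclose(a.as_tuple(), b.as_tuple(), atol=1e-12)

    def test_volume_3d_matches_independent_recomputation(self, rng):
        """Build all 52 matrices with an explicit triple loop and average."""
        img = ColorImage(rng.random((16, 16, 3)))
        config = GLCMConfig()
        ours = averaged_haralick(img, config, "volume_3d")

        q = np.stack([quantize(img.channel(k), 8) for k in range(3)], axis=-1)
        h, w, kk = q.shape
        all_feats = []
        n_built = 0
        for orient in ORIENTATIONS_3D:
            for d in config.distances:
                n_built += 1
                counts = np.zeros((8, 8))
                di, dj, dk = (o * d for o in orient)
                for i in range(h):
                    for j in range(w):
                        for k in range(kk):
                            a, b, c = i + di, j + dj, k + dk
                            if 0 <= a < h and 0 <= b < w and 0 <= c < kk:
                                counts[q[i, j, k] - 1, q[a, b, c] - 1] += 1
                                counts[q[a, b, c] - 1, q[i, j, k] - 1] += 1
                if counts.sum() == 0:
                    continue
                all_feats.append(haralick(
                    GLCM(counts / counts.sum(), orient, d, 1)))
        assert n_built == 52
        ref = np.mean([f.as_tuple() for f in all_feats], axis=0)
        np.testing.assert_allclose(ours.as_tuple(), ref, atol=1e-12)
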