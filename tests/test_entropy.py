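"""Tests for the fuzzy entropy measures against the brute-force oracle
and their structural invariants."""

import numpy as np
import pytest

from colorfuzen import (ColorImage, EntropyParams, compute_entropy, fuzenc2d,
                        fuzenm2d, fuzenv2d, generate_mix2d_multichannel,
                        MixProcessSpec, phi_pair_2d)
from colorfuzen.entropy import entropy_r_sweep
from colorfuzen.oracle import oracle_entropy, oracle_phi_plane

from conftest import random_image


class TestParams:
    @pytest.mark.parametrize("kw", [dict(m=0), dict(r=0.0), dict(r=-1.0),
                                    dict(n=0.0)])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            EntropyParams(**kw)

    def test_defaults_are_operating_point(self):
        p = EntropyParams()
        assert (p.m, p.n, p.r) == (2, 2.0, 0.15)


class TestPhiPair2D:
    def test_constant_plane_gives_zero(self):
        phi = phi_pair_2d(np.full((10, 10), 3.3), EntropyParams(m=2))
        assert phi.phi_m == 1.0 and phi.phi_m1 == 1.0
        assert phi.entropy == 0.0
        assert phi.n_patterns == 8 * 8

    def test_matches_quadruple_loop_oracle(self):
        plane = np.random.default_rng(11).random((6, 6))
        params = EntropyParams(m=1, r=0.15)
        phi = phi_pair_2d(plane, params)
        phi_m, phi_m1, ent = oracle_phi_plane(plane, params)
        assert abs(phi.phi_m - phi_m) < 1e-12
        assert abs(phi.phi_m1 - phi_m1) < 1e-12
        assert abs(phi.entropy - ent) < 1e-12

    def test_too_small_plane_rejected(self):
        with pytest.raises(ValueError):
            phi_pair_2d(np.zeros((2, 5)), EntropyParams(m=2))

    def test_single_anchor_degenerate(self):
        with pytest.raises(ValueError):
            phi_pair_2d(np.random.default_rng(0).random((3, 3)),
                        EntropyParams(m=2))


class TestOracleEquivalence:
    """Optimized kernels vs literal transcription on small seeded images."""

    @pytest.mark.parametrize("method,m", [("c2d", 2), ("v2d", 1), ("m2d", 2)])
    def test_seeded_random_images(self, method, m):
        for seed in (0, 1, 2):
            img = random_image(seed, 10, 10, 3)
            params = EntropyParams(m=m, r=0.15)
            fast = compute_entropy(img, method, params)
            slow = oracle_entropy(img, params, method)
            slow = slow if isinstance(slow, list) else [slow]
            np.testing.assert_allclose(fast.values, slow, atol=1e-10)

    def test_oracle_c2d_single_channel_equals_phi_plane(self):
        img = random_image(5, 8, 8, 1)
        params = EntropyParams(m=1, r=0.2)
        assert oracle_entropy(img, params, "c2d")[0] == pytest.approx(
            oracle_phi_plane(img.channel(0), params)[2], abs=1e-14)

    def test_oracle_guard_refuses_large_inputs(self):
        img = random_image(0, 40, 40, 3)
        with pytest.raises(RuntimeError, match="guard"):
            oracle_entropy(img, EntropyParams(m=1), "c2d")


class TestZeroLawAndNesting:
    def test_constant_image_all_methods_exactly_zero(self):
        img = ColorImage(np.full((10, 10, 3), 0.42))
        for method in ("c2d", "v2d", "m2d"):
            res = compute_entropy(img, method, EntropyParams(m=1, r=0.1))
            assert all(v == 0.0 for v in res.values)

    @pytest.mark.parametrize("method,m", [("c2d", 1), ("c2d", 2),
                                          ("v2d", 1), ("v2d", 2),
                                          ("m2d", 1), ("m2d", 2)])
    def test_nonnegative_and_nested_phi(self, method, m):
        for seed in range(5):
            img = random_image(100 + seed, 12, 12, 3)
            res = compute_entropy(img, method, EntropyParams(m=m, r=0.2))
            for phi, val in zip(res.phis, res.values):
                assert 0.0 < phi.phi_m1 <= phi.phi_m <= 1.0
                assert val >= 0.0


class TestSymmetries:
    def test_c2d_channel_reversal(self):
        img = random_image(7, 9, 9, 3)
        rev = ColorImage(img.pixels[:, :, ::-1])
        params = EntropyParams(m=2)
        fwd = fuzenc2d(img, params).values
        bwd = fuzenc2d(rev, params).values
        np.testing.assert_allclose(fwd, bwd[::-1], atol=1e-12)

    def test_m2d_channel_permutation_invariant(self):
        img = random_image(8, 9, 9, 3)
        perm = ColorImage(img.pixels[:, :, [2, 0, 1]])
        params = EntropyParams(m=2)
        assert fuzenm2d(img, params).scalar == pytest.approx(
            fuzenm2d(perm, params).scalar, abs=1e-12)


class TestConstraints:
    def test_v2d_m_bound(self):
        img = random_image(1, 10, 10, 3)
        with pytest.raises(ValueError, match="K-1"):
            fuzenv2d(img, EntropyParams(m=3))

    def test_m2d_depth_unconstrained(self):
        img = random_image(1, 10, 10, 3)
        res = fuzenm2d(img, EntropyParams(m=4))
        assert np.isfinite(res.scalar)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            compute_entropy(random_image(0), "x2d", EntropyParams())


class TestRSweep:
    def test_sweep_matches_single_evaluations(self):
        img = random_image(3, 10, 10, 3)
        rs = np.array([0.1, 0.2, 0.4])
        for method in ("c2d", "v2d", "m2d"):
            m = 1 if method == "v2d" else 2
            sweep = np.atleast_2d(entropy_r_sweep(img, method, m, 2.0, rs))
            for qi, r in enumerate(rs):
                res = compute_entropy(img, method, EntropyParams(m=m, r=r))
                if method == "c2d":
                    np.testing.assert_allclose(sweep[:, qi], res.values,
                                               atol=1e-12)
                else:
                    assert sweep[0, qi] == pytest.approx(res.scalar,
                                                         abs=1e-12)


def test_noise_more_irregular_than_periodic():
    """Pure noise must score higher than the pure periodic pattern."""
    spec0 = MixProcessSpec(p=0.0, height=32, width=32)
    spec1 = MixProcessSpec(p=1.0, height=32, width=32)
    periodic = generate_mix2d_multichannel(spec0, (1, 2, 3))
    noise = generate_mix2d_multichannel(spec1, (1, 2, 3))
    params = EntropyParams(m=1, r=0.15)
    for method in ("c2d", "v2d", "m2d"):
        lo = np.mean(compute_entropy(periodic, method, params).values)
        hi = np.mean(compute_entropy(noise, method, params).values)
        assert hi > lo
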