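"""Forward stick+zeppelin signal model, noise, and kernel projections."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre

from dkimicro import (
    FiberConfiguration,
    TissueParams,
    add_rician_noise,
    kappa_from_p2,
    kernel_projection_K_l,
    kernel_response,
    odf_invariant_p_l,
    simulate_voxel,
)
from dkimicro.signal import simulate_watson_voxel

from conftest import random_rotation


class TestKernelResponse:
    def test_zero_b_identity(self, reference_params):
        for c in (0.0, 0.5, 1.0):
            assert kernel_response(0.0, c, reference_params) == 1.0

    def test_pure_stick_transverse(self):
        params = TissueParams(f=1.0, Da=2.0, De_par=1.0, De_perp=0.5)
        for b in (0.5, 1.0, 2.0):
            assert kernel_response(b, 0.0, params) == pytest.approx(1.0, abs=1e-15)

    def test_two_exponential_sum(self, reference_params):
        # f e^{-b Da} + (1-f) e^{-b De_par} at cos_psi = 1
        expected = 0.7 * np.exp(-2.2) + 0.3 * np.exp(-1.8)
        assert kernel_response(1.0, 1.0, reference_params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_domain_errors(self, reference_params):
        with pytest.raises(ValueError):
            kernel_response(-1.0, 0.5, reference_params)
        with pytest.raises(ValueError):
            kernel_response(1.0, 1.5, reference_params)


class TestSimulateVoxel:
    def test_single_stick_along_gradients(self, scheme):
        params = TissueParams(f=1.0, Da=2.0, De_par=1.0, De_perp=0.5)
        # put the stick along each gradient in turn: signal = exp(-b Da)
        fib = FiberConfiguration.single_stick(scheme.bvecs[10])
        sig = simulate_voxel(scheme, fib, params, s0=100.0)
        assert sig[10] == pytest.approx(100.0 * np.exp(-scheme.bvals[10] * 2.0), rel=1e-12)

    def test_isotropic_gaussian_limit(self, scheme, rng):
        params = TissueParams(f=0.0, Da=1.0, De_par=1.1, De_perp=1.1)
        fib = FiberConfiguration(rng.standard_normal((30, 3)))
        sig = simulate_voxel(scheme, fib, params)
        assert np.allclose(sig, np.exp(-scheme.bvals * 1.1), atol=1e-12)

    def test_two_orthogonal_sticks(self, scheme):
        params = TissueParams(f=1.0, Da=2.0, De_par=1.0, De_perp=0.5)
        fib = FiberConfiguration(np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]))
        one_shell = type(scheme)(
            np.array([0.0, 1.0]), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        )
        sig = simulate_voxel(one_shell, fib, params, s0=2.0)
        assert sig[1] == pytest.approx(np.exp(-2.0) + 1.0, rel=1e-12)

    def test_rotation_invariance(self, scheme, reference_params, rng):
        fib = FiberConfiguration.from_watson(kappa_from_p2(0.8), 30, rng)
        base = simulate_voxel(scheme, fib, reference_params)
        for _ in range(3):
            R = random_rotation(rng)
            rot = simulate_voxel(scheme.rotated(R), fib.rotated(R), reference_params)
            assert np.max(np.abs(rot - base)) < 1e-10

    def test_signal_strictly_decreasing_in_b(self, reference_params, rng):
        fib = FiberConfiguration.from_watson(5.0, 30, rng)
        g = rng.standard_normal(3)
        g /= np.linalg.norm(g)
        bs = np.linspace(0.0, 3.0, 20)
        from dkimicro import AcquisitionScheme

        sch = AcquisitionScheme(bs, np.tile(g, (20, 1)))
        sig = simulate_voxel(sch, fib, reference_params)
        assert np.all(np.diff(sig[1:]) < 0)

    def test_watson_series_matches_stick_ensemble(self, scheme, reference_params):
        kappa = kappa_from_p2(0.85)
        exact = simulate_watson_voxel(scheme, kappa, reference_params)
        big = FiberConfiguration.from_watson(
            kappa, 100_000, np.random.default_rng(5)
        )
        mc = simulate_voxel(scheme, big, reference_params)
        assert np.max(np.abs(exact - mc)) < 2e-3


class TestRicianNoise:
    def test_infinite_snr_is_identity(self, rng):
        sig = np.array([1.0, 0.5, 0.2])
        assert np.array_equal(add_rician_noise(sig, np.inf, rng), sig)

    def test_determinism_under_seed(self):
        sig = np.linspace(0.1, 1.0, 50)
        a = add_rician_noise(sig, 25.0, np.random.default_rng(7))
        b = add_rician_noise(sig, 25.0, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_zero_signal_rayleigh_mean(self):
        # |sigma (e1 + i e2)| has mean sigma sqrt(pi/2)
        rng = np.random.default_rng(42)
        draws = add_rician_noise(np.zeros(100_000), 1.0, rng, s0=1.0)
        expected = np.sqrt(np.pi / 2.0)
        se = np.sqrt((2.0 - np.pi / 2.0) / draws.size)
        assert abs(np.mean(draws) - expected) < 3 * se

    def test_invalid_snr(self, rng):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), 0.0, rng)


class TestKernelProjections:
    def test_b0_normalization(self, reference_params):
        assert kernel_projection_K_l(0.0, reference_params, 0) == pytest.approx(1.0, abs=1e-14)
        assert kernel_projection_K_l(0.0, reference_params, 2) == pytest.approx(0.0, abs=1e-14)

    def test_isotropic_kernel(self):
        params = TissueParams(f=0.0, Da=1.0, De_par=0.9, De_perp=0.9)
        for b in (0.5, 1.0, 2.0):
            assert kernel_projection_K_l(b, params, 0) == pytest.approx(
                np.exp(-b * 0.9), rel=1e-12
            )
            assert kernel_projection_K_l(b, params, 2) == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("l", [0, 2])
    def test_matches_doubled_order_quadrature(self, l):
        params = TissueParams(f=1.0, Da=2.0, De_par=1.0, De_perp=0.3)
        x, w = leggauss(128)
        x01 = 0.5 * (x + 1.0)
        w01 = 0.5 * w
        k = 1.0 * np.exp(-1.0 * 2.0 * x01**2)
        oracle = (2 * l + 1) * np.sum(w01 * eval_legendre(l, x01) * k)
        assert kernel_projection_K_l(1.0, params, l) == pytest.approx(oracle, abs=1e-8)

    def test_unsupported_l(self, reference_params):
        with pytest.raises(ValueError):
            kernel_projection_K_l(1.0, reference_params, 3)


class TestOdfInvariants:
    def test_single_stick_normalization(self):
        fib = FiberConfiguration.single_stick()
        assert odf_invariant_p_l(fib, 0) == 1.0
        assert odf_invariant_p_l(fib, 2) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_pair(self):
        fib = FiberConfiguration(np.array([[0, 0, 1.0], [0, 0, -1.0]]))
        assert odf_invariant_p_l(fib, 2) == pytest.approx(1.0, abs=1e-12)

    def test_dense_isotropic_limit(self, rng):
        pts = rng.standard_normal((10_000, 3))
        fib = FiberConfiguration(pts)
        assert odf_invariant_p_l(fib, 2) < 0.05

    def test_rotation_invariance(self, rng):
        fib = FiberConfiguration.from_watson(8.0, 30, rng)
        base = odf_invariant_p_l(fib, 2)
        for _ in range(3):
            rot = odf_invariant_p_l(fib.rotated(random_rotation(rng)), 2)
            assert abs(rot - base) < 1e-10

    def test_odd_l_rejected(self):
        with pytest.raises(ValueError):
            odf_invariant_p_l(FiberConfiguration.single_stick(), 3)
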