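"""Constrained WLLS kurtosis-tensor estimation and derived metrics."""

import numpy as np
import pytest

from dkimicro import (
    FiberConfiguration,
    TissueParams,
    axisymmetric_components,
    cumulant_signal,
    fit_dki_wlls,
    forward_components,
    kappa_from_p2,
    scalar_metrics,
    simulate_voxel,
)
from dkimicro.dki import KurtosisFit, W_IDX

from conftest import random_rotation


def interior_tensors(rng, scale=0.3):
    """Random (D, W15) pair safely inside the directional constraints."""
    A = rng.standard_normal((3, 3)) * 0.2
    D = A @ A.T + np.diag([1.2, 0.9, 0.7])
    W15 = np.zeros(15)
    W15[:3] = rng.uniform(0.1, scale, 3)       # diagonal quartic terms
    W15[9:12] = rng.uniform(0.05, scale / 2, 3)  # paired terms
    return D, W15


class TestWllsExactness:
    def test_cumulant_signal_recovery(self, scheme, rng):
        for _ in range(5):
            D, W15 = interior_tensors(rng)
            sig = cumulant_signal(scheme, 800.0, D, W15)
            fit = fit_dki_wlls(scheme, sig)
            assert not fit.constrained
            assert np.max(np.abs(fit.D - D)) < 1e-10
            assert np.max(np.abs(fit.W15 - W15)) < 1e-10
            assert fit.s0 == pytest.approx(800.0, rel=1e-12)

    def test_isotropic_monoexponential(self, scheme):
        sig = np.exp(-scheme.bvals * 1.3)
        fit = fit_dki_wlls(scheme, sig)
        assert np.max(np.abs(fit.D - 1.3 * np.eye(3))) < 1e-10
        assert np.max(np.abs(fit.W15)) < 1e-9

    def test_isotropic_bigaussian_mixture(self):
        # equal fractions of D=1 and D=2: MD = 1.5, K = 3 Var/Mean^2 = 1/3.
        # Evaluated in the small-b regime where the cumulant identity is
        # uncontaminated by higher-order terms of the two-exponential signal.
        from dkimicro import study_protocol

        small = study_protocol(shells=(0.1, 0.15, 0.2))
        sig = 0.5 * np.exp(-small.bvals * 1.0) + 0.5 * np.exp(-small.bvals * 2.0)
        met = scalar_metrics(fit_dki_wlls(small, sig, constrained=False))
        assert met.md == pytest.approx(1.5, abs=1e-3)
        assert met.mk == pytest.approx(1.0 / 3.0, abs=5e-3)

    def test_input_validation(self, scheme):
        with pytest.raises(ValueError):
            fit_dki_wlls(scheme, np.ones(scheme.n_volumes - 1))
        with pytest.raises(ValueError):
            fit_dki_wlls(scheme, np.full(scheme.n_volumes, -1.0))


class TestScalarMetrics:
    def test_zero_kurtosis_tensor(self, scheme):
        D = np.diag([1.8, 0.6, 0.6])
        sig = cumulant_signal(scheme, 1.0, D, np.zeros(15))
        met = scalar_metrics(fit_dki_wlls(scheme, sig, constrained=False))
        assert abs(met.ak) < 1e-9 and abs(met.rk) < 1e-9 and abs(met.mk) < 1e-9
        assert met.ad == pytest.approx(1.8, abs=1e-10)
        assert met.rd == pytest.approx(0.6, abs=1e-10)

    def test_isotropic_fa_zero(self, scheme):
        sig = np.exp(-scheme.bvals * 1.0)
        met = scalar_metrics(fit_dki_wlls(scheme, sig))
        assert met.fa == pytest.approx(0.0, abs=1e-8)

    def test_prolate_fa_closed_form(self):
        dpar, dperp = 2.0, 0.5
        fit = KurtosisFit(s0=1.0, D=np.diag([dpar, dperp, dperp]), W15=np.zeros(15))
        met = scalar_metrics(fit)
        # two-distinct-eigenvalue closed form
        lam = np.array([dpar, dperp, dperp])
        md = lam.mean()
        expected = np.sqrt(1.5 * np.sum((lam - md) ** 2) / np.sum(lam**2))
        assert met.fa == pytest.approx(expected, abs=1e-12)
        assert met.ad >= met.rd

    def test_metrics_rotation_invariant(self, scheme, rng):
        D, W15 = interior_tensors(rng)
        sig = cumulant_signal(scheme, 1.0, D, W15)
        met = scalar_metrics(fit_dki_wlls(scheme, sig))
        for _ in range(3):
            R = random_rotation(rng)
            met_r = scalar_metrics(fit_dki_wlls(scheme.rotated(R), sig))
            for name in ("ad", "rd", "md", "fa", "ak", "rk", "mk"):
                assert getattr(met_r, name) == pytest.approx(
                    getattr(met, name), abs=1e-8
                ), name


def exactly_axisymmetric_fit(rng, axis=np.array([0.0, 0.0, 1.0])):
    """Random exactly-axisymmetric (D, W) about the z-axis."""
    dpar, dperp = rng.uniform(1.2, 2.2), rng.uniform(0.3, 0.8)
    D = np.diag([dperp, dperp, dpar])
    # axisymmetric quartic form: W(g) = w0 + w2 P2(gz) + w4 P4(gz)
    w0, w2, w4 = rng.uniform(0.2, 0.8), rng.uniform(-0.2, 0.3), rng.uniform(-0.2, 0.2)
    from scipy.special import eval_legendre

    from dkimicro.dki import _w_monomials, sphere_quadrature

    # solve for the 15 components reproducing the Legendre profile on a frame
    dirs, _ = sphere_quadrature(12, 24)
    target = w0 + w2 * eval_legendre(2, dirs[:, 2]) + w4 * eval_legendre(4, dirs[:, 2])
    M = _w_monomials(dirs)
    W15, *_ = np.linalg.lstsq(M, target, rcond=None)
    return KurtosisFit(s0=1.0, D=D, W15=W15)


class TestAxisymmetricComponents:
    def test_prolate_hand_values(self):
        fit = KurtosisFit(s0=1.0, D=np.diag([0.5, 0.5, 2.0]), W15=np.zeros(15))
        ax = axisymmetric_components(fit, axis=np.array([0.0, 0.0, 1.0]))
        assert ax["D0"] == pytest.approx(1.0, abs=1e-12)
        assert ax["D2"] == pytest.approx(1.0, abs=1e-12)
        assert ax["D_par"] == pytest.approx(2.0) and ax["D_perp"] == pytest.approx(0.5)

    def test_isotropic_kurtosis_content(self, scheme):
        # isotropic D and W: all directional kurtosis K -> W2 = W4 = 0, W0 = K
        K = 0.6
        D = np.eye(3) * 1.2
        W15 = np.zeros(15)
        W15[:3] = K            # W_iiii = K
        W15[9:12] = K / 3.0    # W_iijj = K/3 makes W(g) = K for all g
        fit = KurtosisFit(s0=1.0, D=D, W15=W15)
        ax = axisymmetric_components(fit, axis=np.array([0.0, 0.0, 1.0]))
        assert ax["W2"] == pytest.approx(0.0, abs=1e-12)
        assert ax["W4"] == pytest.approx(0.0, abs=1e-12)
        assert ax["W0"] == pytest.approx(K, abs=1e-12)

    def test_kurtosis_conversions_against_directional_oracle(self, rng):
        """AK = W_par Dbar^2/D_par^2 and RK = W_perp Dbar^2/D_perp^2 must
        agree with directly evaluated apparent kurtosis for axisymmetric
        tensors."""
        for _ in range(5):
            fit = exactly_axisymmetric_fit(rng)
            ax = axisymmetric_components(fit, axis=np.array([0.0, 0.0, 1.0]))
            md = fit.md
            ak_direct = float(fit.k_app(np.array([[0.0, 0.0, 1.0]]))[0])
            rk_direct = float(fit.k_app(np.array([[1.0, 0.0, 0.0]]))[0])
            assert ax["W_par"] * md**2 / ax["D_par"] ** 2 == pytest.approx(
                ak_direct, abs=1e-10
            )
            assert ax["W_perp"] * md**2 / ax["D_perp"] ** 2 == pytest.approx(
                rk_direct, abs=1e-10
            )

    def test_wbar_is_full_trace_fifth(self, rng):
        fit = exactly_axisymmetric_fit(rng)
        w = dict(zip(W_IDX, fit.W15))
        tr = (w[(0, 0, 0, 0)] + w[(1, 1, 1, 1)] + w[(2, 2, 2, 2)]
              + 2 * (w[(0, 0, 1, 1)] + w[(0, 0, 2, 2)] + w[(1, 1, 2, 2)]))
        ax = axisymmetric_components(fit)
        assert ax["W_bar"] == pytest.approx(tr / 5.0, rel=1e-12)


class TestConstraints:
    def test_violation_is_enforced_and_flagged(self, scheme):
        # a cumulant signal engineered so directional kurtosis exceeds the
        # b_max/(3 D_app) bound: the solver must activate and satisfy it
        D = np.diag([1.6, 1.0, 0.8])
        W15 = np.zeros(15)
        W15[:3] = [0.4, 0.5, 0.9]     # K_app along z exceeds the bound
        W15[9:12] = [0.15, 0.2, 0.1]
        sig = cumulant_signal(scheme, 1.0, D, W15)
        fit = fit_dki_wlls(scheme, sig)
        assert fit.constrained
        from dkimicro.dki import _constraint_matrix

        G = _constraint_matrix(scheme)
        x = np.concatenate([[np.log(fit.s0)],
                            [fit.D[0, 0], fit.D[1, 1], fit.D[2, 2],
                             fit.D[0, 1], fit.D[0, 2], fit.D[1, 2]],
                            fit.md**2 * fit.W15])
        assert np.min(G @ x) > -1e-8

    def test_interior_fit_not_flagged(self, scheme, rng):
        D, W15 = interior_tensors(rng)
        sig = cumulant_signal(scheme, 1.0, D, W15)
        assert not fit_dki_wlls(scheme, sig).constrained


class TestMomentSystemConsistency:
    def test_watson_voxel_components_match_forward_relations(self, scheme, reference_params):
        """DKI components of a simulated Watson voxel agree with the moment
        system evaluated at the true parameters, within the empirically
        established b^2-truncation envelope at b_max = 2."""
        from dkimicro.signal import simulate_watson_voxel

        p2 = 0.85
        sig = simulate_watson_voxel(scheme, kappa_from_p2(p2), reference_params)
        fit = fit_dki_wlls(scheme, sig, constrained=False)
        ax = axisymmetric_components(fit, axis=np.array([0.0, 0.0, 1.0]))
        expected = forward_components(reference_params, p2)
        # envelope measured empirically at b_max = 2 (errors scale away as
        # the shells shrink, confirming they are truncation, not convention)
        for key, tol in (("D0", 0.01), ("D2", 0.02), ("W0", 0.05), ("W2", 0.2), ("W4", 0.1)):
            assert ax[key] == pytest.approx(expected[key], abs=tol), key
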