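"""Diffusion kurtosis tensor estimation and derived metrics.

The cumulant expansion of the log signal truncated at b^2,

    ln S/S0 = -b sum_ij g_i g_j D_ij
              + (b^2/6) Dbar^2 sum_ijkl g_i g_j g_k g_l W_ijkl,

is linear in (ln S0, D, V) with V = Dbar^2 W, so estimation proceeds by
weighted linear least squares: an ordinary pass provides predicted signals
whose squares serve as weights for a second, heteroscedasticity-corrected
pass. Directional plausibility constraints

    D_app(g) > 0,   0 < K_app(g) < b_max / (3 D_app(g))

are linear in the same parameters and, when violated by the unconstrained
fit on a fixed evaluation set of directions, are enforced by
inequality-constrained least squares (least-distance programming solved
through a single non-negative least-squares call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import nnls

from .acquisition import AcquisitionScheme, fibonacci_sphere

__all__ = [
    "KurtosisFit",
    "DkiMetrics",
    "fit_dki_wlls",
    "scalar_metrics",
    "axisymmetric_components",
    "cumulant_signal",
    "dki_design_matrix",
]

# unique tensor components in fixed order, with multiplicities
D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
D_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

W_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]


def _w_mult():
    out = []
    for idx in W_IDX:
        counts = [idx.count(a) for a in set(idx)]
        m = 24
        for c in counts:
            for k in range(2, c + 1):
                m //= k
        out.append(float(m))
    return np.array(out)


W_MULT = _w_mult()

N_CONSTRAINT_SPHERE = 60  # extra evaluation directions beyond the acquisition set
MK_QUAD_THETA = 24        # polar Gauss-Legendre order for spherical averaging
MK_QUAD_PHI = 48          # azimuthal points (1152 directions total)
RING_POINTS = 64          # ring average of the smooth periodic K_app integrand


def _d_monomials(g: np.ndarray) -> np.ndarray:
    return np.stack([g[:, i] * g[:, j] for i, j in D_IDX], axis=1) * D_MULT


def _w_monomials(g: np.ndarray) -> np.ndarray:
    return np.stack(
        [g[:, i] * g[:, j] * g[:, k] * g[:, l] for i, j, k, l in W_IDX], axis=1
    ) * W_MULT


def dki_design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """(N, 22) design for parameters (ln S0, D_6, V_15) with V = Dbar^2 W."""
    ones = np.ones((bvals.size, 1))
    Ad = -bvals[:, None] * _d_monomials(bvecs)
    Aw = (bvals[:, None] ** 2 / 6.0) * _w_monomials(bvecs)
    return np.hstack([ones, Ad, Aw])


def _vec_to_tensor_D(d6: np.ndarray) -> np.ndarray:
    D = np.zeros((3, 3))
    for v, (i, j) in zip(d6, D_IDX):
        D[i, j] = v
        D[j, i] = v
    return D


@dataclass(frozen=True)
class KurtosisFit:
    """Fitted b=0 signal, diffusion tensor and (unitless) kurtosis tensor."""

    s0: float
    D: np.ndarray                 # (3, 3) symmetric, um^2/ms
    W15: np.ndarray               # 15 unique components of W (Dbar^2 convention)
    constrained: bool = False     # constraint enforcement was activated
    success: bool = True
    condition_number: float = np.nan

    @property
    def md(self) -> float:
        return float(np.trace(self.D) / 3.0)

    def d_app(self, g: np.ndarray) -> np.ndarray:
        """Apparent diffusivity along unit direction(s) g."""
        g = np.atleast_2d(g)
        return _d_monomials(g) @ np.array([self.D[i, j] for i, j in D_IDX])

    def w_app(self, g: np.ndarray) -> np.ndarray:
        """Directional kurtosis-tensor contraction sum W_ijkl g_i g_j g_k g_l."""
        g = np.atleast_2d(g)
        return _w_monomials(g) @ self.W15

    def k_app(self, g: np.ndarray) -> np.ndarray:
        """Directional apparent kurtosis K_app = Dbar^2 W(g) / D_app(g)^2."""
        return self.md**2 * self.w_app(g) / self.d_app(g) ** 2

    @property
    def w_trace(self) -> float:
        """Full trace sum_i sum_j W_iijj."""
        w = dict(zip(W_IDX, self.W15))
        return float(
            w[(0, 0, 0, 0)] + w[(1, 1, 1, 1)] + w[(2, 2, 2, 2)]
            + 2.0 * (w[(0, 0, 1, 1)] + w[(0, 0, 2, 2)] + w[(1, 1, 2, 2)])
        )


@dataclass(frozen=True)
class DkiMetrics:
    ad: float
    rd: float
    md: float
    fa: float
    ak: float
    rk: float
    mk: float
    principal_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))


def cumulant_signal(
    scheme: AcquisitionScheme, s0: float, D: np.ndarray, W15: np.ndarray
) -> np.ndarray:
    """Exact signal of the truncated cumulant model for given tensors."""
    fit = KurtosisFit(s0=s0, D=np.asarray(D, float), W15=np.asarray(W15, float))
    b = scheme.bvals
    g = scheme.bvecs
    lnS = -b * fit.d_app(g) + (b**2 / 6.0) * fit.md**2 * fit.w_app(g)
    lnS[scheme.b0_mask] = 0.0
    return s0 * np.exp(lnS)


_constraint_cache: dict = {}


def _constraint_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """Rows G such that G x >= 0 encodes the directional constraints."""
    key = (scheme.bvals.tobytes(), scheme.bvecs.tobytes(),
           scheme.frame_rotation.tobytes())
    cached = _constraint_cache.get(key)
    if cached is not None:
        return cached
    dirs = scheme.bvecs[~scheme.b0_mask]
    # deduplicate acquisition directions (shells may share a table)
    uniq = [dirs[0]]
    for d in dirs[1:]:
        if all(min(np.sum((d - u) ** 2), np.sum((d + u) ** 2)) > 1e-10 for u in uniq):
            uniq.append(d)
    # the auxiliary sphere is attached to the gradient frame so the
    # constrained estimator stays rotation covariant
    sphere = fibonacci_sphere(N_CONSTRAINT_SPHERE) @ scheme.frame_rotation.T
    g = np.vstack([np.array(uniq), sphere])
    b_max = float(np.max(scheme.bvals))
    md_ = _d_monomials(g)
    mw_ = _w_monomials(g)
    n = g.shape[0]
    z1 = np.zeros((n, 1))
    G_dapp = np.hstack([z1, md_, np.zeros((n, 15))])          # D_app >= 0
    G_kpos = np.hstack([z1, np.zeros((n, 6)), mw_])           # V(g)  >= 0
    G_kmax = np.hstack([z1, (b_max / 3.0) * md_, -mw_])       # V(g) <= b_max D_app / 3
    G = np.vstack([G_dapp, G_kpos, G_kmax])
    _constraint_cache[key] = G
    return G


def _ldp_constrained_lstsq(A: np.ndarray, y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """min ||A x - y|| subject to G x >= 0 via LDP reduction to NNLS."""
    Q, R = np.linalg.qr(A)
    x_ls = np.linalg.solve(R, Q.T @ y)
    Ghat = np.linalg.solve(R.T, G.T).T       # G R^{-1}
    h = -G @ x_ls
    n = Ghat.shape[1]
    E = np.vstack([Ghat.T, h[None, :]])      # (n+1, m)
    fvec = np.zeros(n + 1)
    fvec[-1] = 1.0
    u, _ = nnls(E, fvec)
    r = E @ u - fvec
    if abs(r[-1]) < 1e-12:
        raise np.linalg.LinAlgError("incompatible inequality constraints")
    z = -r[:-1] / r[-1]
    return x_ls + np.linalg.solve(R, z)


def fit_dki_wlls(
    scheme: AcquisitionScheme,
    signal: np.ndarray,
    constrained: bool = True,
) -> KurtosisFit:
    """Two-pass weighted linear least squares DKI fit.

    Pass one is ordinary least squares on the log signal; its predicted
    signals squared are the weights of the second pass (the optimal
    weighting under additive noise on S). With ``constrained`` the
    directional plausibility constraints are checked on the evaluation set
    and enforced when violated.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (scheme.n_volumes,):
        raise ValueError("signal length does not match the scheme")
    if np.any(signal <= 0):
        raise ValueError("signals must be positive for the log-linear fit")
    if scheme.shells.size < 2 or scheme.n_volumes < 22:
        raise ValueError("need >= 22 volumes spanning >= 2 nonzero shells")

    A = dki_design_matrix(scheme.bvals, scheme.bvecs)
    y = np.log(signal)

    x_ols, *_ = np.linalg.lstsq(A, y, rcond=None)
    w = np.exp(A @ x_ols)  # predicted signals
    Aw = A * w[:, None]
    yw = y * w
    x, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    cond = float(np.linalg.cond(Aw))

    was_constrained = False
    success = True
    if constrained:
        G = _constraint_matrix(scheme)
        if np.any(G @ x < -1e-10):
            was_constrained = True
            try:
                x = _ldp_constrained_lstsq(Aw, yw, G)
            except np.linalg.LinAlgError:
                success = False

    s0 = float(np.exp(x[0]))
    D = _vec_to_tensor_D(x[1:7])
    md = float(np.trace(D) / 3.0)
    W15 = x[7:] / md**2 if md > 0 else np.full(15, np.nan)
    if md <= 0:
        success = False
    return KurtosisFit(
        s0=s0, D=D, W15=W15, constrained=was_constrained, success=success,
        condition_number=cond,
    )


def sphere_quadrature(n_theta: int = MK_QUAD_THETA, n_phi: int = MK_QUAD_PHI):
    """Deterministic product quadrature on the sphere.

    Gauss-Legendre in the polar cosine times a uniform azimuthal rule;
    weights sum to one, so a weighted sum is the spherical mean. Converges
    spectrally for the smooth directional-kurtosis integrand, keeping
    numerically averaged metrics rotation invariant to well below 1e-8.
    """
    xc, wc = leggauss(n_theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    ct = np.repeat(xc, n_phi)
    st = np.sqrt(np.clip(1.0 - ct**2, 0.0, None))
    ph = np.tile(phi, n_theta)
    dirs = np.column_stack([st * np.cos(ph), st * np.sin(ph), ct])
    w = np.repeat(wc, n_phi) / (2.0 * n_phi)
    return dirs, w


_MK_DIRS, _MK_WEIGHTS = sphere_quadrature()


def principal_axis(D: np.ndarray) -> np.ndarray:
    """Principal eigenvector with a deterministic sign convention.

    The eigenvector of the largest eigenvalue, oriented so its largest-
    magnitude component is positive (ties on eigenvalues resolve to the
    last column returned by the symmetric eigensolver, which is itself
    deterministic for a given matrix).
    """
    _, vecs = np.linalg.eigh(D)
    v = vecs[:, -1]
    lead = np.argmax(np.abs(v))
    return v if v[lead] > 0 else -v


def _perp_ring(axis: np.ndarray, n: int = RING_POINTS) -> np.ndarray:
    """Equally spaced unit vectors in the plane perpendicular to axis."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    phi = 2.0 * np.pi * np.arange(n) / n
    return np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)


def scalar_metrics(fit: KurtosisFit) -> DkiMetrics:
    """AD/RD/MD/FA from the diffusion tensor eigenvalues; AK/RK/MK from
    directional apparent kurtosis (MK as a numerical spherical mean over a
    fixed 1152-direction product quadrature, RK over a perpendicular ring)."""
    evals = np.linalg.eigvalsh(fit.D)
    axis = principal_axis(fit.D)
    md = fit.md
    ad = float(evals[-1])
    rd = float(np.mean(evals[:2]))
    denom = np.sum(evals**2)
    fa = 0.0 if denom == 0 else float(
        np.sqrt(1.5 * np.sum((evals - md) ** 2) / denom)
    )
    mk = float(np.sum(_MK_WEIGHTS * fit.k_app(_MK_DIRS)))
    ak = float(fit.k_app(axis[None, :])[0])
    rk = float(np.mean(fit.k_app(_perp_ring(axis))))
    return DkiMetrics(ad=ad, rd=rd, md=md, fa=fa, ak=ak, rk=rk, mk=mk, principal_axis=axis)


def axisymmetric_components(fit: KurtosisFit, axis: np.ndarray | None = None) -> dict:
    """Axially symmetric tensor components about ``axis``.

    Returns D_par, D_perp, W_par, W_perp, W_bar and the Legendre-basis set
    {D0, D2, W0, W2, W4} used by the model inversion:

        D0 = (D_par + 2 D_perp)/3          D2 = (2/3)(D_par - D_perp)
        W0 = W_bar                          (W_bar = Tr(W)/5)
        W2 = (3 W_par + 5 W_bar - 8 W_perp)/7
        W4 = (4/7)(W_par - 3 W_bar + 2 W_perp)

    W_par and W_perp are directional contractions of W (perpendicular as a
    ring average), chosen so AK = W_par Dbar^2 / D_par^2 and
    RK = W_perp Dbar^2 / D_perp^2 hold exactly for axisymmetric tensors.
    """
    a = principal_axis(fit.D) if axis is None else np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    d_par = float(a @ fit.D @ a)
    d_perp = float((np.trace(fit.D) - d_par) / 2.0)
    w_bar = fit.w_trace / 5.0
    w_par = float(fit.w_app(a[None, :])[0])
    w_perp = float(np.mean(fit.w_app(_perp_ring(a))))
    return {
        "D_par": d_par,
        "D_perp": d_perp,
        "W_par": w_par,
        "W_perp": w_perp,
        "W_bar": w_bar,
        "D0": (d_par + 2.0 * d_perp) / 3.0,
        "D2": (2.0 / 3.0) * (d_par - d_perp),
        "W0": w_bar,
        "W2": (3.0 * w_par + 5.0 * w_bar - 8.0 * w_perp) / 7.0,
        "W4": (4.0 / 7.0) * (w_par - 3.0 * w_bar + 2.0 * w_perp),
    }
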