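"""Two-compartment stick+zeppelin forward model.

The diffusion-weighted signal from a single fiber segment oriented along
``n`` with gradient direction ``g`` (xi = g.n) is

    K(b, xi) = f exp(-b Da xi^2)
               + (1 - f) exp(-b De_perp - b (De_par - De_perp) xi^2)

i.e. a "stick" (zero-radius cylinder) for intra-neurite water with
longitudinal diffusivity Da, plus an axially symmetric Gaussian
("zeppelin") for extra-neurite water. A voxel's signal is the kernel
averaged over the fiber orientation distribution. Exchange, finite
diffusion time, and compartmental T2 differences are all outside this
model's assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre

from .acquisition import AcquisitionScheme
from .watson import sample_watson

__all__ = [
    "TissueParams",
    "FiberConfiguration",
    "kernel_response",
    "simulate_voxel",
    "simulate_watson_voxel",
    "add_rician_noise",
    "kernel_projection_K_l",
    "odf_invariant_p_l",
]

# fixed-order Gauss-Legendre rule on [0, 1]; the integrand is smooth and
# antipodally even so the half interval suffices
_GL_ORDER = 64
_gl_x, _gl_w = leggauss(_GL_ORDER)
_GL_X = 0.5 * (_gl_x + 1.0)
_GL_W = 0.5 * _gl_w


@dataclass(frozen=True)
class TissueParams:
    """Scalar compartment parameters (diffusivities in um^2/ms)."""

    f: float          # intra-neurite signal fraction
    Da: float         # intra-neurite longitudinal diffusivity
    De_par: float     # extra-neurite longitudinal diffusivity
    De_perp: float    # extra-neurite transverse diffusivity

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if min(self.Da, self.De_par, self.De_perp) < 0:
            raise ValueError("diffusivities must be >= 0")

    @property
    def delta_e(self) -> float:
        """Extra-neurite diffusivity anisotropy De_par - De_perp."""
        return self.De_par - self.De_perp

    def as_array(self) -> np.ndarray:
        return np.array([self.f, self.Da, self.De_par, self.De_perp])


@dataclass(frozen=True)
class FiberConfiguration:
    """A set of equally weighted fiber segments (delta-mixture ODF).

    ``kappa``/``mu`` record the generating Watson distribution when the
    segments were sampled from one; they are metadata, not constraints.
    """

    orientations: np.ndarray
    kappa: Optional[float] = None
    mu: Optional[np.ndarray] = None

    def __post_init__(self):
        ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        if ori.ndim != 2 or ori.shape[1] != 3 or ori.shape[0] < 1:
            raise ValueError("orientations must be (N, 3) with N >= 1")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length orientation")
        ori = ori / norms[:, None]
        object.__setattr__(self, "orientations", ori)

    @property
    def n_segments(self) -> int:
        return self.orientations.shape[0]

    @classmethod
    def single_stick(cls, axis=(0.0, 0.0, 1.0)) -> "FiberConfiguration":
        return cls(np.asarray(axis, dtype=float)[None, :], kappa=np.inf)

    @classmethod
    def from_watson(
        cls, kappa: float, n: int, rng: np.random.Generator, mu=(0.0, 0.0, 1.0)
    ) -> "FiberConfiguration":
        mu = np.asarray(mu, dtype=float)
        return cls(sample_watson(kappa, mu, n, rng), kappa=kappa, mu=mu)

    def rotated(self, R: np.ndarray) -> "FiberConfiguration":
        mu = None if self.mu is None else R @ self.mu
        return FiberConfiguration(self.orientations @ R.T, kappa=self.kappa, mu=mu)


def kernel_response(b, cos_psi, params: TissueParams):
    """Single-segment signal fraction K(b, cos_psi); broadcasts over inputs."""
    b = np.asarray(b, dtype=float)
    cos_psi = np.asarray(cos_psi, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if np.any(np.abs(cos_psi) > 1.0 + 1e-12):
        raise ValueError("|cos_psi| must be <= 1")
    c2 = np.clip(cos_psi, -1.0, 1.0) ** 2
    intra = params.f * np.exp(-b * params.Da * c2)
    extra = (1.0 - params.f) * np.exp(-b * params.De_perp - b * params.delta_e * c2)
    out = intra + extra
    return float(out) if out.ndim == 0 else out


def simulate_voxel(
    scheme: AcquisitionScheme,
    fibers: FiberConfiguration,
    params: TissueParams,
    s0: float = 1.0,
) -> np.ndarray:
    """Noise-free signal vector, one value per scheme volume.

    Diffusion-weighted volumes carry s0 times the kernel averaged over the
    fiber segments; b=0 volumes carry s0.
    """
    cosines = scheme.bvecs @ fibers.orientations.T  # (n_vol, n_seg)
    sig = np.mean(kernel_response(scheme.bvals[:, None], cosines, params), axis=1)
    sig[scheme.b0_mask] = 1.0
    return s0 * sig


def add_rician_noise(
    signal: np.ndarray, snr: float, rng: np.random.Generator, s0: float = 1.0
) -> np.ndarray:
    """Rician-corrupted magnitude signal with sigma = s0 / snr.

    Each value becomes |v + sigma (eps1 + i eps2)| with independent standard
    normal eps; deterministic for a seeded generator.
    """
    if not snr > 0:
        raise ValueError("snr must be > 0")
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("signal must be non-negative")
    if np.isinf(snr):
        return signal.copy()
    sigma = s0 / snr
    re = signal + sigma * rng.standard_normal(signal.shape)
    im = sigma * rng.standard_normal(signal.shape)
    return np.hypot(re, im)


def kernel_projection_K_l(b, params: TissueParams, l: int):
    """Legendre projection K_l(b) = (2l+1) * int_0^1 K(b, x) P_l(x) dx.

    Normalized so K_0(0) = 1 and so that the rotational-invariant signal
    decomposition factorizes as S_l(b) = p_l K_l(b). Evaluated with a fixed
    64-point Gauss-Legendre rule; broadcasts over an array of b-values.
    """
    if l not in (0, 2, 4):
        raise ValueError("l must be one of 0, 2, 4")
    b = np.asarray(b, dtype=float)
    k = kernel_response(b[..., None], _GL_X, params)  # (..., 64)
    out = (2 * l + 1) * np.sum(_GL_W * eval_legendre(l, _GL_X) * k, axis=-1)
    return float(out) if out.ndim == 0 else out


def simulate_watson_voxel(
    scheme: AcquisitionScheme,
    kappa: float,
    params: TissueParams,
    mu=(0.0, 0.0, 1.0),
    s0: float = 1.0,
    lmax: int = 16,
) -> np.ndarray:
    """Noise-free signal for an exactly-Watson ODF (no stick sampling).

    Uses the axisymmetric convolution series
    S(g) = sum_l p_l^W(kappa) K_l(b) P_l(g . mu), truncated at ``lmax``;
    the Watson Legendre moments beyond degree 4 are evaluated by
    quadrature. This is the infinite-segment limit of ``simulate_voxel``
    with Watson-sampled fibers.
    """
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    xq, wq = leggauss(200)
    # exponent shifted by -kappa for overflow safety; the shift cancels in p_l
    dens = np.exp(kappa * (xq**2 - 1.0)) if np.isfinite(kappa) else None
    z = np.sum(wq * dens) if dens is not None else None
    cosg = scheme.bvecs @ mu
    sig = np.zeros(scheme.n_volumes)
    for l in range(0, lmax + 1, 2):
        if dens is None or kappa > 1e5:
            pl = 1.0  # delta-ODF limit; the quadrature degenerates here
        else:
            pl = float(np.sum(wq * dens * eval_legendre(l, xq)) / z)
        k = kernel_response(scheme.bvals[:, None], _GL_X, params)
        kl = (2 * l + 1) * np.sum(_GL_W * eval_legendre(l, _GL_X) * k, axis=-1)
        sig += pl * kl * eval_legendre(l, cosg)
    sig[scheme.b0_mask] = 1.0
    return s0 * sig


def odf_invariant_p_l(fibers: FiberConfiguration, l: int) -> float:
    """Rotational invariant p_l of the delta-mixture ODF.

    Normalized so that a single stick gives p_l = 1 and a dense isotropic
    set gives p_l -> 0 for l > 0; p_0 is identically 1. Computed via the
    spherical-harmonic addition theorem,
    p_l^2 = (1/N^2) sum_ij P_l(n_i . n_j), which is manifestly invariant
    under joint rotation and antipodal flips of the segments.
    """
    if l % 2 != 0 or l < 0:
        raise ValueError("l must be a non-negative even integer")
    if l == 0:
        return 1.0
    n = fibers.orientations
    gram = np.clip(n @ n.T, -1.0, 1.0)
    val = float(np.mean(eval_legendre(l, gram)))
    return float(np.sqrt(max(val, 0.0)))
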