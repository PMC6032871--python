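"""Real even spherical harmonics and per-shell rotational invariants.

Conventions (used consistently for signal and ODF coefficients): the basis
is real, orthonormal on the sphere, restricted to even degrees (the
diffusion signal is antipodally symmetric). The per-shell invariants are

    S_l(b) = sqrt( (2l+1) / (4 pi) * sum_m c_lm(b)^2 )

which makes S_0(0) = 1 for b=0-normalized data and factorizes the
stick+zeppelin signal as S_l(b) = p_l K_l(b) with the kernel projections
``kernel_projection_K_l`` and ODF invariants ``odf_invariant_p_l``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .acquisition import AcquisitionScheme

__all__ = ["real_even_sh_basis", "sh_decompose_shell", "rotational_invariants",
           "shell_invariants", "RotInvSeries"]

CONDITION_LIMIT = 1e6


def _even_lm(lmax: int):
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def real_even_sh_basis(dirs: np.ndarray, lmax: int) -> np.ndarray:
    """Design matrix of real orthonormal even-degree SH sampled at dirs."""
    dirs = np.atleast_2d(dirs)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    cols = []
    for l, m in _even_lm(lmax):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            cols.append(y.real)
        elif m > 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
        else:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
    return np.stack(cols, axis=1)


def sh_decompose_shell(signals: np.ndarray, dirs: np.ndarray, lmax: int):
    """Least-squares real even-SH coefficients of one shell.

    Antipodal symmetrization is implicit in the even-degree basis. Returns
    (coefficients keyed by (l, m), condition number of the design).
    """
    if lmax % 2 != 0:
        raise ValueError("lmax must be even")
    lm = _even_lm(lmax)
    if len(signals) < len(lm):
        raise ValueError(
            f"need >= {len(lm)} directions for lmax={lmax}, got {len(signals)}"
        )
    B = real_even_sh_basis(dirs, lmax)
    cond = float(np.linalg.cond(B))
    if cond > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            f"ill-conditioned SH design (cond={cond:.3g})"
        )
    coef, *_ = np.linalg.lstsq(B, np.asarray(signals, float), rcond=None)
    return dict(zip(lm, coef)), cond


def rotational_invariants(coeffs: dict) -> dict:
    """Rotation-invariant magnitudes S_l from SH coefficients."""
    lmax = max(l for l, _ in coeffs)
    out = {}
    for l in range(0, lmax + 1, 2):
        ssq = sum(v**2 for (ll, _), v in coeffs.items() if ll == l)
        out[l] = float(np.sqrt((2 * l + 1) / (4.0 * np.pi) * ssq))
    return out


@dataclass(frozen=True)
class RotInvSeries:
    """Per-shell rotational invariants of a b=0-normalized voxel signal."""

    shells: np.ndarray            # nonzero b-values, ascending
    S0: np.ndarray                # l=0 invariant per shell
    S2: np.ndarray                # l=2 invariant per shell
    coeffs: tuple = field(default=(), repr=False)   # per-shell SH coefficient dicts
    condition_numbers: np.ndarray = field(default_factory=lambda: np.array([]))


def shell_invariants(
    scheme: AcquisitionScheme, signal: np.ndarray, lmax: int = 4
) -> RotInvSeries:
    """Decompose each shell of a voxel signal and collect S_0, S_2.

    The signal is normalized by the mean of the b=0 volumes first. lmax=4
    is supported by 30-direction shells; only l=0,2 feed the invariant fit.
    """
    signal = np.asarray(signal, dtype=float)
    s0 = float(np.mean(signal[scheme.b0_mask]))
    if not s0 > 0:
        raise ValueError("non-positive b=0 signal")
    norm = signal / s0
    shells = scheme.shells
    S0, S2, conds, coeffs = [], [], [], []
    for b in shells:
        m = scheme.shell_mask(b)
        c, cond = sh_decompose_shell(norm[m], scheme.bvecs[m], lmax)
        inv = rotational_invariants(c)
        S0.append(inv[0])
        S2.append(inv.get(2, 0.0))
        conds.append(cond)
        coeffs.append(c)
    return RotInvSeries(
        shells=shells, S0=np.array(S0), S2=np.array(S2),
        coeffs=tuple(coeffs), condition_numbers=np.array(conds),
    )
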