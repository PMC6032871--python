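"""Watson orientation-distribution mathematics.

The Watson distribution is the standard axially symmetric, antipodally
symmetric ODF on the sphere, with density proportional to
``exp(kappa * (mu . n)**2)``.  Its degree-2 and degree-4 Legendre moments
``p2`` and ``p4`` summarize fiber orientation dispersion: ``kappa -> 0``
gives an isotropic ODF (``p2 = p4 = 0``) and ``kappa -> inf`` a single
orientation (``p2 = p4 = 1``).

Closed forms use Dawson's function F:

    p2(kappa) = (1/4) * (3 / (sqrt(kappa) F(sqrt(kappa))) - 2 - 3/kappa)
    p4(kappa) = (105 + 12 kappa (5 + kappa)
                 + 5 sqrt(kappa) (2 kappa - 21) / F(sqrt(kappa))) / (32 kappa^2)

Near kappa = 0 these expressions suffer catastrophic cancellation (the p4
form loses ~19 digits by kappa = 1e-4), so Taylor series are used below
``KAPPA_SMALL`` = 0.02, where both branches agree to ~1e-12; above
``KAPPA_LARGE`` the asymptotic expansions take over.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import dawsn

__all__ = [
    "watson_p2",
    "watson_p4",
    "kappa_from_p2",
    "dispersion_angle",
    "sample_watson",
]

KAPPA_SMALL = 0.02
KAPPA_LARGE = 1e4


def _check_kappa(kappa: np.ndarray) -> np.ndarray:
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("Watson concentration kappa must be >= 0")
    return kappa


def watson_p2(kappa):
    """Degree-2 Legendre moment of the Watson ODF.

    Strictly increasing in kappa, with p2(0) = 0 and p2(inf) = 1.
    Accepts scalars or arrays.
    """
    kappa = _check_kappa(kappa)
    scalar = kappa.ndim == 0
    k = np.atleast_1d(kappa)
    out = np.empty_like(k)

    small = k < KAPPA_SMALL
    large = k > KAPPA_LARGE
    mid = ~(small | large)

    ks = k[small]
    out[small] = (2 * ks / 15 + 4 * ks**2 / 315 - 8 * ks**3 / 4725
                  - 16 * ks**4 / 31185)

    kl = k[large]
    with np.errstate(invalid="ignore"):
        out[large] = 1.0 - 3 / (2 * kl) - 3 / (4 * kl**2)
    out[large][~np.isfinite(kl)] = 1.0
    out[k == np.inf] = 1.0

    km = k[mid]
    sk = np.sqrt(km)
    F = dawsn(sk)
    out[mid] = 0.25 * (3.0 / (sk * F) - 2.0 - 3.0 / km)

    return float(out[0]) if scalar else out


def watson_p4(kappa):
    """Degree-4 Legendre moment of the Watson ODF (0 at kappa=0, 1 at inf)."""
    kappa = _check_kappa(kappa)
    scalar = kappa.ndim == 0
    k = np.atleast_1d(kappa)
    out = np.empty_like(k)

    small = k < KAPPA_SMALL
    large = k > KAPPA_LARGE
    mid = ~(small | large)

    ks = k[small]
    out[small] = 4 * ks**2 / 315 + 16 * ks**3 / 10395 - 464 * ks**4 / 2027025

    kl = k[large]
    with np.errstate(invalid="ignore"):
        out[large] = 1.0 - 5.0 / kl + 25.0 / (4 * kl**2)
    out[k == np.inf] = 1.0

    km = k[mid]
    sk = np.sqrt(km)
    F = dawsn(sk)
    out[mid] = (105.0 + 12.0 * km * (5.0 + km) + 5.0 * sk * (2.0 * km - 21.0) / F) / (
        32.0 * km**2
    )

    return float(out[0]) if scalar else out


def _p2_scalar(k: float) -> float:
    """Fast float-only p2; same branch structure as watson_p2."""
    if k < KAPPA_SMALL:
        return 2 * k / 15 + 4 * k * k / 315 - 8 * k**3 / 4725 - 16 * k**4 / 31185
    if k > KAPPA_LARGE:
        return 1.0 - 3.0 / (2 * k) - 3.0 / (4 * k * k) if np.isfinite(k) else 1.0
    sk = k**0.5
    F = float(dawsn(sk))
    return 0.25 * (3.0 / (sk * F) - 2.0 - 3.0 / k)


def _p4_scalar(k: float) -> float:
    """Fast float-only p4; same branch structure as watson_p4."""
    if k < KAPPA_SMALL:
        return 4 * k * k / 315 + 16 * k**3 / 10395 - 464 * k**4 / 2027025
    if k > KAPPA_LARGE:
        return 1.0 - 5.0 / k + 25.0 / (4 * k * k) if np.isfinite(k) else 1.0
    sk = k**0.5
    F = float(dawsn(sk))
    return (105.0 + 12.0 * k * (5.0 + k) + 5.0 * sk * (2.0 * k - 21.0) / F) / (32.0 * k * k)


def kappa_from_p2(p2: float) -> float:
    """Invert the monotone map kappa -> p2 by bracketed root finding.

    Returns 0 for p2 <= 0 and inf for p2 >= 1.
    """
    if not 0.0 <= p2 <= 1.0:
        raise ValueError("p2 must lie in [0, 1]")
    if p2 <= 0.0:
        return 0.0
    if p2 >= 1.0:
        return np.inf
    lo, hi = 1e-8, 1e8
    if p2 <= _p2_scalar(lo):
        return lo
    if p2 >= _p2_scalar(hi):
        return hi
    return brentq(lambda k: _p2_scalar(k) - p2, lo, hi, xtol=1e-12, rtol=1e-14)


def dispersion_angle(p2):
    """Representative dispersion angle (degrees) from p2.

    Uses cos^2(theta_disp) = (2 p2 + 1) / 3. A single orientation
    (p2 = 1) gives 0 degrees; full isotropy (p2 = 0) gives ~54.7 degrees
    (the magic angle).
    """
    p2 = np.asarray(p2, dtype=float)
    if np.any(p2 < 0) or np.any(p2 > 1):
        raise ValueError("p2 must lie in [0, 1]")
    theta = np.degrees(np.arccos(np.sqrt((2.0 * p2 + 1.0) / 3.0)))
    return float(theta) if theta.ndim == 0 else theta


def sample_watson(kappa: float, mu, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n unit vectors from a Watson distribution with mean axis mu.

    Batch rejection sampling against the uniform sphere with envelope
    exp(kappa (t^2 - 1)) <= 1; acceptance degrades like 1/sqrt(kappa) which
    is acceptable for the concentrations used here (kappa <~ 1e3).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if not np.isfinite(kappa) or kappa > 1e6:
        return np.tile(mu, (n, 1))

    ts = np.empty(0)
    # sample t = cos(theta) from density ~ exp(kappa t^2) on [-1, 1]
    while ts.size < n:
        m = max(4 * (n - ts.size), 256)
        t = rng.uniform(-1.0, 1.0, size=m)
        u = rng.uniform(0.0, 1.0, size=m)
        acc = u < np.exp(kappa * (t**2 - 1.0))
        ts = np.concatenate([ts, t[acc]])
    ts = ts[:n]

    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    st = np.sqrt(np.clip(1.0 - ts**2, 0.0, None))
    local = np.column_stack([st * np.cos(phi), st * np.sin(phi), ts])

    # rotate local z-axis onto mu
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, mu)
    s = np.linalg.norm(v)
    c = float(np.dot(z, mu))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return local @ R.T
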