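"""Analytic DKI-to-model inversion under a Watson ODF ("Method 1").

Input is the axisymmetric component set {D0, D2, W0, W2, W4} of a DKI fit.
Under an axisymmetric ODF the stick+zeppelin moments obey, with
Delta_e = De_par - De_perp and (p2, p4) the ODF invariants:

    3 D0                              = f Da + (1-f)(3 De_perp + Delta_e)
    (3/2) D2                          = p2 [f Da + (1-f) Delta_e]
    D2^2 + 5 D0^2 (1 + W0/3)          = f Da^2 + (1-f)(5 De_perp^2
                                        + (10/3) De_perp Delta_e + Delta_e^2)
    D2(D2 + 7 D0)/2 + (7/12) W2 D0^2  = p2 [f Da^2 + (1-f)((7/3) De_perp
                                        Delta_e + Delta_e^2)]
    (9/4) D2^2 + (35/24) W4 D0^2      = p4 [f Da^2 + (1-f) Delta_e^2]

Given p2, the first four equations admit exactly two algebraic solutions
for (f, Da, De_par, De_perp) - the +/- branches. A Watson ODF ties p4 to
p2 through the concentration kappa, so the fifth equation becomes a scalar
root-finding problem in p2 on [0, 1], solved by a 1000-point sign-change
scan plus bisection. Both branch solutions fit the data equally well; the
+ branch is the correct one when the underlying tissue satisfies
4 - sqrt(40/3) < (Da - De_par)/De_perp < 4 + sqrt(40/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .signal import TissueParams
from .watson import _p4_scalar, dispersion_angle, kappa_from_p2, watson_p4

__all__ = [
    "BranchSolution",
    "solve_watson_inversion",
    "ground_truth_branch",
    "select_branch",
    "forward_components",
    "BRANCH_BETA_LOW",
    "BRANCH_BETA_HIGH",
]

BRANCH_BETA_LOW = 4.0 - np.sqrt(40.0 / 3.0)
BRANCH_BETA_HIGH = 4.0 + np.sqrt(40.0 / 3.0)

DIFFUSIVITY_MAX = 4.0   # um^2/ms, plausibility bound (relaxed from 3 for overshoot)
GRID_POINTS = 1000
P2_FLOOR = 1e-3         # scan start; the moment equations degenerate at p2 = 0
BISECT_TOL = 1e-10


@dataclass(frozen=True)
class BranchSolution:
    """One branch of the Watson inversion (may be marked not-found)."""

    branch: str                   # "plus" or "minus"
    found: bool
    f: float = np.nan
    Da: float = np.nan
    De_par: float = np.nan
    De_perp: float = np.nan
    p2: float = np.nan
    kappa: float = np.nan
    theta_disp: float = np.nan    # degrees
    plausible: bool = False
    multiplicity: int = 0         # admissible kappa roots found for this branch
    roots: tuple = ()             # all roots as (p2, f, Da, De_par, De_perp)

    @property
    def params(self) -> TissueParams:
        if not self.found:
            raise ValueError(f"{self.branch} branch has no solution")
        return TissueParams(
            f=self.f, Da=self.Da, De_par=self.De_par, De_perp=self.De_perp
        )


def forward_components(params: TissueParams, p2: float, p4: float | None = None) -> dict:
    """Evaluate the moment system forward: model parameters -> {D0..W4}.

    With ``p4`` omitted, the Watson value at kappa(p2) is used.
    """
    if p4 is None:
        p4 = float(watson_p4(kappa_from_p2(p2)))
    f, Da, Det = params.f, params.Da, params.De_perp
    De = params.delta_e
    D0 = (f * Da + (1 - f) * (3 * Det + De)) / 3.0
    D2 = (2.0 / 3.0) * p2 * (f * Da + (1 - f) * De)
    q0 = f * Da**2 + (1 - f) * (5 * Det**2 + (10.0 / 3.0) * Det * De + De**2)
    q2 = f * Da**2 + (1 - f) * ((7.0 / 3.0) * Det * De + De**2)
    q4 = f * Da**2 + (1 - f) * De**2
    W0 = 3.0 * ((q0 - D2**2) / (5.0 * D0**2) - 1.0)
    W2 = (p2 * q2 - 0.5 * D2 * (D2 + 7.0 * D0)) / ((7.0 / 12.0) * D0**2)
    W4 = (p4 * q4 - (9.0 / 4.0) * D2**2) / ((35.0 / 24.0) * D0**2)
    return {"D0": D0, "D2": D2, "W0": W0, "W2": W2, "W4": W4}


def _f_quadratic_terms(H0, H2, Q0, Q2):
    """Numerator, discriminant, denominator of the closed-form f quadratic.

    Obtained by symbolic elimination of (Da, De_par, De_perp) from the
    first four moment equations; the two roots differ by the sign of the
    square-root term, whose coefficient is -(H0 - H2)^2 for the branch
    labeled +1. Works on scalars or arrays.
    """
    N0 = (-35 * H0**4 + 50 * H0**3 * H2 + 33 * H0**2 * H2**2 + 333 * H0**2 * Q0
          - 360 * H0**2 * Q2 - 76 * H0 * H2**3 - 342 * H0 * H2 * Q0
          + 396 * H0 * H2 * Q2 + 28 * H2**4 + 9 * H2**2 * Q0 - 36 * H2**2 * Q2
          - 486 * Q0**2 + 972 * Q0 * Q2 - 486 * Q2**2)
    disc = (1225 * H0**4 + 1400 * H0**3 * H2 - 1560 * H0**2 * H2**2
            - 4410 * H0**2 * Q0 - 1800 * H0**2 * Q2 - 1120 * H0 * H2**3
            - 2520 * H0 * H2 * Q0 + 10080 * H0 * H2 * Q2 + 784 * H2**4
            - 4248 * H2**2 * Q0 + 1440 * H2**2 * Q2 + 3969 * Q0**2
            + 3240 * Q0 * Q2 - 6480 * Q2**2)
    den = 18 * (7 * H0**2 * Q0 - 10 * H0**2 * Q2 + 4 * H0 * H2 * Q0
                + 2 * H0 * H2 * Q2 - 11 * H2**2 * Q0 + 8 * H2**2 * Q2
                - 27 * Q0**2 + 54 * Q0 * Q2 - 27 * Q2**2)
    return N0, disc, den


def _solve_f(H0, H2, Q0, Q2, sign):
    """Closed-form f for one algebraic branch (vectorized)."""
    N0, disc, den = _f_quadratic_terms(H0, H2, Q0, Q2)
    with np.errstate(invalid="ignore", divide="ignore"):
        root = np.where(disc >= 0, np.sqrt(np.abs(disc)), np.nan)
        return (N0 - sign * (H0 - H2) ** 2 * root) / den


def _branch_params_scalar(comps: dict, p2: float, sign: int):
    """Float-only twin of _branch_params for tight root-finding loops."""
    D0, D2, W0, W2 = comps["D0"], comps["D2"], comps["W0"], comps["W2"]
    H0 = 3.0 * D0
    H2 = 1.5 * D2 / p2
    Q0 = D2 * D2 + 5.0 * D0 * D0 * (1.0 + W0 / 3.0)
    Q2 = (0.5 * D2 * (D2 + 7.0 * D0) + (7.0 / 12.0) * W2 * D0 * D0) / p2
    N0, disc, den = _f_quadratic_terms(H0, H2, Q0, Q2)
    if disc < 0 or den == 0:
        return None
    f = (N0 - sign * (H0 - H2) ** 2 * disc**0.5) / den
    c = (H0 - H2) / 3.0
    E = Q0 - Q2
    if c == 0 or f in (0.0, 1.0):
        return None
    v = E * (1.0 - f) / c - 5.0 * c
    De_perp = c / (1.0 - f)
    Da = (H2 - v) / f
    return f, Da, v / (1.0 - f) + De_perp, De_perp


def _branch_params(comps: dict, p2, sign):
    """Recover (f, Da, De_par, De_perp) at trial p2 for one algebraic branch."""
    p2 = np.asarray(p2, dtype=float)
    D0, D2, W0, W2 = comps["D0"], comps["D2"], comps["W0"], comps["W2"]
    H0 = 3.0 * D0
    with np.errstate(invalid="ignore", divide="ignore"):
        H2 = 1.5 * D2 / p2
        Q0 = np.full_like(p2, D2**2 + 5.0 * D0**2 * (1.0 + W0 / 3.0))
        Q2 = (0.5 * D2 * (D2 + 7.0 * D0) + (7.0 / 12.0) * W2 * D0**2) / p2
        f = _solve_f(H0, H2, Q0, Q2, sign)
        c = (H0 - H2) / 3.0                       # (1-f) De_perp
        E = Q0 - Q2
        v = E * (1.0 - f) / c - 5.0 * c           # (1-f) Delta_e
        De_perp = c / (1.0 - f)
        Delta_e = v / (1.0 - f)
        Da = (H2 - v) / f
    return f, Da, Delta_e + De_perp, De_perp


@lru_cache(maxsize=8)
def _p2_grid(n: int):
    """Fixed scan grid with the Watson kappa and p4 tabulated once."""
    p2 = np.linspace(P2_FLOOR, 1.0 - 1e-9, n)
    kappa = np.array([kappa_from_p2(v) for v in p2])
    return p2, kappa, watson_p4(kappa)


def _kappa_bracketed(p2: float, grid) -> float:
    """kappa(p2) with the search bracketed by the cached scan grid."""
    from .watson import _p2_scalar

    p2s, kappas, _ = grid
    i = int(np.searchsorted(p2s, p2))
    if 0 < i < p2s.size:
        lo, hi = kappas[i - 1], kappas[i]
        if _p2_scalar(lo) <= p2 <= _p2_scalar(hi):
            return brentq(lambda k: _p2_scalar(k) - p2, lo, hi, xtol=1e-12, rtol=1e-14)
    return kappa_from_p2(p2)


def _residual_grid(comps: dict, sign: int, n: int):
    p2, res_p, res_m = _residual_grid_both(comps, n)
    return p2, res_p if sign == +1 else res_m


def _residual_grid_both(comps: dict, n: int):
    """Fifth-equation residuals of both branches on the scan grid.

    The sign-independent algebra (moment combinations, discriminant,
    Watson p4 table) is shared between the branches.
    """
    p2, _, p4 = _p2_grid(n)
    D0, D2, W0, W2 = comps["D0"], comps["D2"], comps["W0"], comps["W2"]
    R5 = (9.0 / 4.0) * D2**2 + (35.0 / 24.0) * comps["W4"] * D0**2
    H0 = 3.0 * D0
    with np.errstate(invalid="ignore", divide="ignore"):
        H2 = 1.5 * D2 / p2
        Q0 = D2**2 + 5.0 * D0**2 * (1.0 + W0 / 3.0)
        Q2 = (0.5 * D2 * (D2 + 7.0 * D0) + (7.0 / 12.0) * W2 * D0**2) / p2
        N0, disc, den = _f_quadratic_terms(H0, H2, Q0, Q2)
        root = np.where(disc >= 0, np.sqrt(np.abs(disc)), np.nan)
        sq = (H0 - H2) ** 2 * root
        out = []
        c = (H0 - H2) / 3.0
        E = Q0 - Q2
        for f in ((N0 - sq) / den, (N0 + sq) / den):
            v = E * (1.0 - f) / c - 5.0 * c
            Delta_e = v / (1.0 - f)
            Da = (H2 - v) / f
            q4 = f * Da**2 + (1.0 - f) * Delta_e**2
            out.append(p4 * q4 - R5)
    return p2, out[0], out[1]


def _residual_scalar(comps: dict, sign: int, p2: float, grid=None) -> float:
    pars = _branch_params_scalar(comps, p2, sign)
    if pars is None:
        return np.nan
    f, Da, De_par, De_perp = pars
    kappa = kappa_from_p2(p2) if grid is None else _kappa_bracketed(p2, grid)
    p4 = _p4_scalar(kappa)
    q4 = f * Da**2 + (1.0 - f) * (De_par - De_perp) ** 2
    R5 = (9.0 / 4.0) * comps["D2"] ** 2 + (35.0 / 24.0) * comps["W4"] * comps["D0"] ** 2
    return p4 * q4 - R5


def _feasible_scalar(comps: dict, sign: int, p2: float) -> bool:
    """Whether the branch has a real solution at p2 (discriminant test only)."""
    return _branch_params_scalar(comps, p2, sign) is not None


def _is_plausible(f, Da, De_par, De_perp, p2) -> bool:
    vals = (f, Da, De_par, De_perp, p2)
    if not all(np.isfinite(vals)):
        return False
    return (
        0.0 <= f <= 1.0
        and 0.0 <= p2 <= 1.0
        and all(0.0 <= d <= DIFFUSIVITY_MAX for d in (Da, De_par, De_perp))
    )


def solve_watson_inversion(
    components: dict, grid_points: int = GRID_POINTS
) -> tuple[BranchSolution, BranchSolution]:
    """Invert {D0, D2, W0, W2, W4} to model parameters; both branches.

    For each algebraic branch (the sign of the square root in the
    closed-form solution of the first four equations; +1 is the branch
    that recovers tissue with beta = (Da - De_par)/De_perp inside
    4 +/- sqrt(40/3)), the fifth-equation residual is scanned over the p2
    grid and every sign change is refined by bisection to 1e-10. The scan
    also probes the edges of the discriminant-positive region, where the
    two branches merge and a root can sit flush against the boundary.
    One solution per branch is returned (largest-kappa root when several
    are admissible, with the multiplicity recorded); a branch with no
    root carries ``found=False``.
    """
    if not np.isfinite(list(components.values())).all():
        raise ValueError("components must be finite")
    if components["D0"] <= 0:
        raise ValueError("D0 must be positive")

    grid = _p2_grid(grid_points)
    p2g, res_plus, res_minus = _residual_grid_both(components, grid_points)
    solutions = []
    for sign, label, res in ((+1, "plus", res_plus), (-1, "minus", res_minus)):
        ok = np.isfinite(res)
        roots = [float(p) for p in p2g[ok & (res == 0.0)]]

        def _fun(p):
            return _residual_scalar(components, sign, p, grid)

        def _feas(p):
            return _feasible_scalar(components, sign, p)

        both = ok[:-1] & ok[1:]
        with np.errstate(invalid="ignore"):
            crossing = np.flatnonzero(both & (res[:-1] * res[1:] < 0))
        for i in crossing:
            roots.append(brentq(_fun, p2g[i], p2g[i + 1], xtol=BISECT_TOL))
        for i in np.flatnonzero(ok[:-1] != ok[1:]):
            root = _boundary_root(_fun, _feas, p2g[i], p2g[i + 1], bool(ok[i + 1]))
            if root is not None:
                roots.append(root)

        cands = []
        for root in roots:
            f, Da, De_par, De_perp = (
                float(x) for x in _branch_params(components, np.array(root), sign)
            )
            if all(np.isfinite((f, Da, De_par, De_perp))):
                cands.append((float(root), f, Da, De_par, De_perp))

        if not cands:
            solutions.append(BranchSolution(branch=label, found=False))
            continue
        cands.sort(key=lambda c: c[0])
        root, f, Da, De_par, De_perp = cands[-1]  # largest p2 <=> largest kappa
        solutions.append(
            BranchSolution(
                branch=label, found=True, f=f, Da=Da, De_par=De_par,
                De_perp=De_perp, p2=root, kappa=kappa_from_p2(root),
                theta_disp=float(dispersion_angle(root)),
                plausible=_is_plausible(f, Da, De_par, De_perp, root),
                multiplicity=len(cands),
                roots=tuple(cands),
            )
        )
    return solutions[0], solutions[1]


def _boundary_root(fun, feasible, p_bad, p_good, good_on_right, tol=BISECT_TOL):
    """Root search against the edge of the real-solution region.

    One endpoint of the interval has no real branch solution (negative
    discriminant). Bisect the feasibility boundary, then bracket between
    a point just inside it and the feasible endpoint.
    """
    a, b = p_bad, p_good
    # shrink [infeasible, feasible] (in whichever orientation) to the edge
    for _ in range(60):
        m = 0.5 * (a + b)
        if feasible(m):
            b = m
        else:
            a = m
        if abs(b - a) < tol:
            break
    inside = b
    f_in = fun(inside)
    f_out = fun(p_good)
    if not (np.isfinite(f_in) and np.isfinite(f_out)):
        return None
    if f_in == 0.0:
        return float(inside)
    if f_in * f_out < 0:
        lo2, hi2 = (inside, p_good) if good_on_right else (p_good, inside)
        return brentq(fun, lo2, hi2, xtol=tol)
    return None


def ground_truth_branch(params: TissueParams) -> str:
    """Branch label implied by known tissue parameters (beta criterion)."""
    if params.De_perp <= 0:
        raise ValueError("branch criterion undefined for De_perp = 0")
    beta = (params.Da - params.De_par) / params.De_perp
    return "plus" if BRANCH_BETA_LOW < beta < BRANCH_BETA_HIGH else "minus"


def select_branch(
    solutions: tuple[BranchSolution, BranchSolution],
    policy: str = "plus",
    ground_truth: Optional[TissueParams] = None,
) -> Optional[BranchSolution]:
    """Pick one branch per policy: "plus" (study default, motivated by
    callosal histology), "minus", or "ground_truth" (requires the true
    parameters). Returns None when no plausible solution matches."""
    plus, minus = solutions
    if policy == "ground_truth":
        if ground_truth is None:
            raise ValueError("ground_truth policy needs the true parameters")
        policy = ground_truth_branch(ground_truth)
    if policy not in ("plus", "minus"):
        raise ValueError(f"unknown branch policy: {policy}")
    chosen = plus if policy == "plus" else minus
    if chosen.found and chosen.plausible:
        return chosen
    other = minus if policy == "plus" else plus
    if other.found and other.plausible:
        return None  # requested branch missing; caller decides on fallback
    return None
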