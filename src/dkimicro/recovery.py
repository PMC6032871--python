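"""Parameter-recovery simulation studies.

Two experiments mirror the study's numerical validation:

* a random ground-truth sweep - per virtual voxel, tissue parameters are
  drawn uniformly from biophysically relevant intervals, 30 fiber segments
  are sampled from a Watson distribution at a target dispersion (the
  *realized* stick-set p2 is the truth used for scoring, since no
  axisymmetry is imposed on the drawn set), Rician noise is added at the
  protocol SNR, and both estimation methods run; errors are summarized as
  RMSD per parameter over a grid of lower dispersion bounds p2_min;

* a fixed ground-truth accuracy/precision study - one voxel configuration,
  many noise realizations, reporting the relative mean signed difference
  <(estimate - truth)/truth> and the relative standard deviation
  std(estimate)/truth per parameter, per method, and per branch for the
  analytic inversion.

Implausible outcomes (outside 0 <= f, p2 <= 1, 0 <= D <= 4) are discarded
and accounted as rates, mirroring the study's filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme, study_protocol
from .dki import axisymmetric_components, fit_dki_wlls
from .method1 import ground_truth_branch, solve_watson_inversion
from .method2 import fit_rotinv
from .sh import shell_invariants
from .signal import FiberConfiguration, TissueParams, add_rician_noise, odf_invariant_p_l, simulate_voxel
from .watson import kappa_from_p2

__all__ = ["SweepConfig", "run_sweep", "run_fixed_gt", "rmsd", "PARAM_NAMES"]

PARAM_NAMES = ("f", "Da", "De_par", "De_perp", "p2")

FULL_SCALE_VOXELS = 10000        # the study's sweep size
FULL_SCALE_REALIZATIONS = 1000   # the study's fixed-truth size
REDUCED_VOXELS = 500             # shipped reduced-scale presets
REDUCED_REALIZATIONS = 200


@dataclass(frozen=True)
class SweepConfig:
    """Random ground-truth sweep configuration (study defaults)."""

    n_voxels: int = REDUCED_VOXELS
    f_range: tuple = (0.1, 1.0)
    Da_range: tuple = (0.5, 3.0)
    De_par_range: tuple = (0.5, 3.0)
    De_perp_range: tuple = (0.1, 1.5)
    p2_min_grid: tuple = tuple(np.round(np.arange(0.0, 0.91, 0.1), 1))
    n_segments: int = 30
    snr: float = 25.0
    seed: int = 0
    lmax: int = 4

    def __post_init__(self):
        if self.n_voxels < 1 or self.n_segments < 1:
            raise ValueError("counts must be positive")
        if any(not 0.0 <= p <= 0.9 for p in self.p2_min_grid):
            raise ValueError("p2_min values must lie in [0, 0.9]")


def rmsd(estimates, truths) -> float:
    """Root mean squared deviation sqrt(mean((estimate - truth)^2))."""
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if e.shape != t.shape:
        raise ValueError("length mismatch")
    if e.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((e - t) ** 2)))


def _draw_truth(cfg: SweepConfig, p2_min: float, rng: np.random.Generator):
    params = TissueParams(
        f=rng.uniform(*cfg.f_range),
        Da=rng.uniform(*cfg.Da_range),
        De_par=rng.uniform(*cfg.De_par_range),
        De_perp=rng.uniform(*cfg.De_perp_range),
    )
    p2_target = rng.uniform(p2_min, 1.0)
    fibers = FiberConfiguration.from_watson(
        kappa_from_p2(p2_target), cfg.n_segments, rng
    )
    return params, fibers, odf_invariant_p_l(fibers, 2)


def _estimate_voxel(scheme, noisy, truth_params, rng, lmax):
    """Run both methods on one noisy voxel; returns dict of estimate rows."""
    out = {}
    fit = fit_dki_wlls(scheme, noisy)
    if fit.success:
        ax = axisymmetric_components(fit)
        comps = {k: ax[k] for k in ("D0", "D2", "W0", "W2", "W4")}
        try:
            plus, minus = solve_watson_inversion(comps)
            sol = plus if ground_truth_branch(truth_params) == "plus" else minus
            if sol.found and sol.plausible:
                out["method1"] = np.array(
                    [sol.f, sol.Da, sol.De_par, sol.De_perp, sol.p2]
                )
        except ValueError:
            pass
    try:
        series = shell_invariants(scheme, noisy, lmax=lmax)
        r2 = fit_rotinv(series, rng=rng, n_starts=1)
        if r2.converged:
            out["method2"] = r2.x
    except (ValueError, np.linalg.LinAlgError):
        pass
    return out


def run_sweep(config: SweepConfig, scheme: AcquisitionScheme | None = None) -> pd.DataFrame:
    """Random ground-truth sweep over the p2_min grid.

    Returns a tidy frame with columns p2_min, method, parameter, rmsd,
    n_used, n_total, discard_rate. Deterministic for a fixed config seed.
    """
    if scheme is None:
        scheme = study_protocol(snr=config.snr)
    rows = []
    for p2_min in config.p2_min_grid:
        rng = np.random.default_rng([config.seed, int(round(p2_min * 10))])
        truths = {m: [] for m in ("method1", "method2")}
        ests = {m: [] for m in ("method1", "method2")}
        for _ in range(config.n_voxels):
            params, fibers, p2_real = _draw_truth(config, p2_min, rng)
            clean = simulate_voxel(scheme, fibers, params)
            noisy = (
                add_rician_noise(clean, config.snr, rng)
                if np.isfinite(config.snr)
                else clean
            )
            truth_vec = np.array([*params.as_array(), p2_real])
            for method, est in _estimate_voxel(
                scheme, noisy, params, rng, config.lmax
            ).items():
                truths[method].append(truth_vec)
                ests[method].append(est)
        for method in ("method1", "method2"):
            t = np.array(truths[method]).reshape(-1, 5)
            e = np.array(ests[method]).reshape(-1, 5)
            for j, name in enumerate(PARAM_NAMES):
                rows.append(
                    {
                        "p2_min": p2_min,
                        "method": method,
                        "parameter": name,
                        "rmsd": rmsd(e[:, j], t[:, j]) if len(e) else np.nan,
                        "n_used": len(e),
                        "n_total": config.n_voxels,
                        "discard_rate": 1.0 - len(e) / config.n_voxels,
                    }
                )
    return pd.DataFrame(rows)


def run_fixed_gt(
    params: TissueParams = TissueParams(f=0.7, Da=2.2, De_par=1.8, De_perp=0.5),
    p2: float = 0.7,
    n_realizations: int = REDUCED_REALIZATIONS,
    snr: float = 25.0,
    seed: int = 0,
    n_segments: int = 30,
    scheme: AcquisitionScheme | None = None,
    lmax: int = 4,
) -> pd.DataFrame:
    """Fixed ground-truth accuracy/precision study.

    One stick configuration is drawn at the target dispersion and held
    fixed; each realization adds fresh Rician noise. Columns: method
    (method1_plus / method1_minus / method2), parameter, rel_bias
    (relative mean signed difference), rel_std, n_used, n_total.
    """
    if scheme is None:
        scheme = study_protocol(snr=snr)
    rng = np.random.default_rng([seed, 1])
    fibers = FiberConfiguration.from_watson(kappa_from_p2(p2), n_segments, rng)
    p2_real = odf_invariant_p_l(fibers, 2)
    clean = simulate_voxel(scheme, fibers, params)
    truth = np.array([*params.as_array(), p2_real])

    est = {"method1_plus": [], "method1_minus": [], "method2": []}
    for _ in range(n_realizations):
        noisy = add_rician_noise(clean, snr, rng) if np.isfinite(snr) else clean
        fit = fit_dki_wlls(scheme, noisy)
        if fit.success:
            ax = axisymmetric_components(fit)
            comps = {k: ax[k] for k in ("D0", "D2", "W0", "W2", "W4")}
            try:
                plus, minus = solve_watson_inversion(comps)
            except ValueError:
                plus = minus = None
            for sol, key in ((plus, "method1_plus"), (minus, "method1_minus")):
                if sol is not None and sol.found and sol.plausible:
                    est[key].append([sol.f, sol.Da, sol.De_par, sol.De_perp, sol.p2])
        try:
            r2 = fit_rotinv(shell_invariants(scheme, noisy, lmax=lmax), rng=rng, n_starts=1)
            if r2.converged:
                est["method2"].append(r2.x)
        except (ValueError, np.linalg.LinAlgError):
            pass

    rows = []
    for method, values in est.items():
        v = np.array(values).reshape(-1, 5)
        for j, name in enumerate(PARAM_NAMES):
            if len(v):
                rel = (v[:, j] - truth[j]) / truth[j]
                bias, std = float(np.mean(rel)), float(np.std(v[:, j]) / truth[j])
            else:
                bias = std = np.nan
            rows.append(
                {
                    "method": method,
                    "parameter": name,
                    "truth": truth[j],
                    "rel_bias": bias,
                    "rel_std": std,
                    "n_used": len(v),
                    "n_total": n_realizations,
                }
            )
    return pd.DataFrame(rows)
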