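"""ROI-level group comparison and covariate correlation.

Voxels are filtered at FA >= 0.5 (inclusive) to limit CSF partial-volume
contamination, averaged per subject and region, compared between groups
with Welch's unequal-variance two-sided t-test, and correlated with
clinical covariates within the patient group using Spearman's rank
coefficient (exact two-sided p for n <= 9 without ties, large-sample
approximation otherwise).

No multiple-comparison correction is applied at the ROI level; the
``flagged`` column marks raw p < 0.05 and callers are expected to treat
it accordingly.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["summarize_roi", "welch_t_test", "spearman_corr", "run_group_analysis"]

FA_THRESHOLD = 0.5
ALPHA = 0.05
EXACT_SPEARMAN_MAX_N = 9


def summarize_roi(
    voxel_table: pd.DataFrame,
    value_columns: list[str],
    fa_threshold: float = FA_THRESHOLD,
) -> pd.DataFrame:
    """Subject x region means over voxels passing the FA filter.

    Rows (subject, region) with no surviving voxel are dropped. The
    returned frame carries n_voxels_used per row.
    """
    required = {"subject_id", "group", "region", "fa", *value_columns}
    missing = required - set(voxel_table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    kept = voxel_table[voxel_table["fa"] >= fa_threshold]
    grouped = kept.groupby(["subject_id", "group", "region"], sort=True)
    out = grouped[value_columns].mean()
    out["n_voxels_used"] = grouped.size()
    return out.reset_index()


def welch_t_test(group_a, group_b) -> dict:
    """Welch's two-sided t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return {"t": 0.0, "df": float(a.size + b.size - 2), "p": 1.0}
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for Spearman rho (small n, no ties)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = x.size
    denom = n * (n**2 - 1) / 6.0
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in permutations(ry):
        r = 1.0 - np.sum((rx - np.array(perm)) ** 2) / denom
        count += abs(r) >= target
        total += 1
    return count / total


def spearman_corr(x, y) -> dict:
    """Spearman rank correlation with midrank ties, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input")
    rho, p = sps.spearmanr(x, y)
    has_ties = (np.unique(x).size < x.size) or (np.unique(y).size < y.size)
    if x.size <= EXACT_SPEARMAN_MAX_N and not has_ties:
        p = _spearman_exact_p(x, y, float(rho))
    return {"rho": float(rho), "p": float(p)}


def run_group_analysis(
    roi_table: pd.DataFrame,
    parameters: list[str],
    covariates: pd.DataFrame | None = None,
    covariate_columns: tuple = ("hamd17", "duration_years", "dose_mg"),
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Region x parameter group tests plus within-patient correlations.

    ``roi_table`` is the output of :func:`summarize_roi` (must contain
    group labels "patient"/"control"). ``covariates`` is a subject-level
    table carrying the clinical scores. Returns a tidy frame with one row
    per test: test ("welch" or "spearman:<cov>"), region, parameter, the
    statistic, p, and a flagged column at raw p < alpha (uncorrected, as
    in ROI analyses of this design).
    """
    rows = []
    for region, sub in roi_table.groupby("region", sort=True):
        pat = sub[sub["group"] == "patient"]
        con = sub[sub["group"] == "control"]
        for par in parameters:
            a = pat[par].to_numpy(dtype=float)
            b = con[par].to_numpy(dtype=float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if min(a.size, b.size) < 2:
                raise ValueError(
                    f"insufficient group sizes for {par} in region {region}"
                )
            w = welch_t_test(a, b)
            rows.append(
                {
                    "test": "welch",
                    "region": region,
                    "parameter": par,
                    "statistic": w["t"],
                    "df": w["df"],
                    "p": w["p"],
                    "mean_patients": float(np.mean(a)),
                    "mean_controls": float(np.mean(b)),
                    "flagged": w["p"] < alpha,
                }
            )
            if covariates is not None:
                keep = ["subject_id"] + [
                    c for c in covariates.columns
                    if c != "subject_id" and c not in pat.columns
                ]
                merged = pat.merge(covariates[keep], on="subject_id", how="left")
                for cov in covariate_columns:
                    if cov not in merged.columns:
                        continue
                    xs = merged[par].to_numpy(dtype=float)
                    ys = merged[cov].to_numpy(dtype=float)
                    ok = np.isfinite(xs) & np.isfinite(ys)
                    if ok.sum() < 3 or np.unique(xs[ok]).size < 2 or np.unique(ys[ok]).size < 2:
                        continue
                    s = spearman_corr(xs[ok], ys[ok])
                    rows.append(
                        {
                            "test": f"spearman:{cov}",
                            "region": region,
                            "parameter": par,
                            "statistic": s["rho"],
                            "df": float(ok.sum() - 2),
                            "p": s["p"],
                            "mean_patients": np.nan,
                            "mean_controls": np.nan,
                            "flagged": s["p"] < alpha,
                        }
                    )
    return pd.DataFrame(rows)
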