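"""ROI summaries, Welch test, Spearman correlation, group analysis."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dkimicro.stats import (
    run_group_analysis,
    spearman_corr,
    summarize_roi,
    welch_t_test,
)


def voxel_frame(fa_values, f_values, subject="S1", group="control", region="I"):
    return pd.DataFrame(
        {
            "subject_id": subject,
            "group": group,
            "region": region,
            "fa": fa_values,
            "f": f_values,
        }
    )


class TestSummarizeRoi:
    def test_all_above_threshold_retained(self):
        df = voxel_frame([0.6, 0.6, 0.6], [0.1, 0.2, 0.3])
        out = summarize_roi(df, ["f"])
        assert out.loc[0, "n_voxels_used"] == 3
        assert out.loc[0, "f"] == pytest.approx(0.2)

    def test_threshold_is_inclusive(self):
        df = voxel_frame([0.4, 0.5, 0.6], [1.0, 2.0, 3.0])
        out = summarize_roi(df, ["f"])
        assert out.loc[0, "n_voxels_used"] == 2
        assert out.loc[0, "f"] == pytest.approx(2.5)

    def test_zero_threshold_equals_unfiltered_mean(self):
        df = voxel_frame([0.1, 0.3, 0.9], [1.0, 2.0, 6.0])
        out = summarize_roi(df, ["f"], fa_threshold=0.0)
        assert out.loc[0, "f"] == pytest.approx(3.0)

    def test_empty_rows_dropped(self):
        df = voxel_frame([0.1, 0.2], [1.0, 2.0])
        out = summarize_roi(df, ["f"])
        assert len(out) == 0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            summarize_roi(pd.DataFrame({"fa": [0.6]}), ["f"])


class TestWelch:
    def test_identical_groups(self):
        r = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["t"] == 0.0
        assert r["p"] == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 4.0, 5.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        r = welch_t_test(a, b)
        assert r["t"] == pytest.approx(t_hand, abs=1e-10)
        assert r["df"] == pytest.approx(df_hand, abs=1e-10)
        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        assert r["p"] == pytest.approx(p_hand, abs=1e-12)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 14)
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert spearman_corr(x, x**3)["rho"] == pytest.approx(1.0)
        assert spearman_corr(x, -np.sqrt(x))["rho"] == pytest.approx(-1.0)

    def test_midrank_ties_against_brute_force(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 7.0, 8.0, 9.0, 10.0, 11.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 5.0, 8.0, 7.0, 10.0, 9.0])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_hand = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y)["rho"] == pytest.approx(rho_hand, abs=1e-12)

    def test_exact_small_sample_p(self):
        # n = 5, no ties: p must match full enumeration of rank permutations
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r = spearman_corr(x, y)
        rx = sps.rankdata(x)
        denom = len(x) * (len(x) ** 2 - 1) / 6
        rhos = [
            1 - np.sum((rx - np.array(p)) ** 2) / denom
            for p in permutations(sps.rankdata(y))
        ]
        p_exact = np.mean([abs(v) >= abs(r["rho"]) - 1e-12 for v in rhos])
        assert r["p"] == pytest.approx(p_exact, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def make_roi_table(rng, n_pat=10, n_con=12, effect=0.0, regions=("I", "II")):
    rows = []
    for g, n in (("patient", n_pat), ("control", n_con)):
        for i in range(n):
            for reg in regions:
                shift = effect if (g == "patient" and reg == "II") else 0.0
                rows.append(
                    {
                        "subject_id": f"{g[0]}{i}",
                        "group": g,
                        "region": reg,
                        "f": rng.normal(0.7 + shift, 0.03),
                    }
                )
    return pd.DataFrame(rows)


class TestGroupAnalysis:
    def test_null_flag_rate_nominal(self):
        """Type-I calibration of the Welch layer: with no implanted effect
        the raw p < 0.05 flag rate stays within binomial bounds of 5%."""
        rng = np.random.default_rng(77)
        flags, total = 0, 0
        for _ in range(150):
            res = run_group_analysis(make_roi_table(rng), ["f"])
            flags += int(res["flagged"].sum())
            total += len(res)
        rate = flags / total
        half = 1.96 * np.sqrt(0.05 * 0.95 / total)
        assert 0.05 - half < rate < 0.05 + half

    def test_implanted_effect_detected(self):
        rng = np.random.default_rng(3)
        res = run_group_analysis(make_roi_table(rng, effect=-0.05), ["f"])
        row = res[(res["region"] == "II") & (res["test"] == "welch")].iloc[0]
        assert row["flagged"] and row["statistic"] < 0

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(5)
        tab = make_roi_table(rng, effect=-0.03)
        res1 = run_group_analysis(tab, ["f"])
        res2 = run_group_analysis(tab.sample(frac=1, random_state=1), ["f"])
        pd.testing.assert_frame_equal(res1, res2)

    def test_covariate_correlations_included(self):
        rng = np.random.default_rng(9)
        tab = make_roi_table(rng)
        cov = pd.DataFrame(
            {
                "subject_id": tab["subject_id"].unique(),
                "hamd17": rng.uniform(0, 30, tab["subject_id"].nunique()),
            }
        )
        res = run_group_analysis(tab, ["f"], covariates=cov)
        assert (res["test"] == "spearman:hamd17").sum() == 2  # one per region

    def test_insufficient_groups_rejected(self):
        df = pd.DataFrame(
            {
                "subject_id": ["p1", "c1", "c2"],
                "group": ["patient", "control", "control"],
                "region": ["I"] * 3,
                "f": [0.7, 0.68, 0.72],
            }
        )
        with pytest.raises(ValueError):
            run_group_analysis(df, ["f"])
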