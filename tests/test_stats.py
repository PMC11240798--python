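"""Cohort statistics: rank tests, effect sizes, and the report builder."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from surrocor.stats import (
    COVARIATE_COLS,
    ROI_LABELS,
    build_reports,
    cohens_d_from_t,
    dunn_bonferroni,
    effect_size_r,
    friedman,
    mann_whitney,
    spearman,
    ttest_ind,
    validate_cohort,
)


class TestFriedman:
    def test_consistent_rank_order_closed_form(self):
        # every subject ranks the conditions identically: Chi2 = 6 at n=k=3
        table = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9.0]])
        res = friedman(table)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2

    def test_all_equal_gives_zero_statistic(self):
        res = friedman(np.full((4, 3), 7.0))
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(20):
            n, k = rng.integers(3, 10), rng.integers(3, 7)
            table = rng.normal(size=(n, k))
            if rng.random() < 0.5:  # introduce ties
                table = np.round(table)
            ours = friedman(table)
            ref_stat, ref_p = sps.friedmanchisquare(*table.T)
            assert ours.statistic == pytest.approx(ref_stat, abs=1e-10)
            assert ours.p == pytest.approx(ref_p, abs=1e-12)

    def test_missing_cells_rejected(self):
        table = np.array([[1, 2, 3], [4, np.nan, 6.0]])
        with pytest.raises(ValueError, match="missing"):
            friedman(table)
        with pytest.raises(ValueError):
            friedman(np.array([[1.0, 2, 3]]))  # n = 1


class TestDunnBonferroni:
    def test_identical_columns_give_null_results(self):
        table = np.tile(np.arange(5.0)[:, None], (1, 4))
        ph = dunn_bonferroni(table)
        assert np.allclose(ph["z"], 0.0)
        assert np.allclose(ph["p_adjusted"], 1.0)

    def test_pair_count_for_nine_rois(self, rng):
        ph = dunn_bonferroni(rng.normal(size=(6, 9)), labels=ROI_LABELS)
        assert len(ph) == 36

    def test_adjusted_p_never_below_raw(self, rng):
        ph = dunn_bonferroni(rng.normal(size=(5, 5)))
        assert (ph["p_adjusted"] >= ph["p"] - 1e-15).all()
        assert (ph["p_adjusted"] <= 1.0).all()

    def test_z_formula_against_hand_computation(self):
        table = np.array([[1, 2, 3], [1, 2, 3], [2, 1, 3.0]])
        ph = dunn_bonferroni(table, labels=["a", "b", "c"])
        mean_ranks = np.array([4 / 3, 5 / 3, 3.0])
        se = np.sqrt(3 * 4 / (6 * 3))
        row = ph[(ph.group_i == "a") & (ph.group_j == "c")].iloc[0]
        assert row.z == pytest.approx((mean_ranks[0] - mean_ranks[2]) / se)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0

    def test_identical_groups_give_null_z(self):
        res = mann_whitney([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.extra["z"] == 0.0
        assert res.statistic == pytest.approx(16 / 2)

    def test_u_is_min_convention_and_z_negative(self, rng):
        a, b = rng.normal(size=26), rng.normal(1.0, size=31)
        res = mann_whitney(a, b)
        assert res.statistic == min(res.extra["U1"], res.extra["U2"])
        assert res.extra["z"] <= 0.0

    def test_p_matches_scipy_asymptotic(self, rng):
        for _ in range(10):
            a = rng.normal(size=rng.integers(5, 30))
            b = rng.normal(0.5, size=rng.integers(5, 30))
            res = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_u_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=8), rng.normal(size=11)
        base = mann_whitney(a, b).statistic
        for f in (np.exp, np.arctan, lambda x: x**3):
            assert mann_whitney(f(a), f(b)).statistic == base

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0, 2.0])


class TestEffectSizes:
    @pytest.mark.parametrize(
        "z,n,expected",
        [(-3.65, 57, 0.48), (-2.4, 57, 0.32), (-2.19, 57, 0.29), (0.0, 57, 0.0)],
    )
    def test_r_from_z(self, z, n, expected):
        assert round(effect_size_r(z, n), 2) == expected

    @pytest.mark.parametrize("t,na,nb,expected", [(-1.12, 26, 31, 0.30), (0.0, 5, 5, 0.0)])
    def test_d_from_t(self, t, na, nb, expected):
        assert round(cohens_d_from_t(t, na, nb), 2) == expected

    def test_d_conversion_is_algebraic_identity_of_pooled_d(self, rng):
        a, b = rng.normal(size=12), rng.normal(0.7, 1.0, size=17)
        res = ttest_ind(a, b)
        assert cohens_d_from_t(res.statistic, 12, 17) == pytest.approx(
            res.effect_size, abs=1e-12
        )


class TestSpearman:
    def test_monotone_series(self):
        x = np.array([1.0, 2, 5, 9, 11])
        assert spearman(x, x**3).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        res = spearman([1.0, 2, 3, 4, 5], [2.0, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(0.8)

    def test_symmetry_and_sign_flip(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert spearman(x, y).statistic == pytest.approx(spearman(y, x).statistic)
        assert spearman(x, -y).statistic == pytest.approx(-spearman(x, y).statistic)

    def test_zero_rank_variance_flagged(self):
        res = spearman([1.0, 1, 1, 1], [1.0, 2, 3, 4])
        assert np.isnan(res.statistic) and np.isnan(res.p)


class TestTTest:
    def test_identical_groups(self):
        res = ttest_ind([1.0, 2, 3], [1.0, 2, 3])
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_four_point_hand_computation(self):
        # pooled s^2 = 2, t = -1 / (sqrt(2) * sqrt(1/2 + 1/2)) = -1/sqrt(2)
        res = ttest_ind([0.0, 2.0], [1.0, 3.0])
        assert res.statistic == pytest.approx(-1.0 / np.sqrt(2.0))
        assert res.df == 2
        assert res.ci[0] < 0 < res.ci[1]

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            ttest_ind([2.0, 2.0], [2.0, 2.0])


def _toy_cohort(n=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        row = {
            "patient_id": f"P{i}",
            "sex": "M" if i % 2 == 0 else "F",
            "height_cm": rng.normal(170, 8),
            "bmi": rng.normal(27, 4),
            "sat_pct": rng.uniform(10, 25),
            "vat_pct": rng.uniform(1, 8),
            "tat_pct": rng.uniform(15, 30),
            "ts_magnitude_mm": rng.normal(8, 2),
        }
        for lab in ROI_LABELS:
            row[f"mag_{lab}"] = rng.uniform(1, 6)
            row[f"r_{lab}"] = rng.uniform(0.5, 1.0)
        rows.append(row)
    return pd.DataFrame(rows)


class TestReports:
    def test_missing_columns_named(self):
        df = _toy_cohort().drop(columns=["mag_B", "vat_pct"])
        with pytest.raises(ValueError, match="mag_B"):
            validate_cohort(df)

    def test_duplicate_patient_rejected(self):
        df = _toy_cohort()
        df.loc[1, "patient_id"] = df.loc[0, "patient_id"]
        with pytest.raises(ValueError, match="patient_id"):
            validate_cohort(df)

    def test_report_shapes(self, tmp_path):
        reports = build_reports(_toy_cohort(), out_dir=tmp_path)
        assert len(reports["covariate_spearman"]) == len(COVARIATE_COLS) * 9 * 2
        assert len(reports["friedman_posthoc"]) == 36 * 2
        assert len(reports["sex_comparison"]) == 18
        assert (tmp_path / "covariate_spearman.csv").exists()
        assert (tmp_path / "friedman.md").exists()

    def test_identical_rois_give_null_friedman_block(self):
        df = _toy_cohort()
        for lab in ROI_LABELS:
            df[f"mag_{lab}"] = df["mag_A"]
            df[f"r_{lab}"] = 0.9
        reports = build_reports(df)
        fried = reports["friedman"].set_index("block")
        assert fried.loc["magnitude", "p"] == pytest.approx(1.0)
        corr_block = reports["covariate_spearman"].query("block == 'correlation'")
        assert not corr_block["significant"].any()

    def test_constructed_bmi_effect_recovered(self):
        # BMI built anti-monotone with the A-row magnitudes: the A-row
        # Spearman cells must come out negative and significant
        df = _toy_cohort(n=30, seed=3)
        order = df["bmi"].rank()
        for lab in ("A", "A_R", "A_L"):
            df[f"mag_{lab}"] = 3.0 - 0.05 * order + np.random.default_rng(4).normal(
                0, 0.05, len(df)
            )
        reports = build_reports(df)
        sp = reports["covariate_spearman"]
        cells = sp[
            (sp.block == "magnitude") & (sp.covariate == "bmi")
            & (sp.roi.isin(["A", "A_R", "A_L"]))
        ]
        assert (cells["rho"] < 0).all()
        assert cells["significant"].all()
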