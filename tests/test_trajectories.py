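"""Age regressions, Fisher r-to-z, BH-FDR and group-mean comparisons."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from retscn import (
    CohortTable,
    Group,
    Layer,
    Sector,
    compare_group_means,
    default_config,
    fdr_adjust,
    fisher_r_to_z,
    fit_age_regression,
    generate_cohort,
    null_config,
    slope_difference_test,
    trajectory_report,
)
from retscn.cohort import NODES

from conftest import make_cohort, make_record


def cohort_with_line(slope, intercept=3.0, n=20, noise=0.0, seed=0,
                     group=Group.HC):
    """Cohort whose RNFL_C follows thickness = intercept + slope*age."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        age = float(rng.uniform(20, 80))
        val = intercept + slope * age + noise * rng.standard_normal()
        records.append(
            make_record(
                subject_id=f"S{i}", group=group, age=age,
                overrides={(Layer.RNFL, Sector.C): val},
            )
        )
    return CohortTable(records)


class TestRegression:
    def test_noiseless_line(self):
        table = cohort_with_line(slope=0.2)
        fit = fit_age_regression(table, Group.HC, Layer.RNFL, "C")
        assert fit.slope == pytest.approx(0.2, abs=1e-12)
        assert fit.intercept == pytest.approx(3.0, abs=1e-10)
        assert fit.r == pytest.approx(1.0, abs=1e-12)

    def test_normal_equations_oracle(self):
        table = cohort_with_line(slope=0.1, noise=4.0, seed=1)
        fit = fit_age_regression(table, Group.HC, Layer.RNFL, "C")
        ages = table.ages(Group.HC)
        vals = np.array(
            [r.thickness[(Layer.RNFL, Sector.C)] for r in table.records]
        )
        X = np.column_stack([np.ones(len(ages)), ages])
        beta = np.linalg.solve(X.T @ X, X.T @ vals)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert np.sign(fit.slope) == np.sign(fit.r)

    def test_null_rejection_rate_near_alpha(self):
        """p-values behave like a null test: rejection rate ~ alpha."""
        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            table = cohort_with_line(slope=0.0, intercept=40.0, noise=3.0,
                                     n=30, seed=seed)
            fit = fit_age_regression(table, Group.HC, Layer.RNFL, "C")
            rejections += fit.p < 0.05
        rate = rejections / n_reps
        assert rate < 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_reps) + 0.02

    def test_planted_slope_ci_coverage(self):
        """95% CI of the estimated slope covers the planted truth at about
        the nominal rate on default-sized synthetic groups."""
        true_slope = 0.03
        covered = 0
        n_reps = 100
        for seed in range(n_reps):
            table = cohort_with_line(
                slope=true_slope, intercept=40.0, noise=2.83, n=156,
                seed=1000 + seed,
            )
            fit = fit_age_regression(table, Group.HC, Layer.RNFL, "C")
            half = stats.t.ppf(0.975, fit.n - 2) * fit.stderr
            covered += abs(fit.slope - true_slope) <= half
        assert covered >= 93 - 5  # binomial slack around 95/100

    def test_zero_thickness_variance_warns(self):
        table = make_cohort(n_hc=8, n_dwor=0)
        for rec in table.records:
            rec.thickness[(Layer.RPE, Sector.C)] = 14.0
        with pytest.warns(UserWarning, match="zero thickness variance"):
            fit = fit_age_regression(table, Group.HC, Layer.RPE, "C")
        assert fit.r == 0.0 and fit.p == 1.0

    def test_zero_age_variance_rejected(self):
        records = [
            make_record(subject_id=f"S{i}", age=50.0) for i in range(6)
        ]
        with pytest.raises(ValueError, match="age variance"):
            fit_age_regression(CohortTable(records), Group.HC, Layer.RNFL, "C")


class TestFisherRToZ:
    def test_equal_correlations(self):
        z, p = fisher_r_to_z(0.3, 50, 0.3, 80)
        assert z == 0.0 and p == 1.0

    def test_hand_evaluation(self):
        z, p = fisher_r_to_z(0.5, 100, 0.0, 100)
        expected = np.arctanh(0.5) / np.sqrt(2.0 / 97.0)
        assert z == pytest.approx(expected, abs=1e-12)
        assert z == pytest.approx(3.825, abs=2e-3)
        assert p == pytest.approx(2 * stats.norm.sf(expected), abs=1e-15)

    def test_antisymmetry(self):
        z1, p1 = fisher_r_to_z(0.4, 60, -0.1, 90)
        z2, p2 = fisher_r_to_z(-0.1, 90, 0.4, 60)
        assert z1 == pytest.approx(-z2, abs=1e-15)
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="Fisher"):
            fisher_r_to_z(1.0, 50, 0.0, 50)
        with pytest.raises(ValueError, match="n > 3"):
            fisher_r_to_z(0.2, 3, 0.1, 50)

    @settings(max_examples=200, derandomize=True)
    @given(
        r1=st.floats(-0.99, 0.99), r2=st.floats(-0.99, 0.99),
        n1=st.integers(4, 500), n2=st.integers(4, 500),
    )
    def test_matches_atanh_definition(self, r1, r2, n1, n2):
        z, p = fisher_r_to_z(r1, n1, r2, n2)
        z_ref = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
            1 / (n1 - 3) + 1 / (n2 - 3)
        )
        assert z == pytest.approx(z_ref, abs=1e-12)
        assert 0.0 <= p <= 1.0


def bh_rejection_oracle(p_values, alphas):
    """q_i = smallest alpha on the grid at which step-up BH rejects p_i."""
    p = np.asarray(p_values)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.full(m, np.inf)
    for alpha in alphas:
        thresh = alpha * np.arange(1, m + 1) / m
        passing = np.flatnonzero(p[order] <= thresh)
        k = passing.max() + 1 if passing.size else 0
        for idx in order[:k]:
            q[idx] = min(q[idx], alpha)
    return q


class TestFdr:
    def test_single_p(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert q == pytest.approx([0.05] * 5, abs=1e-15)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(15)
            q = fdr_adjust(p)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)
            assert np.all(q >= p - 1e-15)
            assert np.all(q <= 1.0)

    def test_matches_rejection_threshold_oracle(self):
        rng = np.random.default_rng(1)
        grid = np.round(np.arange(0.001, 1.0001, 0.001), 3)
        for _ in range(10):
            p = np.round(rng.random(int(rng.integers(2, 13))), 3)
            q = fdr_adjust(p)
            oracle = bh_rejection_oracle(p, grid)
            # oracle resolution is the grid step
            assert q == pytest.approx(oracle, abs=1.01e-3)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.random(40)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert fdr_adjust(p) == pytest.approx(q_ref, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError, match="p-values"):
            fdr_adjust([0.1, 1.2])


class TestGroupMeans:
    def test_identical_groups_null(self):
        records = [
            make_record(subject_id=f"S{i}", group=g, age=40.0 + i)
            for g in Group for i in range(4)
        ]
        c = compare_group_means(CohortTable(records), Layer.RNFL, "C")
        assert c.t == 0.0 and c.p == 1.0

    def test_textbook_welch(self):
        records = []
        for i, v in enumerate([1.0, 2.0, 3.0]):
            records.append(make_record(subject_id=f"H{i}", group=Group.HC,
                                       age=30.0 + i,
                                       overrides={(Layer.GCL, Sector.C): v}))
        for i, v in enumerate([4.0, 5.0, 6.0]):
            records.append(make_record(subject_id=f"D{i}", group=Group.DWOR,
                                       age=30.0 + i,
                                       overrides={(Layer.GCL, Sector.C): v}))
        c = compare_group_means(CohortTable(records), Layer.GCL, "C")
        t_ref, p_ref = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False)
        assert c.t == pytest.approx(float(t_ref), abs=1e-12)
        assert c.p == pytest.approx(float(p_ref), abs=1e-12)
        assert (c.mean_hc, c.mean_dwor) == (2.0, 5.0)

    def test_planted_offset_recovered(self):
        """The +0.69 um RNFL_C offset in the DWOR-like group shows the right
        direction in most default cohorts and reaches p < 0.05 at a rate
        consistent with the Welch power at these group sizes and noise levels
        (~0.4-0.5; the effect is intrinsically borderline at n=156/78)."""
        direction = significant = 0
        for seed in range(20):
            table, _ = generate_cohort(default_config(seed=300 + seed))
            c = compare_group_means(table, Layer.RNFL, "C")
            direction += c.mean_dwor > c.mean_hc
            significant += (c.mean_dwor > c.mean_hc) and (c.p < 0.05)
        assert direction >= 15
        assert significant >= 6


class TestTrajectoryReport:
    def test_row_count_is_cartesian(self, default_cohort):
        table, _ = default_cohort
        df = trajectory_report(table)
        assert len(df) == 10 * 3  # 7 primary + 3 composite layers x 3 regions
        assert set(df.columns) >= {"layer", "region", "r_hc", "r_dwor",
                                   "z", "p", "q"}
        assert np.all(df["q"] >= df["p"] - 1e-15)

    def test_planted_hc_slope_has_smallest_q(self):
        """A strong HC-only age slope in one region dominates the family."""
        hits = 0
        for seed in range(10):
            cfg = dataclasses.replace(
                null_config(seed=500 + seed),
                age_slopes={(Group.HC, Layer.INL, s): 0.12
                            for s in (Sector.IS, Sector.II, Sector.IN, Sector.IT)},
            )
            table, _ = generate_cohort(cfg)
            df = trajectory_report(table)
            best = df.loc[df["q"].idxmin()]
            hits += (best["layer"] == "INL") and (best["region"] == "Avg_I")
        assert hits >= 7

    def test_slope_difference_flag(self):
        table, _ = generate_cohort(default_config(seed=42))
        fit_hc = fit_age_regression(table, Group.HC, Layer.INL, "C")
        fit_dw = fit_age_regression(table, Group.DWOR, Layer.INL, "C")
        z, p = slope_difference_test(fit_hc, fit_dw)
        z_ref = (fit_hc.slope - fit_dw.slope) / np.sqrt(
            fit_hc.stderr**2 + fit_dw.stderr**2
        )
        assert z == pytest.approx(z_ref, abs=1e-12)
        assert 0 <= p <= 1
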