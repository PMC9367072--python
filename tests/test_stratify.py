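"""Residual strata, per-stratum LACEs, Cochran Q and the trend test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stratmr.grs import fit_exposure_assoc
from stratmr.stratify import (
    StratumEstimate,
    assign_quantile_strata,
    cochran_q,
    residualize,
    stratified_analysis,
    stratum_lace,
    subgroup_analysis,
    trend_meta_regression,
)
from stratmr.survival import fit_outcome_assoc, ratio_estimate

from conftest import cohort_score


def make_stratum(i, median, lace, se, n=100, events=10):
    return StratumEstimate(i, n, events, median, lace, se)


class TestResidualize:
    def test_zero_beta_is_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(residualize(x, np.ones(3), 0.0), x)

    def test_perfect_instrument_gives_constant_residual(self):
        score = np.array([0.5, 1.0, 2.0])
        resid = residualize(3.0 * score, score, 3.0)
        assert np.allclose(resid, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            assign_quantile_strata(resid, 2)

    def test_residual_orthogonal_to_score(self, linear_cohort):
        cfg, table = linear_cohort
        score = cohort_score(table, cfg)
        est = fit_exposure_assoc(score, table["hscrp"].to_numpy())
        resid = residualize(table["hscrp"].to_numpy(), score, est.beta)
        assert abs(np.corrcoef(resid, score)[0, 1]) < 0.02


class TestQuantileStrata:
    def test_even_split(self):
        labels = assign_quantile_strata(np.random.default_rng(0).normal(size=100), 10)
        counts = np.bincount(labels)[1:]
        assert list(counts) == [10] * 10

    def test_remainder_rule(self):
        labels = assign_quantile_strata(np.random.default_rng(1).normal(size=101), 10)
        counts = sorted(np.bincount(labels)[1:])
        assert counts == [10] * 9 + [11]

    def test_strata_are_ordered_by_value(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=200)
        labels = assign_quantile_strata(v, 4)
        for k in range(1, 4):
            assert v[labels == k].max() <= v[labels == k + 1].min()

    def test_ties_split_deterministically(self):
        v = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 0.0])
        a = assign_quantile_strata(v, 3)
        b = assign_quantile_strata(v, 3)
        assert np.array_equal(a, b)
        assert np.bincount(a)[1:].tolist() == [2, 2, 2]

    def test_too_few_strata_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            assign_quantile_strata(np.arange(10.0), 1)


class TestCochranQ:
    def test_hand_computed_example(self):
        strata = [make_stratum(1, 1.0, 0.0, 0.1), make_stratum(2, 2.0, 0.2, 0.1)]
        q, p = cochran_q(strata)
        assert q == pytest.approx(2.0)
        assert p == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-12)
        assert p == pytest.approx(0.1573, abs=5e-4)

    def test_identical_estimates_give_zero(self):
        strata = [make_stratum(i, float(i), 0.3, 0.1) for i in range(1, 5)]
        q, p = cochran_q(strata)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        strata = [
            make_stratum(i, float(i), float(rng.normal()), 0.1 + float(rng.random()))
            for i in range(1, 8)
        ]
        q1, _ = cochran_q(strata)
        q2, _ = cochran_q(list(reversed(strata)))
        assert q1 == pytest.approx(q2)

    def test_matches_bruteforce_two_pass(self):
        rng = np.random.default_rng(4)
        strata = [
            make_stratum(i, float(i), float(rng.normal()), 0.05 + float(rng.random()))
            for i in range(1, 10)
        ]
        q, _ = cochran_q(strata)
        w = np.array([1 / s.lace_se**2 for s in strata])
        b = np.array([s.lace for s in strata])
        mean = np.sum(w * b) / np.sum(w)
        assert q == pytest.approx(np.sum(w * (b - mean) ** 2), abs=1e-12)

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError):
            cochran_q([make_stratum(1, 1.0, 0.1, 0.1)])


class TestTrend:
    def test_constant_laces_give_zero_slope(self):
        strata = [make_stratum(i, float(i), 0.25, 0.1) for i in range(1, 6)]
        slope, se, p = trend_meta_regression(strata)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_exact_linear_relation(self):
        strata = [make_stratum(i, float(i), 2.0 * i, 0.1) for i in range(1, 6)]
        slope, _, _ = trend_meta_regression(strata)
        assert slope == pytest.approx(2.0, abs=1e-10)

    def test_equal_weights_match_ols_oracle(self):
        rng = np.random.default_rng(5)
        x = np.array([0.5, 1.0, 2.0, 3.5, 5.0])
        y = rng.normal(size=5)
        strata = [make_stratum(i + 1, x[i], y[i], 0.2) for i in range(5)]
        slope, _, _ = trend_meta_regression(strata)
        ols = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(ols, abs=1e-10)

    def test_identical_medians_rejected(self):
        strata = [make_stratum(i, 1.0, 0.1 * i, 0.1) for i in range(1, 4)]
        with pytest.raises(ValueError, match="identical"):
            trend_meta_regression(strata)


class TestStratumLace:
    def test_single_stratum_reproduces_whole_cohort_estimate(self, small_cohort):
        cfg, table = small_cohort
        score = cohort_score(table, cfg)
        covs = table[["age", "sex"]]
        x = table["hscrp"].to_numpy()
        time, event = table["time"].to_numpy(), table["event"].to_numpy()
        gx = fit_exposure_assoc(score, x, covs)
        gy = fit_outcome_assoc(score, time, event, covs)
        whole = ratio_estimate(gy, gx)
        strata = stratum_lace(
            time, event, score, x, np.ones(len(table), dtype=int), covs, beta_gx=gx
        )
        assert len(strata) == 1
        assert strata[0].lace == pytest.approx(whole.beta_iv, abs=1e-12)
        assert strata[0].lace_se == pytest.approx(whole.se_iv, abs=1e-12)

    def test_partition_conservation(self, linear_cohort):
        cfg, table = linear_cohort
        score = cohort_score(table, cfg)
        covs = table[["age", "sex"]]
        x = table["hscrp"].to_numpy()
        res = stratified_analysis(
            table["time"].to_numpy(), table["event"].to_numpy(), score, x, covs, k=10
        )
        assert sum(s.n for s in res.strata) == len(table)
        assert sum(s.n_events for s in res.strata) == int(table["event"].sum())
        assert res.n_strata == 10

    def test_homogeneous_truth_gives_homogeneous_laces(self, linear_cohort):
        cfg, table = linear_cohort
        score = cohort_score(table, cfg)
        covs = table[["age", "sex"]]
        res = stratified_analysis(
            table["time"].to_numpy(), table["event"].to_numpy(), score,
            table["hscrp"].to_numpy(), covs, k=5,
        )
        for s in res.strata:
            assert abs(s.lace - cfg.theta) < 3 * s.lace_se
        assert res.p_het > 0.01


class TestSubgroups:
    def test_binary_variable_uses_natural_groups(self, linear_cohort):
        cfg, table = linear_cohort
        score = cohort_score(table, cfg)
        res = subgroup_analysis(table, "sex", score)
        assert res.n_strata == 2
        sizes = sorted(s.n for s in res.strata)
        assert sizes == sorted(
            [int((table["sex"] == 0).sum()), int((table["sex"] == 1).sum())]
        )

    def test_unknown_variable_lists_columns(self, small_cohort):
        cfg, table = small_cohort
        score = cohort_score(table, cfg)
        with pytest.raises(KeyError, match="hscrp"):
            subgroup_analysis(table, "nonexistent", score)

    def test_clinical_cutpoint_grouping(self, linear_cohort):
        cfg, table = linear_cohort
        score = cohort_score(table, cfg)
        res = subgroup_analysis(table, "ldl", score, cutpoints=[160.0])
        assert res.n_strata == 2
        # group medians straddle the cutpoint
        meds = sorted(s.exposure_median for s in res.strata)
        assert meds[0] < 160.0 < meds[1]

    def test_no_interaction_means_no_heterogeneity(self, linear_cohort):
        # simulator has no sex-exposure interaction
        cfg, table = linear_cohort
        score = cohort_score(table, cfg)
        res = subgroup_analysis(table, "sex", score)
        assert res.p_het > 0.01


class TestColliderBias:
    def test_residual_strata_less_biased_than_raw_strata(self):
        # confounded cohorts: stratifying on raw exposure conditions on a
        # collider and distorts stratum estimates; residual strata do not
        from stratmr.simulate import SimulationConfig, simulate_cohort

        resid_laces, raw_laces = [], []
        theta = 0.10
        for seed in range(10):
            cfg = SimulationConfig(n_individuals=12_000, seed=3000 + seed)
            table = simulate_cohort(cfg)
            score = cohort_score(table, cfg)
            covs = table[["age", "sex"]]
            x = table["hscrp"].to_numpy()
            time, event = table["time"].to_numpy(), table["event"].to_numpy()
            gx = fit_exposure_assoc(score, x, covs)
            resid = stratified_analysis(
                time, event, score, x, covs, k=10, beta_gx=gx
            )
            raw = stratified_analysis(
                time, event, score, x, covs, k=10, beta_gx=gx,
                stratify_values=x, stratify_on="raw_exposure",
            )
            resid_laces += [s.lace for s in resid.strata]
            raw_laces += [s.lace for s in raw.strata]
        # raw-exposure strata are systematically displaced from theta
        # (toward the confounder-induced direction); residual strata are not
        assert np.mean(raw_laces) < np.mean(resid_laces)
        assert abs(np.mean(resid_laces) - theta) < abs(np.mean(raw_laces) - theta)
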