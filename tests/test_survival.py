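"""Cox instrument-outcome fits and the ratio-of-coefficients estimator."""

import math

import numpy as np
import pandas as pd
import pytest

from stratmr.grs import AssocEstimate, fit_exposure_assoc
from stratmr.survival import (
    fit_outcome_assoc,
    format_estimate,
    ratio_estimate,
)


def make_assoc(beta, se, n=1000, model="linear", n_events=100):
    return AssocEstimate(beta=beta, se=se, n=n, model=model, n_events=n_events)


def simulate_ph(n, beta, seed, baseline=0.05, horizon=20.0):
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    t = rng.exponential(1.0 / (baseline * np.exp(beta * score)))
    event = (t <= horizon).astype(int)
    return score, np.minimum(t, horizon), event


class TestOutcomeAssoc:
    def test_recovers_log_hazard_per_score_unit(self):
        score, time, event = simulate_ph(20_000, 0.05, seed=1)
        est = fit_outcome_assoc(score, time, event)
        assert est.model == "proportional_hazards"
        assert abs(est.beta - 0.05) < 3 * est.se

    def test_matches_lifelines_cox(self):
        # independent implementation cross-check
        import lifelines

        score, time, event = simulate_ph(3_000, 0.2, seed=2)
        est = fit_outcome_assoc(score, time, event)
        df = pd.DataFrame({"s": score, "T": time, "E": event})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert est.beta == pytest.approx(cph.params_["s"], abs=1e-6)
        assert est.se == pytest.approx(cph.standard_errors_["s"], abs=1e-6)

    def test_no_events_is_error(self):
        score, time, _ = simulate_ph(100, 0.0, seed=3)
        with pytest.raises(ValueError, match="no events"):
            fit_outcome_assoc(score, time, np.zeros(100, dtype=int))

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_outcome_assoc(np.ones(5), np.array([1.0, 0.0, 1, 1, 1]), np.ones(5, dtype=int))

    def test_efron_ties_agree_with_jitter_average(self):
        # Efron's approximation targets the average over tie orderings;
        # with small tie groups the tied fit matches the jitter-averaged
        # fit to high precision
        score, time, event = simulate_ph(400, 0.2, seed=4)
        tied = np.round(time, 3) + 1e-5
        b_tied = fit_outcome_assoc(score, tied, event).beta
        betas = []
        for r in range(200):
            jit = tied + np.random.default_rng(r).uniform(0, 1e-6, size=len(tied))
            betas.append(fit_outcome_assoc(score, jit, event).beta)
        sem = np.std(betas) / np.sqrt(len(betas))
        # agreement to 1e-6 up to the Monte-Carlo error of the average
        assert abs(b_tied - np.mean(betas)) < 1e-6 + 3 * sem

    def test_wald_type_one_error_calibrated(self):
        rejections = 0
        reps = 120
        for seed in range(reps):
            score, time, event = simulate_ph(800, 0.0, seed=1000 + seed)
            est = fit_outcome_assoc(score, time, event)
            if abs(est.beta / est.se) > 1.96:
                rejections += 1
        assert 0.005 < rejections / reps < 0.12


class TestRatioEstimate:
    def test_first_order_arithmetic(self):
        mr = ratio_estimate(
            make_assoc(0.05, 0.01, model="proportional_hazards"),
            make_assoc(0.5, 1e-12),
            method="ratio_delta1",
        )
        assert mr.beta_iv == pytest.approx(0.1)
        assert mr.se_iv == pytest.approx(0.02)
        assert mr.hr == pytest.approx(math.exp(0.1))

    def test_null_numerator_gives_unit_hr(self):
        mr = ratio_estimate(
            make_assoc(0.0, 0.01, model="proportional_hazards"),
            make_assoc(0.5, 0.05),
        )
        assert mr.beta_iv == 0.0
        assert mr.hr == 1.0
        assert mr.ci_low <= 1.0 <= mr.ci_high

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            ratio_estimate(make_assoc(0.1, 0.01), make_assoc(0.0, 0.05))

    def test_second_order_delta_matches_monte_carlo(self):
        # away from the weak-instrument regime the delta expansion matches
        # the simulated sd of a ratio of independent normals within 5%
        rng = np.random.default_rng(7)
        cases = [(0.05, 0.01, 0.5, 0.04), (-0.2, 0.05, 1.0, 0.08), (0.3, 0.02, 0.8, 0.05)]
        for by, sy, bx, sx in cases:
            mr = ratio_estimate(
                make_assoc(by, sy, model="proportional_hazards"),
                make_assoc(bx, sx),
            )
            draws = rng.normal(by, sy, 400_000) / rng.normal(bx, sx, 400_000)
            assert mr.se_iv == pytest.approx(draws.std(), rel=0.05)

    def test_fieller_interval_brackets_delta_estimate(self):
        mr = ratio_estimate(
            make_assoc(0.05, 0.01, model="proportional_hazards"),
            make_assoc(0.5, 0.02),
            method="fieller",
        )
        assert mr.ci_low < mr.hr < mr.ci_high

    def test_fieller_unbounded_for_weak_instrument(self):
        mr = ratio_estimate(
            make_assoc(0.05, 0.01, model="proportional_hazards"),
            make_assoc(0.05, 0.20),
            method="fieller",
        )
        assert mr.ci_low == 0.0 or math.isinf(mr.ci_high)

    def test_scale_equivariance_in_weights(self):
        # rescaling the score rescales both stages; the ratio is invariant
        for c in (0.5, 3.0):
            a = ratio_estimate(
                make_assoc(0.05, 0.01, model="proportional_hazards"),
                make_assoc(0.5, 0.02),
            )
            b = ratio_estimate(
                make_assoc(0.05 * c, 0.01 * c, model="proportional_hazards"),
                make_assoc(0.5 * c, 0.02 * c),
            )
            assert a.beta_iv == pytest.approx(b.beta_iv)
            assert a.se_iv == pytest.approx(b.se_iv)


class TestTwoStageEquivalence:
    def test_ratio_equals_tsls_on_continuous_outcome(self):
        # one-sample identity: slope(y~G)/slope(x~G) == 2SLS slope
        rng = np.random.default_rng(11)
        n = 5_000
        g = rng.binomial(2, 0.3, n).astype(float)
        u = rng.normal(size=n)
        x = 0.4 * g + u + rng.normal(size=n)
        y = 1.5 + 0.7 * x + 2.0 * u + rng.normal(size=n)

        slope_gy = fit_exposure_assoc(g, y)
        slope_gx = fit_exposure_assoc(g, x)
        wald = slope_gy.beta / slope_gx.beta

        # independent two-stage computation
        X1 = np.column_stack([np.ones(n), g])
        xhat = X1 @ np.linalg.lstsq(X1, x, rcond=None)[0]
        X2 = np.column_stack([np.ones(n), xhat])
        tsls = np.linalg.lstsq(X2, y, rcond=None)[0][1]
        assert abs(wald - tsls) < 1e-8


class TestNaiveVsInstrumented:
    def test_confounding_biases_naive_cox_not_mr(self, linear_cohort):
        from statsmodels.duration.hazard_regression import PHReg
        from conftest import cohort_score

        cfg, table = linear_cohort
        covs = table[["age", "sex"]]
        # naive: Cox on measured exposure, confounder unadjusted
        exog = np.column_stack([table["hscrp"], covs])
        naive = PHReg(table["time"], exog, status=table["event"], ties="efron").fit(disp=0)
        assert naive.params[0] - cfg.theta > 3 * naive.bse[0]
        # instrumented: ratio estimate covers the truth
        score = cohort_score(table, cfg)
        gx = fit_exposure_assoc(score, table["hscrp"].to_numpy(), covs)
        gy = fit_outcome_assoc(score, table["time"].to_numpy(), table["event"].to_numpy(), covs)
        mr = ratio_estimate(gy, gx)
        assert abs(mr.beta_iv - cfg.theta) < 3 * mr.se_iv


class TestFormatting:
    def test_reference_interval_rendering(self):
        beta = math.log(1.11)
        se = (math.log(1.17) - math.log(1.06)) / (2 * 1.959963984540054)
        mr = ratio_estimate(
            make_assoc(beta, se, model="proportional_hazards"), make_assoc(1.0, 1e-14)
        )
        assert format_estimate(mr) == "1.11 (1.06–1.17)"

    def test_null_formats_as_one(self):
        mr = ratio_estimate(
            make_assoc(0.0, 0.01, model="proportional_hazards"), make_assoc(1.0, 1e-14)
        )
        assert format_estimate(mr).startswith("1.00 (")

    def test_digit_control_and_half_up(self):
        from stratmr.survival import _round_half_up

        # exact halves round away from zero, not to even
        assert _round_half_up(1.005, 2) == "1.01"
        assert _round_half_up(1.115, 2) == "1.12"
        mr = ratio_estimate(
            make_assoc(math.log(1.3774), 0.001, model="proportional_hazards"),
            make_assoc(1.0, 1e-14),
        )
        assert format_estimate(mr, digits=2).startswith("1.38 ")
        assert format_estimate(mr, digits=3).startswith("1.377 ")
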