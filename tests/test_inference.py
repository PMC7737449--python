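"""Estimation: sufficient statistics, closed-form MLE, covariate and shift
fits, MCMC, and likelihood correctness against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma

from edflow import presets
from edflow.inference import (
    SufficientStats, exact_loglik, extract_stats, fit_covariates, fit_mcmc,
    fit_mle, fit_shift_model, spells_from_frame,
)
from edflow.simulate import CohortConfig, simulate_cohort
from edflow.state_model import RateModel, ShiftSchedule, TRANSITIONS

from conftest import wald_ci_coverage


def one_patient_frame(t_phys=0.2, t_obs=None, t_dep=1.2, disposition="discharge",
                      arrival="2013-01-01T08:00:00.000000"):
    return pd.DataFrame(
        {
            "patient_id": ["p0"],
            "arrival_iso8601": [arrival],
            "triage_level": [3],
            "age_group": [2],
            "category": ["adult-nontrauma"],
            "t_triage_h": [0.0],
            "t_physician_h": [t_phys],
            "t_observation_h": [t_obs],
            "t_departure_h": [t_dep],
            "disposition": [disposition],
        }
    )


class TestExtractStats:
    def test_single_patient_bookkeeping(self):
        stats = extract_stats(one_patient_frame())
        assert stats.n_events[(1, 2)] == 1
        assert stats.n_events[(2, 4)] == 1
        assert sum(stats.n_events.values()) == 2
        assert stats.person_time[1] == pytest.approx(0.2)
        assert stats.person_time[2] == pytest.approx(1.0)

    def test_empty_input(self):
        stats = extract_stats(pd.DataFrame(columns=one_patient_frame().columns))
        assert all(v == 0 for v in stats.n_events.values())
        assert all(v == 0.0 for v in stats.person_time.values())

    def test_non_monotone_record_rejected_with_id(self):
        bad = one_patient_frame(t_phys=1.5, t_dep=1.2)
        with pytest.raises(ValueError, match="p0"):
            extract_stats(bad)
        stats = extract_stats(bad, on_invalid="skip")
        assert sum(stats.n_events.values()) == 0

    def test_tied_timestamps_jittered(self):
        stats = extract_stats(one_patient_frame(t_phys=0.2, t_dep=0.2))
        assert stats.n_jittered == 1
        assert stats.person_time[2] == pytest.approx(1.0 / 3600.0)

    def test_shift_attribution_follows_entry_clock(self):
        # arrival 05:30, physician at +1.0 h (06:30) -> spells in shifts 0 and 1
        df = one_patient_frame(t_phys=1.0, t_dep=2.0,
                               arrival="2013-01-01T05:30:00.000000")
        stats = extract_stats(df, shift_schedule=ShiftSchedule())
        spells = stats.spells.set_index("state")
        assert spells.loc[1, "shift"] == 0
        assert spells.loc[2, "shift"] == 1


class TestMle:
    def test_closed_form(self):
        stats = SufficientStats(
            n_events={(1, 2): 10}, person_time={1: 5.0, 2: 0.0, 3: 0.0}
        )
        fit = fit_mle(stats)
        assert fit.rates[(1, 2)].estimate == pytest.approx(2.0)
        lo, hi = fit.rates[(1, 2)].low, fit.rates[(1, 2)].high
        assert lo == pytest.approx(2.0 * math.exp(-1.959964 / math.sqrt(10)), rel=1e-5)
        assert lo < 2.0 < hi

    def test_zero_events_flagged_not_raised(self):
        stats = SufficientStats(n_events={(1, 2): 5}, person_time={1: 2.0})
        fit = fit_mle(stats)
        assert fit.rates[(1, 4)].estimate == 0.0
        assert (1, 4) in fit.flagged
        assert math.isnan(fit.rates[(1, 4)].low)

    def test_large_simulation_recovery(self, big_cohort):
        fit = fit_mle(extract_stats(big_cohort))
        assert fit.rates[(1, 2)].estimate == pytest.approx(4.224, rel=0.01)


class TestLikelihood:
    def brute_force_loglik(self, df, model):
        """Per-patient product of exponential densities and jump factors."""
        total = 0.0
        spells, _ = spells_from_frame(df)
        for row in spells.itertuples(index=False):
            exits = {j: model.baseline[(row.state, j)]
                     for (i, j) in model.baseline if i == row.state}
            r = sum(exits.values())
            total += math.log(exits[row.dest]) - r * row.sojourn_h
        return total

    def test_matches_brute_force_on_random_records(self, small_cohort):
        df = small_cohort.head(100)
        model = presets.default_model()
        stats = extract_stats(df)
        assert exact_loglik(stats, model) == pytest.approx(
            self.brute_force_loglik(df, model), abs=1e-9
        )

    def test_mle_loglik_consistent_with_exact_formula(self, small_cohort):
        stats = extract_stats(small_cohort)
        fit = fit_mle(stats)
        assert fit.loglik == pytest.approx(
            exact_loglik(stats, fit.rate_model()), abs=1e-9
        )


class TestCovariates:
    def test_intercept_only_reduces_to_mle(self, small_cohort):
        stats = extract_stats(small_cohort)
        mle = fit_mle(stats)
        reduced = fit_covariates(stats, [])
        for t in TRANSITIONS:
            if mle.rates[t].estimate > 0:
                assert reduced.rates[t].estimate == pytest.approx(
                    mle.rates[t].estimate, rel=1e-9
                )
        assert reduced.loglik == pytest.approx(mle.loglik, abs=1e-9)

    def test_constant_zero_covariate_is_null_effect(self, small_cohort):
        df = small_cohort.copy()
        df["age_group"] = 0
        stats = extract_stats(df)
        fit = fit_covariates(stats, ["age_group"], transitions=[(2, 4)])
        assert fit.rr[((2, 4), "age_group")].estimate == pytest.approx(1.0, abs=1e-8)
        mle = fit_mle(stats)
        assert fit.rates[(2, 4)].estimate == pytest.approx(
            mle.rates[(2, 4)].estimate, rel=1e-8
        )

    def test_single_rr_recovery(self):
        model = RateModel(
            baseline=dict(presets.BASELINE_RATES),
            effects={(2, 4): {"triage_level": math.log(1.891)}},
        )
        df = simulate_cohort(CohortConfig(n_patients=100_000, rate_model=model, seed=13))
        fit = fit_covariates(extract_stats(df), ["triage_level"], transitions=[(2, 4)])
        assert 1.85 <= fit.rr[((2, 4), "triage_level")].estimate <= 1.93

    def test_newton_fit_matches_glm_poisson_oracle(self, small_cohort):
        """Independent oracle: statsmodels GLM-Poisson with log-time offset
        on the same spell-level design."""
        import statsmodels.api as sm

        stats = extract_stats(small_cohort)
        fit = fit_covariates(stats, ["triage_level", "age_group"],
                             transitions=[(2, 4)])
        sub = stats.spells[stats.spells["state"] == 2]
        X = np.column_stack(
            [np.ones(len(sub)), sub["triage_level"], sub["age_group"]]
        ).astype(float)
        y = (sub["dest"] == 4).astype(float)
        glm = sm.GLM(
            y, X, family=sm.families.Poisson(),
            offset=np.log(sub["sojourn_h"].astype(float)),
        ).fit()
        assert fit.rates[(2, 4)].estimate == pytest.approx(
            math.exp(glm.params.iloc[0]), rel=1e-6
        )
        assert fit.rr[((2, 4), "triage_level")].estimate == pytest.approx(
            math.exp(glm.params.iloc[1]), rel=1e-6
        )
        assert fit.rr[((2, 4), "age_group")].estimate == pytest.approx(
            math.exp(glm.params.iloc[2]), rel=1e-6
        )

    def test_joint_two_covariate_recovery(self):
        model = RateModel(
            baseline=dict(presets.BASELINE_RATES),
            effects={(2, 4): {"triage_level": math.log(1.891),
                              "age_group": math.log(0.773)}},
        )
        df = simulate_cohort(CohortConfig(n_patients=100_000, rate_model=model, seed=17))
        fit = fit_covariates(
            extract_stats(df), ["triage_level", "age_group"], transitions=[(2, 4)]
        )
        assert fit.rr[((2, 4), "triage_level")].estimate == pytest.approx(1.891, rel=0.03)
        assert fit.rr[((2, 4), "age_group")].estimate == pytest.approx(0.773, rel=0.03)


class TestShiftModel:
    def test_recovers_shift_dependent_rate(self):
        df = simulate_cohort(
            CohortConfig(n_patients=100_000, rate_model=presets.shift_model_q35(), seed=29)
        )
        fits = fit_shift_model(df)
        spells = extract_stats(df, ShiftSchedule()).spells
        for s, q_true in enumerate(presets.SHIFT_Q35):
            est = fits[s].rates[(3, 5)].estimate
            n_events = len(spells.query("state == 3 and dest == 5 and shift == @s"))
            # 5%, widened to 3 Poisson standard errors for sparse strata
            tol = max(0.05, 3.0 / math.sqrt(max(n_events, 1)))
            assert abs(est - q_true) / q_true < tol, (s, est, q_true)

    def test_homogeneous_data_gives_agreeing_shifts(self, big_cohort):
        fits = fit_shift_model(big_cohort)
        pooled = fit_mle(extract_stats(big_cohort))
        p = pooled.rates[(2, 4)].estimate
        for s in range(4):
            iv = fits[s].rates[(2, 4)]
            se_log = (math.log(iv.high) - math.log(iv.low)) / (2 * 1.959964)
            # 4 standard errors: generous enough for four simultaneous checks
            assert abs(math.log(iv.estimate) - math.log(p)) < 4 * se_log

    def test_single_shift_arrivals_leave_others_flagged(self):
        config = CohortConfig(
            n_patients=300, seed=6, arrival_weights=(0.0, 1.0, 0.0, 0.0),
            rate_model=RateModel(baseline={(1, 2): 50.0, (2, 4): 40.0, (2, 3): 1e-3,
                                           (2, 5): 1e-3, (3, 4): 1.0, (3, 5): 1.0,
                                           (1, 4): 1e-3}),
        )
        df = simulate_cohort(config)
        fits = fit_shift_model(df)
        assert (1, 2) in fits[3].flagged  # evening saw no triage spells
        assert fits[1].rates[(1, 2)].estimate > 0


class TestMcmc:
    def test_conjugate_gamma_posterior(self):
        n, T, a, b = 57, 23.0, 2.0, 1.5
        stats = SufficientStats(n_events={(1, 2): n}, person_time={1: T})
        res = fit_mcmc(
            stats, n_iter=21000, burn_in=1000, seed=42,
            priors={(1, 2): ("gamma", a, b)},
        )
        closed_form = gamma.ppf(0.5, a + n, scale=1.0 / (b + T))
        assert res.rates[(1, 2)].estimate == pytest.approx(closed_form, rel=0.02)
        lo_exact = gamma.ppf(0.025, a + n, scale=1.0 / (b + T))
        assert res.rates[(1, 2)].low == pytest.approx(lo_exact, rel=0.05)

    def test_posterior_median_near_mle_at_large_n(self, big_cohort):
        stats = extract_stats(big_cohort)
        res = fit_mcmc(stats, n_iter=8000, burn_in=2000, seed=3)
        mle = fit_mle(stats)
        for t in ((1, 2), (2, 3), (2, 4), (2, 5)):
            assert res.rates[t].estimate == pytest.approx(
                mle.rates[t].estimate, rel=0.01
            )

    def test_fixed_seed_reproducible(self, small_cohort):
        stats = extract_stats(small_cohort)
        a = fit_mcmc(stats, n_iter=2000, burn_in=500, seed=8)
        b = fit_mcmc(stats, n_iter=2000, burn_in=500, seed=8)
        for t in TRANSITIONS:
            assert np.array_equal(a.draws.get(t, np.array([])),
                                  b.draws.get(t, np.array([])))

    def test_acceptance_rate_reported(self, small_cohort):
        res = fit_mcmc(extract_stats(small_cohort), n_iter=3000, burn_in=1000, seed=1)
        rates = res.diagnostics["acceptance_rates"]
        assert rates and all(0.0 < v < 1.0 for v in rates.values())

    def test_iteration_budget_validated(self, small_cohort):
        with pytest.raises(ValueError):
            fit_mcmc(extract_stats(small_cohort), n_iter=100, burn_in=100)


def test_wald_interval_coverage():
    """95% CIs should cover the generating rate in 90-99% of replicates."""
    cover = wald_ci_coverage(n_reps=200, n_patients=2000)
    assert 0.90 <= cover <= 0.99
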