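"""Parametric survival representation, evaluation, fitting and ranking."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from psmcea import (
    Family,
    ParametricSurvival,
    SimSpec,
    SurvivalDataset,
    fit_parametric,
    median_survival,
    select_best_fit,
    simulate_ipd,
    survival_at,
)

LL = Family.LOG_LOGISTIC


class TestSurvivalAt:
    @pytest.mark.parametrize(
        "model",
        [
            ParametricSurvival(LL, 1.54, 0.013),
            ParametricSurvival(Family.WEIBULL, 1.2, 0.05),
            ParametricSurvival(Family.EXPONENTIAL, 1.0, 0.08),
            ParametricSurvival(Family.LOG_NORMAL, 0.9, 12.0),
            ParametricSurvival(Family.GOMPERTZ, 0.05, 0.03),
            ParametricSurvival(Family.GAMMA, 1.7, 0.1),
        ],
        ids=lambda m: m.family.value,
    )
    def test_survival_starts_at_one(self, model):
        assert survival_at(model, 0.0) == 1.0

    def test_loglogistic_half_life_when_lambda_t_gamma_is_one(self):
        # lambda * t**gamma = 1 forces S = 1/2 regardless of the parameters
        model = ParametricSurvival(LL, 1.54, 0.013)
        t_half = (1.0 / 0.013) ** (1.0 / 1.54)
        assert survival_at(model, t_half) == pytest.approx(0.5, abs=1e-12)

    def test_loglogistic_matches_direct_arithmetic(self):
        model = ParametricSurvival(LL, 1.92, 0.010)
        expected = 1.0 / (1.0 + 0.010 * 120.0**1.92)  # hand oracle
        assert survival_at(model, 120.0) == pytest.approx(expected, rel=1e-15)

    def test_negative_time_rejected(self):
        model = ParametricSurvival(LL, 1.5, 0.02)
        with pytest.raises(ValueError, match="non-negative"):
            survival_at(model, -1.0)

    @pytest.mark.parametrize("shape,scale", [(-1.0, 0.1), (0.0, 0.1), (1.0, -2.0),
                                             (float("nan"), 0.1), (1.0, float("inf"))])
    def test_invalid_parameters_rejected(self, shape, scale):
        with pytest.raises(ValueError):
            ParametricSurvival(LL, shape, scale)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        family=st.sampled_from(list(Family)),
        shape=st.floats(0.3, 4.0),
        log_scale=st.floats(-7.0, -0.5),
    )
    def test_survival_non_increasing_and_vanishing(self, family, shape, log_scale):
        shape = 1.0 if family is Family.EXPONENTIAL else shape
        scale = math.exp(log_scale)
        if family is Family.GOMPERTZ:
            shape = shape / 20.0  # hazard growth rate on a monthly scale
        model = ParametricSurvival(family, shape, scale)
        t = np.linspace(0.0, 600.0, 200)
        s = model.survival(t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0.0) & (s <= 1.0))


class TestMedianSurvival:
    def test_closed_form_simple_case(self):
        assert median_survival(ParametricSurvival(LL, 1.0, 0.1)) == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "shape,scale,expected_months",
        [
            (2.29, 0.024, 5.1),   # chemotherapy PFS, all-randomized
            (1.94, 0.0096, 11.0),  # chemotherapy OS, CPS>=5
        ],
    )
    def test_fixture_medians_track_trial_medians(self, shape, scale, expected_months):
        assert median_survival(ParametricSurvival(LL, shape, scale)) == pytest.approx(
            expected_months, abs=0.1
        )

    @pytest.mark.parametrize("shape,scale", [(1.54, 0.013), (2.29, 0.024), (0.8, 0.2)])
    def test_closed_form_agrees_with_bisection(self, shape, scale):
        model = ParametricSurvival(LL, shape, scale)
        root = brentq(lambda t: survival_at(model, t) - 0.5, 1e-9, 1e6, xtol=1e-12)
        assert median_survival(model) == pytest.approx(root, abs=1e-8)

    @pytest.mark.parametrize("family", [f for f in Family if f is not LL])
    def test_other_families_have_half_survival_at_median(self, family):
        shape = 1.0 if family is Family.EXPONENTIAL else 1.3
        if family is Family.GOMPERTZ:
            shape = 0.05
        model = ParametricSurvival(family, shape, 0.05)
        assert survival_at(model, median_survival(model)) == pytest.approx(0.5, abs=1e-9)


class TestSurvivalDataset:
    def test_csv_round_trip(self, tmp_path):
        data = SurvivalDataset(times=[1.0, 2.5, 7.0], events=[1, 0, 1])
        path = tmp_path / "ipd.csv"
        data.to_csv(path)
        back = SurvivalDataset.from_csv(path)
        np.testing.assert_array_equal(back.times, data.times)
        np.testing.assert_array_equal(back.events, data.events)

    def test_validation(self):
        with pytest.raises(ValueError):
            SurvivalDataset(times=[], events=[])
        with pytest.raises(ValueError):
            SurvivalDataset(times=[1.0, -2.0], events=[1, 1])
        with pytest.raises(ValueError):
            SurvivalDataset(times=[1.0], events=[2])


class TestFitParametric:
    def test_exponential_mle_matches_closed_form(self):
        data = simulate_ipd(
            SimSpec(Family.EXPONENTIAL, 1.0, 0.08, n_subjects=800,
                    censoring_fraction_target=0.25, max_followup_months=200, seed=11)
        )
        fit = fit_parametric(data, Family.EXPONENTIAL)
        rate_closed_form = data.n_events / data.times.sum()
        assert fit.converged
        assert fit.model.scale == pytest.approx(rate_closed_form, rel=1e-5)
        assert fit.n_params == 1

    def test_recovers_loglogistic_parameters(self):
        data = simulate_ipd(
            SimSpec(LL, 1.54, 0.013, n_subjects=5000,
                    censoring_fraction_target=0.2, max_followup_months=240, seed=3)
        )
        fit = fit_parametric(data, LL)
        assert fit.converged
        assert fit.model.shape == pytest.approx(1.54, rel=0.05)
        assert fit.model.scale == pytest.approx(0.013, rel=0.15)

    def test_fit_is_deterministic(self):
        data = simulate_ipd(SimSpec(LL, 1.8, 0.02, n_subjects=500, seed=4))
        a, b = fit_parametric(data, LL), fit_parametric(data, LL)
        assert a.model == b.model
        assert a.log_likelihood == b.log_likelihood
        assert a.aic == b.aic and a.bic == b.bic

    def test_all_censored_is_unidentifiable(self):
        data = SurvivalDataset(times=np.arange(1.0, 21.0), events=np.zeros(20, int))
        with pytest.raises(ValueError, match="censored"):
            fit_parametric(data, LL)

    def test_aic_bic_identities(self):
        data = simulate_ipd(SimSpec(LL, 1.6, 0.03, n_subjects=400, seed=9))
        for family in (LL, Family.WEIBULL, Family.EXPONENTIAL):
            fit = fit_parametric(data, family)
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.log_likelihood)
            assert fit.bic == pytest.approx(
                fit.n_params * math.log(fit.n_obs) - 2 * fit.log_likelihood
            )

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        data = simulate_ipd(
            SimSpec(LL, 1.54, 0.013, n_subjects=3000,
                    censoring_fraction_target=0.2, max_followup_months=240, seed=7)
        )
        theirs = lifelines.LogLogisticFitter().fit(data.times, data.events)
        mine = fit_parametric(data, LL)
        assert mine.model.shape == pytest.approx(theirs.beta_, rel=1e-4)
        assert mine.model.scale == pytest.approx(theirs.alpha_ ** -theirs.beta_, rel=1e-4)
        assert mine.log_likelihood == pytest.approx(theirs.log_likelihood_, rel=1e-9)


class TestSelectBestFit:
    def test_single_family_gives_single_result(self):
        data = simulate_ipd(SimSpec(LL, 1.5, 0.02, n_subjects=300, seed=1))
        results = select_best_fit(data, [LL])
        assert len(results) == 1

    def test_results_sorted_by_aic_then_bic_then_name(self):
        data = simulate_ipd(SimSpec(LL, 1.8, 0.02, n_subjects=1500, seed=2))
        results = select_best_fit(data, list(Family))
        keys = [(not r.converged, r.aic, r.bic, r.model.family.value) for r in results]
        assert keys == sorted(keys)

    def test_true_family_usually_ranks_first(self):
        wins = 0
        for seed in range(10):
            data = simulate_ipd(
                SimSpec(LL, 1.8, 0.02, n_subjects=2000,
                        censoring_fraction_target=0.15, max_followup_months=200,
                        seed=seed)
            )
            ranked = select_best_fit(
                data, [LL, Family.LOG_NORMAL, Family.WEIBULL]
            )
            wins += ranked[0].model.family is LL
        assert wins >= 8

    def test_tied_fits_break_on_family_name(self):
        data = simulate_ipd(SimSpec(LL, 1.5, 0.02, n_subjects=300, seed=6))
        results = select_best_fit(data, [LL, Family.WEIBULL])
        forced = [dataclasses.replace(r, log_likelihood=-100.0, n_params=2)
                  for r in results]
        forced.sort(key=lambda r: (not r.converged, r.aic, r.bic, r.model.family.value))
        assert forced[0].aic == forced[1].aic
        assert [r.model.family.value for r in forced] == sorted(
            r.model.family.value for r in forced
        )
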