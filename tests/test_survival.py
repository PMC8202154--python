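"""Cox partial likelihood, C-index, KM/log-rank and stepwise selection
checked against brute-force oracles and lifelines."""

import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from bioage.errors import (
    DegenerateDataError,
    EmptyRiskSetError,
    NotNestedError,
    OrderingError,
)
from bioage.survival import (
    SurvivalFit,
    adjusted_c,
    cox_log_likelihood,
    fit_cox,
    harrells_c,
    kaplan_meier,
    likelihood_ratio_test,
    log_rank,
    proportion_explained,
    stepwise_mortality_score,
    survival_at,
)


def naive_partial_ll(beta, x, times, events, ties):
    """Direct summation over event times; independent of the implementation."""
    beta = np.atleast_1d(beta)
    eta = x @ beta
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        risk = times >= t
        d = tied.sum()
        ll += eta[tied].sum()
        for el in range(d):
            frac = el / d if ties == "efron" else 0.0
            ll -= np.log(np.exp(eta[risk]).sum() - frac * np.exp(eta[tied]).sum())
    return ll


def fixture_no_ties():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.array([1, 1, 0, 1, 0, 1])
    x = np.array([[1.0], [0.0], [1.0], [0.0], [1.0], [0.0]])
    return x, times, events


def fixture_with_ties():
    times = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    events = np.array([1, 1, 1, 0, 1, 0, 1, 0])
    x = np.array([[1.0], [0.5], [0.0], [1.0], [0.0], [1.0], [0.0], [0.5]])
    return x, times, events


class TestFitCox:
    def test_null_log_likelihood_matches_hand_summation(self):
        x, times, events = fixture_no_ties()
        fit = fit_cox(x, times, events)
        # risk-set sizes at the event times 1, 2, 4, 6 are 6, 5, 3, 1
        assert fit.ll_null == pytest.approx(-np.log([6, 5, 3, 1]).sum(), abs=1e-12)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    @pytest.mark.parametrize("fixture", [fixture_no_ties, fixture_with_ties])
    def test_estimate_matches_grid_search_oracle(self, fixture, ties):
        x, times, events = fixture()
        fit = fit_cox(x, times, events, ties=ties)
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = np.array([naive_partial_ll(b, x, times, events, ties) for b in grid])
        best = grid[np.argmax(lls)]
        assert abs(fit.params.iloc[0] - best) < 1e-3
        assert fit.ll == pytest.approx(lls.max(), abs=1e-6)
        assert fit.max_gradient < 1e-6
        assert fit.ll >= fit.ll_null

    def test_log_likelihood_function_agrees_with_naive(self):
        x, times, events = fixture_with_ties()
        for beta in (-0.7, 0.0, 1.3):
            for ties in ("efron", "breslow"):
                assert cox_log_likelihood(beta, x, times, events, ties) == pytest.approx(
                    naive_partial_ll(beta, x, times, events, ties), abs=1e-10
                )

    def test_duplicated_dataset_leaves_estimate_unchanged(self):
        x, times, events = fixture_no_ties()
        fit = fit_cox(x, times, events, ties="breslow")
        fit_dup = fit_cox(
            np.vstack([x, x]),
            np.concatenate([times, times]),
            np.concatenate([events, events]),
            ties="breslow",
        )
        # Breslow's tie rule makes duplication an exact likelihood rescaling
        assert fit_dup.params.iloc[0] == pytest.approx(fit.params.iloc[0], abs=1e-8)

    def test_matches_lifelines_on_simulated_data(self, rng):
        n = 400
        x = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        hazard = 0.05 * np.exp(0.5 * x["a"] - 0.3 * x["b"])
        t_event = rng.exponential(1 / hazard)
        censor = rng.uniform(2, 15, n)
        times = np.minimum(t_event, censor)
        events = (t_event <= censor).astype(int)
        fit = fit_cox(x, times, events)
        cph = CoxPHFitter()
        frame = x.assign(time=times, event=events)
        cph.fit(frame, duration_col="time", event_col="event")
        np.testing.assert_allclose(fit.params, cph.params_, atol=1e-4)
        assert fit.ll == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_no_events_raises(self):
        with pytest.raises(EmptyRiskSetError):
            fit_cox(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]), np.zeros(3, dtype=int))

    def test_perfect_separation_flagged(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 0])
        x = np.array([[1.0], [1.0], [0.0], [0.0]])  # events only at x=1
        with pytest.warns(UserWarning, match="converge"):
            fit = fit_cox(x, times, events)
        assert not fit.converged
        assert np.all(np.abs(fit.params) <= 10.0)


class TestProportionExplained:
    @pytest.mark.parametrize(
        "lls, expected",
        [
            ((-100.0, -90.0, -90.0), 1.0),
            ((-100.0, -100.0, -90.0), 0.0),
            ((-100.0, -95.0, -90.0), 0.5),
        ],
    )
    def test_arithmetic(self, lls, expected):
        assert proportion_explained(*lls) == pytest.approx(expected)

    def test_zero_denominator_is_missing(self):
        assert proportion_explained(-100.0, -100.0, -100.0) is None

    def test_ordering_violation_raises(self):
        with pytest.raises(OrderingError):
            proportion_explained(-90.0, -95.0, -85.0)


def dummy_fit(names, ll):
    return SurvivalFit(
        params=pd.Series(np.zeros(len(names)), index=names),
        ll=ll,
        ll_null=-100.0,
        n=10,
        n_events=5,
        converged=True,
        max_gradient=0.0,
        ties="efron",
    )


class TestLikelihoodRatio:
    def test_identical_models(self):
        fit = dummy_fit(["a"], -90.0)
        statistic, df, p = likelihood_ratio_test(fit, fit)
        assert statistic == 0.0 and df == 0 and p == 1.0

    def test_chi_square_quantile(self):
        statistic, df, p = likelihood_ratio_test(
            dummy_fit(["a"], -90.0), dummy_fit(["a", "b"], -90.0 + 3.841 / 2)
        )
        assert df == 1
        assert p == pytest.approx(0.050, abs=1e-3)

    def test_non_nested_raises(self):
        with pytest.raises(NotNestedError):
            likelihood_ratio_test(dummy_fit(["a"], -90.0), dummy_fit(["b", "c"], -85.0))


def brute_force_c(scores, times, events):
    """O(n^2) pair enumeration with Harrell's conventions: the earlier time
    must be an event; at tied times an event-censored pair is comparable
    (the censored member is known to live longer) but an event-event pair
    is not."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        if not events[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            comparable = times[i] < times[j] or (
                times[i] == times[j] and not events[j]
            )
            if not comparable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den if den else float("nan")


class TestHarrellsC:
    def test_perfect_concordance(self):
        assert harrells_c([3, 2, 1], [1.0, 2.0, 3.0], [1, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert harrells_c([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1]) == 0.5

    def test_censored_fixture_matches_pair_enumeration(self, rng):
        scores = np.array([0.3, 1.2, -0.5, 0.9, 0.9, 2.0, -1.1, 0.0])
        times = np.array([2.0, 1.0, 5.0, 3.0, 4.0, 1.5, 6.0, 2.5])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        assert harrells_c(scores, times, events) == pytest.approx(
            brute_force_c(scores, times, events)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_data_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        scores = rng.normal(size=n).round(1)  # rounded to force score ties
        times = rng.integers(1, 10, n).astype(float)  # time ties too
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        assert harrells_c(scores, times, events) == pytest.approx(
            brute_force_c(scores, times, events)
        )

    def test_no_events_is_missing(self):
        assert np.isnan(harrells_c([1, 2], [1.0, 2.0], [0, 0]))


class TestAdjustedC:
    def make_data(self, rng, n=800):
        age = rng.uniform(40, 70, n)
        hazard = 0.01 * np.exp(0.08 * (age - 55))
        t_event = rng.exponential(1 / hazard)
        censor = rng.uniform(6, 12, n)
        times = np.minimum(t_event, censor)
        events = (t_event <= censor).astype(int)
        return age, times, events

    def test_degenerate_adjustment_equals_unadjusted(self, rng):
        age, times, events = self.make_data(rng)
        covs = pd.DataFrame({"z": np.zeros(len(age))})
        fit = fit_cox(pd.DataFrame({"risk_age": age}), times, events)
        assert fit.params.iloc[0] > 0
        assert adjusted_c(age, covs, times, events) == pytest.approx(
            harrells_c(age, times, events)
        )

    def test_noise_covariate_barely_moves_c(self, rng):
        age, times, events = self.make_data(rng, n=5000)
        base = adjusted_c(age, pd.DataFrame({"z": np.zeros(len(age))}), times, events)
        noisy = adjusted_c(
            age, pd.DataFrame({"z": rng.standard_normal(len(age))}), times, events
        )
        assert abs(noisy - base) < 0.01

    def test_leakage_covariate_inflates_c(self, rng):
        age, times, events = self.make_data(rng)
        base = harrells_c(age, times, events)
        leaky = adjusted_c(
            age, pd.DataFrame({"leak": events.astype(float)}), times, events
        )
        assert leaky > base


class TestKaplanMeierLogRank:
    def test_no_events_curve_is_flat_one(self):
        curves = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0], ["g", "g", "g"])
        assert (curves["g"]["survival"] == 1.0).all()
        statistic, _, p = log_rank([1.0, 2.0, 3.0], [0, 0, 0], ["g", "g", "h"])
        assert np.isnan(statistic) and np.isnan(p)

    def test_single_event_step_closed_form(self):
        n = 5
        times = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 0, 0, 0, 0])
        curves = kaplan_meier(times, events, np.full(n, "g"))
        assert survival_at(curves["g"], 1.9) == 1.0
        assert survival_at(curves["g"], 2.0) == pytest.approx(1 - 1 / n)
        assert survival_at(curves["g"], 6.0) == pytest.approx(1 - 1 / n)

    def test_identical_groups_give_zero_statistic(self):
        times = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        events = np.array([1, 0, 1, 1] * 2)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        statistic, df, p = log_rank(times, events, groups)
        assert df == 1
        assert statistic == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(EmptyRiskSetError):
            kaplan_meier([], [], [])


class TestStepwise:
    def make_scores(self, rng, n, n_noise):
        scores = pd.DataFrame(
            {f"noise{i}": rng.standard_normal(n) for i in range(n_noise)}
        )
        scores["signal"] = rng.standard_normal(n)
        hazard = 0.05 * np.exp(0.8 * scores["signal"])
        t_event = rng.exponential(1 / hazard)
        censor = rng.uniform(6, 12, n)
        return scores, np.minimum(t_event, censor), (t_event <= censor).astype(int)

    def test_planted_signal_is_selected_first(self, rng):
        scores, times, events = self.make_scores(rng, 4000, 5)
        selected, fit, predictor = stepwise_mortality_score(scores, times, events)
        assert selected[0] == "signal"
        assert selected == ["signal"]
        assert fit.params["signal"] == pytest.approx(0.8, abs=0.1)
        assert predictor.shape == (4000,)

    def test_null_entry_rate_consistent_with_alpha(self):
        # 3 pure-noise candidates: P(any enters) ~ 1 - 0.95^3 ~ 0.14
        n_sims, entered = 120, 0
        for sim in range(n_sims):
            rng = np.random.default_rng(1000 + sim)
            scores = pd.DataFrame({f"n{i}": rng.standard_normal(80) for i in range(3)})
            t_event = rng.exponential(1 / 0.08, 80)
            censor = rng.uniform(6, 12, 80)
            times = np.minimum(t_event, censor)
            events = (t_event <= censor).astype(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected, _, _ = stepwise_mortality_score(scores, times, events)
            entered += bool(selected)
        p = 1 - 0.95**3
        se = np.sqrt(p * (1 - p) / n_sims)
        assert abs(entered / n_sims - p) < 4 * se

    def test_zero_events_propagates_error(self, rng):
        scores = pd.DataFrame({"a": rng.standard_normal(5)})
        with pytest.raises(EmptyRiskSetError):
            stepwise_mortality_score(scores, np.arange(1.0, 6.0), np.zeros(5, dtype=int))
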