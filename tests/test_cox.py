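import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

from cnvsurv.cox import (CoxFit, NonIdentifiableError, SurvivalData,
                         fit_cox_left_truncated, kaplan_meier, partial_loglik)
from cnvsurv.cox import test_categorical_2df as categorical_test
from cnvsurv.cox import test_trend as trend_test
from cnvsurv.simulate import SimulationConfig, simulate_survival


def random_fixture(rng, n=12, p=1, truncated=True):
    x = rng.normal(size=(n, p))
    T = rng.exponential(1.0 / (0.01 * np.exp(0.5 * x[:, 0])))
    entry = rng.uniform(0, 60, n) if truncated else np.zeros(n)
    exit_ = np.maximum(T, entry + 1e-3)
    event = rng.random(n) < 0.8
    if not event.any():
        event[0] = True
    return SurvivalData(entry, exit_, event.astype(int), x)


def oracle_beta(data, ties="efron"):
    """Direct numeric maximization of the delayed-entry partial likelihood."""
    p = data.X.shape[1]
    res = optimize.minimize(
        lambda b: -partial_loglik(b, data, ties), np.zeros(p),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return res.x


class TestFit:
    def test_constant_covariate_rejected(self):
        d = SurvivalData([0, 0, 0], [1, 2, 3], [1, 1, 0],
                         np.ones((3, 1)), ("c",))
        with pytest.raises(NonIdentifiableError, match="non-identifiable"):
            fit_cox_left_truncated(d)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_numeric_maximization(self, seed, ties):
        rng = np.random.default_rng(seed)
        d = random_fixture(rng, n=8 + seed, p=1 + seed % 2)
        fit = fit_cox_left_truncated(d, ties=ties)
        assert fit.converged
        assert np.max(np.abs(fit.beta - oracle_beta(d, ties))) < 1e-4

    def test_never_at_risk_subject_is_inert(self):
        rng = np.random.default_rng(10)
        d = random_fixture(rng, n=15)
        # add a censored subject entering after every event time
        last = d.exit.max()
        d2 = SurvivalData(np.append(d.entry, last + 10),
                          np.append(d.exit, last + 20),
                          np.append(d.event, 0),
                          np.vstack([d.X, [[1.5]]]))
        f1 = fit_cox_left_truncated(d)
        f2 = fit_cox_left_truncated(d2)
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)
        assert np.allclose(f1.loglik, f2.loglik, atol=1e-10)

    def test_zero_entries_equal_untruncated_lifelines_fit(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        d = random_fixture(rng, n=60, p=2, truncated=False)
        fit = fit_cox_left_truncated(d)
        df = pd.DataFrame({"T": d.exit, "E": d.event,
                           "x0": d.X[:, 0], "x1": d.X[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, duration_col="T", event_col="E")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-4)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-4)

    def test_delayed_entry_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        d = random_fixture(rng, n=80, p=2)
        fit = fit_cox_left_truncated(d)
        df = pd.DataFrame({"entry": d.entry, "T": d.exit, "E": d.event,
                           "x0": d.X[:, 0], "x1": d.X[:, 1]})
        cph = lifelines.CoxPHFitter().fit(df, duration_col="T", event_col="E",
                                          entry_col="entry")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-4)

    def test_covariate_shift_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        d = random_fixture(rng, n=40)
        f0 = fit_cox_left_truncated(d)
        d_shift = SurvivalData(d.entry, d.exit, d.event, d.X + 7.0)
        d_scale = SurvivalData(d.entry, d.exit, d.event, d.X * 4.0)
        assert np.allclose(fit_cox_left_truncated(d_shift).beta, f0.beta,
                           atol=1e-6)
        assert np.allclose(fit_cox_left_truncated(d_scale).beta, f0.beta / 4.0,
                           atol=1e-6)

    def test_separation_flagged_not_silent(self):
        # perfect separation: covariate 1 exactly for the early deaths
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])[:, None]
        d = SurvivalData(np.zeros(6), [1, 2, 3, 10, 11, 12],
                         [1, 1, 1, 0, 0, 0], x)
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_cox_left_truncated(d)
        assert not fit.converged and fit.separation
        assert np.isnan(fit.p_wald).all()

    def test_hr_ci_brackets_estimate(self):
        rng = np.random.default_rng(6)
        fit = fit_cox_left_truncated(random_fixture(rng, n=50))
        assert fit.ci95[0, 0] < fit.hr[0] < fit.ci95[0, 1]
        assert fit.hr[0] > 0


class TestTrendAndCategorical:
    def _data(self, rng, n=120):
        x = rng.normal(size=(n, 1))
        T = rng.exponential(100.0, n)
        entry = rng.uniform(0, 20, n)
        exit_ = np.maximum(T, entry + 1e-3)
        return SurvivalData(entry, exit_, np.ones(n, int), x)

    def test_constant_states_error(self):
        rng = np.random.default_rng(0)
        d = self._data(rng)
        with pytest.raises(NonIdentifiableError):
            trend_test(np.zeros(d.n), d)
        with pytest.raises(NonIdentifiableError):
            categorical_test(np.zeros(d.n), d)

    def test_categorical_df_collapses_without_gains(self):
        rng = np.random.default_rng(1)
        d = self._data(rng)
        states = rng.choice([-1, 0], size=d.n, p=[0.3, 0.7])
        _, p, df = categorical_test(states, d)
        assert df == 1

    def test_both_levels_give_two_df(self):
        rng = np.random.default_rng(2)
        d = self._data(rng)
        states = rng.choice([-1, 0, 1], size=d.n)
        _, p, df = categorical_test(states, d)
        assert df == 2 and 0 <= p <= 1

    def test_binary_states_categorical_equals_trend_lrt(self):
        # with only {0, +1} states the categorical test is the 1-df LRT of
        # the trend coding (the two codings are affinely equivalent)
        rng = np.random.default_rng(3)
        d = self._data(rng)
        states = rng.choice([0, 1], size=d.n)
        _, p_cat, df = categorical_test(states, d)
        full = fit_cox_left_truncated(d.with_tested(states.astype(float)))
        red = fit_cox_left_truncated(d)
        p_lrt = stats.chi2.sf(2 * (full.loglik - red.loglik), 1)
        assert df == 1
        assert p_cat == pytest.approx(p_lrt, rel=1e-6)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        d = SurvivalData(np.zeros(4), [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                         np.zeros((4, 1)))
        curves = kaplan_meier(np.zeros(4, int), d)
        t, s = curves[0]
        assert np.allclose(t, [1, 2, 3, 4])
        assert np.allclose(s, [0.75, 0.5, 0.25, 0.0])

    def test_no_events_flat_at_one(self):
        d = SurvivalData(np.zeros(3), [5.0, 6.0, 7.0], [1, 0, 0],
                         np.zeros((3, 1)))
        curves = kaplan_meier(np.array([0, 1, 1]), d)
        t, s = curves[1]
        assert s.size == 0  # no event times in the group -> flat curve at 1

    def test_delayed_entry_shrinks_early_risk_set(self):
        # subject entering after the first event is absent from its risk set
        d1 = SurvivalData([0, 0, 0], [1.0, 5.0, 6.0], [1, 1, 0],
                          np.zeros((3, 1)))
        d2 = SurvivalData([0, 2.0, 0], [1.0, 5.0, 6.0], [1, 1, 0],
                          np.zeros((3, 1)))
        s1 = kaplan_meier(np.zeros(3, int), d1)[0][1]
        s2 = kaplan_meier(np.zeros(3, int), d2)[0][1]
        assert s1[0] == pytest.approx(2 / 3)
        assert s2[0] == pytest.approx(1 / 2)  # only 2 at risk at t=1

    def test_matches_lifelines_with_entry(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(8)
        n = 50
        T = rng.exponential(10, n)
        entry = rng.uniform(0, 3, n)
        exit_ = np.maximum(T, entry + 1e-6)
        event = (rng.random(n) < 0.7).astype(int)
        event[0] = 1
        d = SurvivalData(entry, exit_, event, np.zeros((n, 1)))
        t, s = kaplan_meier(np.zeros(n, int), d)[0]
        kmf = lifelines.KaplanMeierFitter().fit(exit_, event, entry=entry)
        ref = kmf.survival_function_at_times(t).to_numpy()
        assert np.allclose(s, ref, atol=1e-10)


class TestAgainstSimulator:
    def test_recovers_planted_log_hazard(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(11)
        n = 1500
        carrier = (rng.random(n) < 0.3).astype(float)
        entry, exit_, event, _ = simulate_survival(cfg, np.log(2.0) * carrier,
                                                   rng)
        fit = fit_cox_left_truncated(
            SurvivalData(entry, exit_, event, carrier[:, None], ("c",)))
        assert abs(fit.beta[0] - np.log(2.0)) < 3 * fit.se[0]

    def test_naive_fit_more_biased_than_delayed_entry(self):
        # strong truncation: ignoring entry times inflates the estimate
        cfg = SimulationConfig(entry_max_days=2000.0, baseline_hazard=5e-4,
                               censor_days=10000.0)
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.choice([0.0, 1.0], n, p=[0.8, 0.2])
        beta = np.log(2.0)
        entry, exit_, event, _ = simulate_survival(cfg, beta * x, rng)
        delayed = fit_cox_left_truncated(
            SurvivalData(entry, exit_, event, x[:, None]))
        naive = fit_cox_left_truncated(
            SurvivalData(np.zeros(n), exit_, event, x[:, None]))
        assert abs(naive.beta[0] - beta) > abs(delayed.beta[0] - beta)
        assert abs(delayed.beta[0] - beta) < 3 * delayed.se[0]
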