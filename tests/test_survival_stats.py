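import numpy as np
import pytest
from scipy import stats

import survscan as sv
from survscan.survival_stats import (
    _cox_scores_batch,
    _logrank_scores_batch,
    _prepare_sorted,
)


def _random_data(rng, n, tie_free=True):
    if tie_free:
        t = rng.exponential(10, n)
    else:
        t = rng.integers(1, 8, n).astype(float)
    e = (rng.random(n) < 0.65).astype(float)
    if e.sum() < 2:
        e[:2] = 1
    return sv.SurvivalData(t, e)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        data = sv.SurvivalData([1, 2, 3, 4], [1, 1, 0, 1])
        curve = sv.km_estimate(data, ["all"] * 4)["all"]
        np.testing.assert_array_equal(curve.event_times, [1, 2, 4])
        np.testing.assert_allclose(curve.survival, [0.75, 0.50, 0.0])
        assert curve.survival_at(3.5) == 0.50
        assert curve.observed == 3.0 and curve.expected == 3.0

    def test_all_censored(self):
        data = sv.SurvivalData([1, 2, 3], [0, 0, 0])
        curves = sv.km_estimate(data, list("aab"))
        for c in curves:
            assert c.observed == 0.0
            assert len(c.event_times) == 0

    def test_identical_groups_have_identical_curves(self):
        t = [2.0, 5.0, 9.0, 11.0]
        e = [1.0, 0.0, 1.0, 1.0]
        data = sv.SurvivalData(t + t, e + e)
        curves = sv.km_estimate(data, ["A"] * 4 + ["B"] * 4)
        a, b = curves["A"], curves["B"]
        np.testing.assert_array_equal(a.survival, b.survival)
        assert a.expected == pytest.approx(b.expected)

    def test_obs_and_exp_totals_match_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(6, 40))
            data = _random_data(rng, n, tie_free=bool(rng.integers(2)))
            groups = rng.integers(0, 3, n).astype(str)
            curves = sv.km_estimate(data, groups)
            obs = sum(c.observed for c in curves)
            exp = sum(c.expected for c in curves)
            assert obs == pytest.approx(exp, abs=1e-10)
            assert obs == pytest.approx(curves.total_events)

    def test_survival_is_monotone_in_unit_interval(self):
        rng = np.random.default_rng(6)
        data = _random_data(rng, 40, tie_free=False)
        for c in sv.km_estimate(data, ["g"] * 40):
            assert (np.diff(c.survival) <= 1e-12).all()
            assert ((c.survival >= 0) & (c.survival <= 1)).all()

    def test_missing_survival_omitted_and_counted(self):
        data = sv.SurvivalData([1, 2, np.nan], [1, 0, np.nan])
        curves = sv.km_estimate(data, ["a", "a", "a"])
        assert curves.n_omitted == 1
        assert curves["a"].n == 2


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [3.0, 7.0, 12.0]
        e = [1.0, 1.0, 0.0]
        data = sv.SurvivalData(t + t, e + e)
        res = sv.logrank_test(data, ["A"] * 3 + ["B"] * 3)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_match_reference(self):
        from lifelines.statistics import logrank_test as ll_logrank

        t = np.array([1.0, 2, 3, 10, 11, 12])
        e = np.ones(6)
        g = ["A"] * 3 + ["B"] * 3
        res = sv.logrank_test(sv.SurvivalData(t, e), g)
        ref = ll_logrank(t[:3], t[3:], e[:3], e[3:])
        assert res.chi_square == pytest.approx(ref.test_statistic, abs=1e-10)

    def test_three_groups_two_df(self):
        rng = np.random.default_rng(2)
        data = _random_data(rng, 30)
        res = sv.logrank_test(data, rng.integers(0, 3, 30).astype(str))
        assert res.df == 2

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        data = _random_data(rng, 25, tie_free=False)
        g = rng.integers(0, 3, 25)
        a = sv.logrank_test(data, g.astype(str))
        relabel = {0: "z", 1: "m", 2: "a"}
        b = sv.logrank_test(data, [relabel[x] for x in g])
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        data = _random_data(rng, 25)
        g = rng.integers(0, 2, 25).astype(str)
        a = sv.logrank_test(data, g)
        b = sv.logrank_test(sv.SurvivalData(data.time * 7.3, data.event), g)
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)

    def test_p_equals_chi2_tail(self):
        rng = np.random.default_rng(10)
        data = _random_data(rng, 30)
        res = sv.logrank_test(data, rng.integers(0, 3, 30).astype(str))
        assert res.p_value == stats.chi2.sf(res.chi_square, res.df)

    def test_single_group_is_error(self):
        data = sv.SurvivalData([1, 2], [1, 1])
        with pytest.raises(ValueError, match="two nonempty groups"):
            sv.logrank_test(data, ["a", "a"])

    def test_eligibility_gate(self):
        # tiny groups: expected events below 5 -> ineligible, stat still there
        data = sv.SurvivalData([1, 2, 3, 4], [1, 1, 1, 1])
        res = sv.logrank_test(data, ["a", "a", "b", "b"])
        assert not res.eligible
        assert np.isfinite(res.chi_square)


class TestCox:
    def test_null_covariate_small_z(self):
        rng = np.random.default_rng(123)
        n = 200
        t = rng.exponential(30, n)
        c = rng.uniform(0, 60, n)
        data = sv.SurvivalData(np.minimum(t, c), (t <= c).astype(float))
        x = rng.normal(2, 0.3, n)
        res = sv.cox_fit(data, x)
        assert abs(res.z) < 4
        assert abs(res.beta) < 3 * res.se

    def test_score_test_close_to_logrank(self):
        rng = np.random.default_rng(77)
        n = 100
        g = rng.integers(0, 2, n)
        t = rng.exponential(np.where(g == 1, 8, 16))
        c = rng.uniform(0, 40, n)
        data = sv.SurvivalData(np.minimum(t, c), (t <= c).astype(float))
        lr = sv.logrank_test(data, g.astype(str))
        cox = sv.cox_fit(data, g.astype(float))
        assert cox.score_chi2 == pytest.approx(lr.chi_square, rel=0.15)

    def test_protective_covariate_negative_beta(self):
        t = np.arange(1.0, 21.0)
        data = sv.SurvivalData(t, np.ones(20))
        res = sv.cox_fit(data, t.copy())  # higher covariate = later death
        assert res.beta < 0

    def test_negation_flips_beta_keeps_z_magnitude(self):
        rng = np.random.default_rng(4)
        data = _random_data(rng, 60)
        x = rng.normal(0, 1, 60)
        a = sv.cox_fit(data, x)
        b = sv.cox_fit(data, -x)
        assert a.beta == pytest.approx(-b.beta, rel=1e-8)
        assert abs(a.z) == pytest.approx(abs(b.z), rel=1e-8)

    def test_degenerate_covariate_rejected(self):
        data = sv.SurvivalData([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="degenerate covariate"):
            sv.cox_fit(data, np.full(3, 2.0))

    def test_no_events_rejected(self):
        data = sv.SurvivalData([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="event"):
            sv.cox_fit(data, np.array([1.0, 2.0, 3.0]))

    def test_efron_ties_match_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(21)
        data = _random_data(rng, 50, tie_free=False)
        x = rng.normal(0, 1, 50)
        ours = sv.cox_fit(data, x, ties="efron")
        df = pd.DataFrame({"t": data.time, "e": data.event, "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert ours.beta == pytest.approx(ref.params_["x"], rel=1e-6)
        assert ours.se == pytest.approx(ref.standard_errors_["x"], rel=1e-6)

    def test_multivariate_adjustment(self):
        rng = np.random.default_rng(31)
        n = 120
        z2 = rng.normal(0, 1, n)
        t = rng.exponential(10 * np.exp(-0.8 * z2))
        c = rng.uniform(0, 40, n)
        data = sv.SurvivalData(np.minimum(t, c), (t <= c).astype(float))
        x = rng.normal(2, 0.4, n)
        res = sv.cox_fit(data, x, extra={"age": z2})
        assert set(res.params.index) == {"copy_number", "age"}
        assert res.params["age"] > 0  # higher z2 -> shorter survival
        assert res.summary().shape[0] == 2

    def test_missing_covariate_omitted(self):
        rng = np.random.default_rng(15)
        data = _random_data(rng, 30)
        x = rng.normal(0, 1, 30)
        x[3] = np.nan
        res = sv.cox_fit(data, x)
        assert res.n_omitted >= 1 and res.n == 30 - res.n_omitted

    def test_monotone_likelihood_flagged(self):
        # perfect separation: covariate order identical to death order
        t = np.arange(1.0, 11.0)
        data = sv.SurvivalData(t, np.ones(10))
        res = sv.cox_fit(data, -t)
        assert not res.converged


class TestBatchedPaths:
    """The vectorized scan internals must agree with the scalar API."""

    def test_logrank_batch_matches_scalar(self):
        rng = np.random.default_rng(42)
        n, M = 60, 25
        data = _random_data(rng, n, tie_free=False)
        codes = rng.integers(0, 3, (M, n))
        prep = _prepare_sorted(data.time, data.event)
        batch = _logrank_scores_batch(prep, codes, k=3)
        for m in range(M):
            res = sv.logrank_test(data, codes[m].astype(str))
            assert batch["stat"][m] == pytest.approx(res.chi_square, rel=1e-9, abs=1e-10)
            assert batch["df"][m] == res.df
            assert bool(batch["eligible"][m]) == res.eligible

    def test_cox_batch_matches_scalar(self):
        rng = np.random.default_rng(43)
        n, M = 80, 15
        data = _random_data(rng, n)
        X = rng.normal(2, 0.5, (M, n))
        prep = _prepare_sorted(data.time, data.event)
        batch = _cox_scores_batch(prep, X)
        for m in range(M):
            res = sv.cox_fit(data, X[m])
            assert batch["beta"][m] == pytest.approx(res.beta, rel=1e-7, abs=1e-10)
            assert batch["se"][m] == pytest.approx(res.se, rel=1e-7)

    def test_cox_batch_flags_constant_covariate(self):
        rng = np.random.default_rng(44)
        data = _random_data(rng, 30)
        X = np.vstack([np.full(30, 2.0), rng.normal(2, 0.5, 30)])
        prep = _prepare_sorted(data.time, data.event)
        batch = _cox_scores_batch(prep, X)
        assert np.isnan(batch["z"][0]) and np.isfinite(batch["z"][1])
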