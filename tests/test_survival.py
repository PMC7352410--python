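import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from pmprisk import (
    CohortAnnotation,
    ValidationError,
    binarize_dfs,
    cox_ph,
    delong_ci,
    delong_compare,
    km_fit,
    logrank_test,
    roc_auc,
    two_sample_t,
)
from pmprisk.survival import (
    EVENT_FREE,
    EVENT_WITHIN,
    INDETERMINATE,
    BinaryOutcomeTable,
)


def _outcomes(flags: dict[str, bool], horizon: float = 24.0) -> BinaryOutcomeTable:
    return BinaryOutcomeTable(
        pd.Series({u: EVENT_WITHIN if f else EVENT_FREE for u, f in flags.items()}),
        horizon)


def _series(d: dict[str, float]) -> pd.Series:
    return pd.Series(d, dtype=float)


def brute_force_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Concordant-pair fraction with half credit for ties (O(n^2) oracle)."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Horizon binarization
# ---------------------------------------------------------------------------

class TestBinarizeDfs:
    def _ann(self, rows):
        recs = []
        for i, (t, e) in enumerate(rows):
            recs.append({"sample_id": f"s{i}", "patient_id": f"p{i}",
                         "lesion_label": "L1", "histology": "DPAM",
                         "dfs_months": t, "dfs_event": e,
                         "os_months": t, "os_event": e})
        return CohortAnnotation(pd.DataFrame(recs).set_index("sample_id"))

    def test_classification_rules(self):
        ann = self._ann([(10.0, True),    # relapse before horizon
                         (30.0, False),   # followed past horizon, no event
                         (10.0, False),   # censored early -> indeterminate
                         (24.0, True),    # event exactly at horizon counts
                         (30.0, True)])   # late event = event-free at horizon
        out = binarize_dfs(ann, 24.0)
        assert out.outcome.tolist() == [EVENT_WITHIN, EVENT_FREE, INDETERMINATE,
                                        EVENT_WITHIN, EVENT_FREE]

    def test_patient_level_unit(self):
        ann = self._ann([(10.0, True), (30.0, False)])
        out = binarize_dfs(ann, 24.0, unit="patient")
        assert set(out.outcome.index) == {"p0", "p1"}


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc(_series({"a": 0.9, "b": 0.8, "c": 0.1}),
                      _outcomes({"a": True, "b": True, "c": False}))
        assert res.auc == 1.0
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)

    def test_constant_scores_give_half(self):
        res = roc_auc(_series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}),
                      _outcomes({"a": True, "b": False, "c": True, "d": False}))
        assert res.auc == 0.5

    def test_single_class_is_error(self):
        with pytest.raises(ValidationError):
            roc_auc(_series({"a": 1.0, "b": 2.0}),
                    _outcomes({"a": True, "b": True}))

    def test_indeterminate_units_excluded(self):
        out = BinaryOutcomeTable(pd.Series({"a": EVENT_WITHIN, "b": EVENT_FREE,
                                            "c": INDETERMINATE}), 24.0)
        res = roc_auc(_series({"a": 2.0, "b": 1.0, "c": 99.0}), out)
        assert res.auc == 1.0
        assert res.n_indeterminate == 1

    def test_matches_brute_force_pair_count_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 51))
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
            ids = [f"u{i}" for i in range(n)]
            res = roc_auc(pd.Series(scores, index=ids),
                          _outcomes(dict(zip(ids, labels))))
            assert res.auc == pytest.approx(brute_force_auc(scores, labels),
                                            abs=1e-12)

    def test_curve_monotone_and_auc_is_trapezoid(self, rng):
        n = 30
        labels = np.arange(n) % 2 == 0
        scores = rng.normal(size=n)
        ids = [f"u{i}" for i in range(n)]
        res = roc_auc(pd.Series(scores, index=ids),
                      _outcomes(dict(zip(ids, labels))))
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()
        assert res.auc == pytest.approx(np.trapezoid(res.tpr, res.fpr))


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

class TestDeLong:
    def test_self_comparison_p_exactly_one(self, rng):
        ids = [f"u{i}" for i in range(12)]
        labels = dict(zip(ids, [True] * 5 + [False] * 7))
        s = pd.Series(rng.normal(size=12), index=ids)
        res = delong_compare(s, s.copy(), _outcomes(labels))
        assert res["z"] == 0.0
        assert res["p_value"] == 1.0

    def test_ci_clipped_at_one_for_perfect_separation(self):
        s = _series({"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.0})
        out = _outcomes({"a": True, "b": True, "c": False, "d": False})
        ci = delong_ci(s, out, level=0.95)
        assert ci["auc"] == 1.0
        assert ci["upper"] <= 1.0
        assert ci["lower"] >= 0.0

    def test_variance_agrees_with_bootstrap(self, rng):
        n = 10
        ids = [f"u{i}" for i in range(n)]
        labels = np.array([True] * 4 + [False] * 6)
        scores = rng.normal(size=n) + labels
        ci = delong_ci(pd.Series(scores, index=ids),
                       _outcomes(dict(zip(ids, labels))))
        boots = []
        for _ in range(10_000):
            b = rng.integers(0, n, n)
            yy = labels[b]
            if yy.all() or not yy.any():
                continue
            boots.append(brute_force_auc(scores[b], yy))
        boot_var = np.var(boots)
        assert ci["se"] ** 2 == pytest.approx(boot_var, rel=0.25)

    def test_detects_a_real_auc_difference(self, rng):
        n = 80
        ids = [f"u{i}" for i in range(n)]
        labels = np.arange(n) % 2 == 0
        informative = rng.normal(size=n) + 2.0 * labels
        noise = pd.Series(rng.normal(size=n), index=ids)
        res = delong_compare(pd.Series(informative, index=ids), noise,
                             _outcomes(dict(zip(ids, labels))))
        assert res["auc_a"] > res["auc_b"]
        assert res["p_value"] < 0.01


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_events_curve_stays_at_one(self):
        fit = km_fit([5.0, 10.0, 15.0], [False, False, False])
        assert (fit.survival == 1.0).all()

    def test_single_event_among_four(self):
        fit = km_fit([5.0, 8.0, 9.0, 12.0], [True, False, False, False])
        assert fit.survival_at(5.0) == 0.75
        assert fit.survival_at(20.0) == 0.75

    def test_hand_computed_product_limit_table(self):
        # n=6: events at 2, 5, 9; censored at 3 and 7; one still at risk at 12
        times = [2.0, 3.0, 5.0, 7.0, 9.0, 12.0]
        events = [True, False, True, False, True, False]
        fit = km_fit(times, events)
        # S(2) = 5/6; S(5) = 5/6 * 3/4 = 5/8; S(9) = 5/8 * 1/2 = 5/16
        assert fit.survival_at(2.0) == pytest.approx(5 / 6)
        assert fit.survival_at(5.0) == pytest.approx(5 / 8)
        assert fit.survival_at(9.0) == pytest.approx(5 / 16)
        assert fit.survival_at(0.0) == 1.0

    def test_late_censored_unit_adds_no_step_after_last_event(self):
        times = [2.0, 4.0, 6.0]
        events = [True, True, False]
        base = km_fit(times, events)
        extended = km_fit(times + [50.0], events + [False])
        # censoring creates no survival step: the set of event (drop) times
        # is unchanged and the curve is flat after the last event
        base_drops = base.times[np.where(np.diff(base.survival) < 0)[0] + 1]
        ext_drops = extended.times[np.where(np.diff(extended.survival) < 0)[0] + 1]
        np.testing.assert_array_equal(base_drops, ext_drops)
        assert extended.survival_at(50.0) == extended.survival_at(4.0)

    def test_grouped_fit_and_empty_group_error(self):
        fits = km_fit([1.0, 2.0, 3.0, 4.0], [True, True, False, False],
                      groups=["a", "a", "b", "b"])
        assert set(fits) == {"a", "b"}
        assert fits["b"].survival_at(10.0) == 1.0

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        t = rng.exponential(10, 40)
        e = rng.random(40) < 0.6
        fit = km_fit(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tt in np.unique(t):
            assert fit.survival_at(tt) == pytest.approx(float(kmf.predict(tt)),
                                                        abs=1e-12)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def brute_force_logrank(times, events, groups):
    """Direct per-event-time hypergeometric summation (2 groups)."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    g = np.asarray(groups)
    labels = pd.unique(g)
    o_minus_e = 0.0
    v = 0.0
    for tt in sorted(set(t[e])):
        n = (t >= tt).sum()
        n1 = ((t >= tt) & (g == labels[0])).sum()
        d = (e & (t == tt)).sum()
        o1 = (e & (t == tt) & (g == labels[0])).sum()
        o_minus_e += o1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / v


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [3.0, 6.0, 9.0, 3.0, 6.0, 9.0]
        e = [True, False, True, True, False, True]
        g = ["a", "a", "a", "b", "b", "b"]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_direct_hypergeometric_summation(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            t = np.round(rng.exponential(10, n), 0) + 1.0  # ties likely
            e = rng.random(n) < 0.7
            g = rng.integers(0, 2, n)
            if len(set(g)) < 2 or not e.any():
                continue
            res = logrank_test(t, e, g)
            assert res.statistic == pytest.approx(brute_force_logrank(t, e, g),
                                                  abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank
        t = rng.exponential(12, 50)
        e = rng.random(50) < 0.8
        g = rng.integers(0, 2, 50)
        res = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-8)

    def test_symmetric_in_group_labels_and_time_units(self, rng):
        t = rng.exponential(10, 30)
        e = rng.random(30) < 0.7
        g = rng.integers(0, 2, 30)
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        c = logrank_test(t * 12.0, e, g)  # months -> years rescale
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.statistic == pytest.approx(c.statistic, abs=1e-12)

    def test_no_events_is_flagged_null_result(self):
        res = logrank_test([1.0, 2.0, 3.0, 4.0], [False] * 4, ["a", "a", "b", "b"])
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.flagged

    def test_observed_event_totals_conserved(self, rng):
        t = rng.exponential(10, 40)
        e = rng.random(40) < 0.6
        g = rng.integers(0, 2, 40)
        res = logrank_test(t, e, g)
        assert sum(res.observed.values()) == int(e.sum())
        assert sum(res.expected.values()) == pytest.approx(int(e.sum()))

    def test_three_group_extension(self, rng):
        t = rng.exponential(10, 60)
        e = rng.random(60) < 0.7
        g = rng.integers(0, 3, 60)
        res = logrank_test(t, e, g)
        assert res.df == 2
        assert 0 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

class TestCoxPH:
    def test_constant_covariate_no_information(self):
        res = cox_ph([1.0, 2.0, 3.0, 4.0], [True, True, False, True],
                     pd.DataFrame({"x": [2.0, 2.0, 2.0, 2.0]}))
        assert res.table.loc["x", "coef"] == 0.0
        assert res.table.loc["x", "hr"] == 1.0

    def test_binary_covariate_matches_grid_search(self, rng):
        n = 40
        x = (np.arange(n) % 2).astype(float)
        t = rng.exponential(np.exp(-1.0 * x))
        t += rng.uniform(0, 1e-6, n)  # no ties
        e = np.ones(n, dtype=bool)
        res = cox_ph(t, e, pd.DataFrame({"x": x}))

        def neg_partial_loglik(beta):
            order = np.argsort(t)
            ts, xs = t[order], x[order]
            ll = 0.0
            for i in range(n):
                risk = ts >= ts[i]
                ll += beta * xs[i] - np.log(np.exp(beta * xs[risk]).sum())
            return -ll

        grid = np.arange(-4.0, 4.0, 1e-4)
        best = grid[np.argmin([neg_partial_loglik(b) for b in grid])]
        assert res.table.loc["x", "coef"] == pytest.approx(best, abs=1e-4)
        assert res.converged

    def test_duplicate_covariate_columns_flagged_rank_deficient(self, rng):
        x = rng.normal(size=20)
        t = rng.exponential(1.0, 20)
        res = cox_ph(t, np.ones(20, bool), pd.DataFrame({"a": x, "b": x}))
        assert res.flag == "rank_deficient"
        assert not res.converged

    def test_complete_separation_flagged_not_crashed(self):
        # covariate perfectly orders the event times -> monotone likelihood
        t = np.arange(1.0, 13.0)
        x = -t
        res = cox_ph(t, np.ones(12, bool), pd.DataFrame({"x": x}))
        assert not res.converged
        assert res.flag in ("monotone_likelihood", "max_iter")

    def test_matches_lifelines_on_untied_times(self, rng):
        # without ties Efron (lifelines default) and Breslow coincide
        from lifelines import CoxPHFitter
        n = 50
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-0.7 * x1 + 0.5 * x2))
        e = rng.random(n) < 0.8
        res = cox_ph(t, e, pd.DataFrame({"x1": x1, "x2": x2}))
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, "t", "e")
        for c in ("x1", "x2"):
            assert res.table.loc[c, "coef"] == pytest.approx(cph.params_[c],
                                                             abs=1e-5)
            assert res.table.loc[c, "se"] == pytest.approx(
                cph.standard_errors_[c], abs=1e-5)

    def test_breslow_tie_handling_maximizes_breslow_likelihood(self, rng):
        # independently coded Breslow partial log-likelihood, maximized by a
        # generic optimizer, must agree with the Newton fit on tied data
        from scipy.optimize import minimize_scalar
        n = 40
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(np.exp(-0.8 * x)) * 4)  # heavy ties
        e = rng.random(n) < 0.85
        res = cox_ph(t, e, pd.DataFrame({"x": x}))

        def neg_breslow_ll(beta):
            ll = 0.0
            for tt in np.unique(t[e]):
                dead = e & (t == tt)
                risk = t >= tt
                ll += beta * x[dead].sum() \
                    - dead.sum() * np.log(np.exp(beta * x[risk]).sum())
            return -ll

        opt = minimize_scalar(neg_breslow_ll, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        assert res.table.loc["x", "coef"] == pytest.approx(opt.x, abs=1e-6)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_shifted_zero_variance_degenerate(self):
        res = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert res["p"] == 0.0 and res["flagged"]

    @pytest.mark.parametrize("variant,equal_var", [("welch", False),
                                                   ("pooled", True)])
    def test_matches_scipy(self, rng, variant, equal_var):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.4, 2.0, 10)
        res = two_sample_t(a, b, variant=variant)
        ref = st.ttest_ind(a, b, equal_var=equal_var)
        assert res["t"] == pytest.approx(ref.statistic, abs=1e-12)
        assert res["p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_formula_directly(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=9)
        res = two_sample_t(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        t_expected = (a.mean() - b.mean()) / np.sqrt(va / 12 + vb / 9)
        df_expected = (va / 12 + vb / 9) ** 2 / (
            (va / 12) ** 2 / 11 + (vb / 9) ** 2 / 8)
        assert res["t"] == pytest.approx(t_expected)
        assert res["df"] == pytest.approx(df_expected)
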