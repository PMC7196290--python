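"""Kaplan-Meier, log-rank, dichotomization and the minimal-p cutoff search."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from ctctools import (
    CutoffStratifier,
    SurvivalRecord,
    days_to_months,
    dichotomize,
    km_estimate,
    logrank_test,
    optimal_cutoff_search,
)
from oracles import km_product_limit, logrank_closed_form


def records(times, events, counts=None, prefix="p"):
    counts = counts if counts is not None else [None] * len(times)
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), int(e), baseline_count_75=c)
        for i, (t, e, c) in enumerate(zip(times, events, counts))
    ]


class TestKaplanMeier:
    def test_four_uncensored_deaths(self):
        est = km_estimate(records([1, 2, 3, 4], [1, 1, 1, 1]))
        steps = est.survival[np.isin(est.timeline, [1, 2, 3, 4])]
        assert np.allclose(steps, [0.75, 0.5, 0.25, 0.0])
        assert est.median == 2.0  # first time S(t) <= 0.5

    def test_all_censored(self):
        est = km_estimate(records([5, 8, 13], [0, 0, 0]))
        assert np.allclose(est.survival, 1.0)
        assert np.isinf(est.median)

    def test_mixed_example_matches_product_limit_oracle(self):
        times = [3, 5, 5, 8, 10, 12]
        events = [1, 0, 1, 1, 0, 1]
        est = km_estimate(records(times, events))
        t_ref, s_ref = km_product_limit(times, events)
        got = est.survival[np.isin(est.timeline, t_ref)]
        assert np.allclose(got, s_ref)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(30, size=25).round(2)
        est = km_estimate(records(times, np.ones(25)))
        for t, s in zip(est.timeline[1:], est.survival[1:]):
            assert s == pytest.approx((times > t).mean())

    def test_no_records_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestLogrank:
    def test_identical_groups(self):
        g = records([2, 4, 6, 8], [1, 1, 0, 1])
        res = logrank_test(g, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(5):
            ta = rng.exponential(10, 15).round(1) + 0.1
            tb = rng.exponential(20, 12).round(1) + 0.1
            ea, eb = rng.integers(0, 2, 15), rng.integers(0, 2, 12)
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(records(ta, ea), records(tb, eb, prefix="q"))
            chi_ref, p_ref = logrank_closed_form(ta, ea, tb, eb)
            assert res.statistic == pytest.approx(chi_ref)
            assert res.p_value == pytest.approx(p_ref)

    def test_matches_lifelines(self, rng):
        ta, tb = rng.exponential(10, 20), rng.exponential(25, 20)
        ea = np.ones(20)
        res = logrank_test(records(ta, ea), records(tb, ea, prefix="q"))
        ref = lifelines_logrank(ta, tb, event_observed_A=ea, event_observed_B=ea)
        assert res.statistic == pytest.approx(ref.test_statistic)
        assert res.p_value == pytest.approx(ref.p_value)

    def test_strong_separation_detected(self):
        early = records(np.arange(1, 21), np.ones(20))
        late = records(np.arange(100, 120), np.ones(20), prefix="q")
        assert logrank_test(early, late).p_value < 0.01

    def test_relabeling_invariance(self, rng):
        a = records(rng.exponential(10, 10), np.ones(10))
        b = records(rng.exponential(30, 10), np.ones(10), prefix="q")
        assert logrank_test(a, b).statistic == pytest.approx(
            logrank_test(b, a).statistic)

    def test_no_events_rejected(self):
        a = records([1, 2], [0, 0])
        with pytest.raises(ValueError, match="event"):
            logrank_test(a, a)


class TestDichotomize:
    def test_printed_cohort_fraction(self):
        counts = [100.0] * 8 + [10.0] * 30  # 8 of 38 above the cutoff
        d = dichotomize(records(np.ones(38) * 5, np.ones(38), counts), 66.0)
        assert (d.n_high, d.n_low) == (8, 30)
        assert 100 * d.frac_high == pytest.approx(21.05, abs=0.01)

    def test_boundary_is_strict(self):
        counts = [10.0, 66.0, 70.0]
        d = dichotomize(records([1, 2, 3], [1, 1, 1], counts), 66.0)
        assert d.n_high == 1  # 66 itself goes Low: High means strictly greater
        d_all_high = dichotomize(records([1, 2, 3], [1, 1, 1], counts), 5.0)
        assert d_all_high.n_low == 0
        d_all_low = dichotomize(records([1, 2, 3], [1, 1, 1], counts), 70.0)
        assert d_all_low.n_high == 0


class TestCutoffSearch:
    def cohort(self, rng, n=40, cutoff=40.0, hr=3.0):
        counts = rng.lognormal(np.log(37), 0.7, n)
        t = 100 * rng.weibull(1.3, n)
        t[counts > cutoff] *= hr ** (-1 / 1.3)
        return records(t + 0.01, np.ones(n), counts)

    def test_matches_exhaustive_grid_oracle(self, rng):
        """best_p equals the minimum over every admissible distinct count."""
        recs = self.cohort(rng)
        res = optimal_cutoff_search(recs, min_group_frac=0.1)
        n = len(recs)
        best = (None, np.inf)
        for c in sorted({r.baseline_count_75 for r in recs}):
            high = [(r.time, r.event) for r in recs if r.baseline_count_75 > c]
            low = [(r.time, r.event) for r in recs if r.baseline_count_75 <= c]
            if len(high) < 0.1 * n or len(low) < 0.1 * n:
                continue
            _, p = logrank_closed_form(*zip(*high), *zip(*low))
            if p < best[1]:
                best = (c, p)
        assert res.best_cutoff == pytest.approx(best[0])
        assert res.best_p == pytest.approx(best[1])
        assert res.best_p == res.grid["p"].min()
        assert (res.grid["n_high"] + res.grid["n_low"] == n).all()

    def test_degenerate_counts_rejected(self):
        recs = records([1, 2, 3], [1, 1, 1], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            optimal_cutoff_search(recs)

    def test_estimator_interface(self, rng):
        recs = self.cohort(rng)
        X = pd.DataFrame({
            "baseline_count_75": [r.baseline_count_75 for r in recs],
            "time": [r.time for r in recs],
            "event": [r.event for r in recs],
        })
        est = CutoffStratifier().fit(X)
        res = optimal_cutoff_search(recs)
        assert est.cutoff_ == res.best_cutoff
        labels = est.predict([est.cutoff_ - 1, est.cutoff_, est.cutoff_ + 1])
        assert list(labels) == ["low", "low", "high"]


def test_days_to_months_reporting_convention():
    assert days_to_months(30.44) == pytest.approx(1.0)
    assert days_to_months(578.4) == pytest.approx(19.0, abs=0.01)
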