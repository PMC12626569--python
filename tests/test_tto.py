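"""Onset-time computation, Weibull fitting and group comparison."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from faerspv.ingest import PartialDate, parse_date
from faerspv.tto import (WeibullFit, classify_failure, compute_tto,
                         cumulative_incidence, fit_weibull, logrank_test,
                         median_iqr, onset_records)


class TestComputeTto:
    def test_calendar_arithmetic_plus_half(self):
        rec = compute_tto(parse_date("20200101"), parse_date("20200110"))
        assert rec.included and rec.tto_days == 9.5

    def test_same_day_yields_half_day(self):
        rec = compute_tto(parse_date("20200101"), parse_date("20200101"))
        assert rec.included and rec.tto_days == 0.5

    def test_event_before_start_excluded(self):
        rec = compute_tto(parse_date("20200110"), parse_date("20200101"))
        assert not rec.included and rec.exclusion_reason == "negative_or_zero"

    @pytest.mark.parametrize("start, event, reason", [
        ("202001", "20200110", "partial_date"),
        ("20200101", "2020", "partial_date"),
        ("", "20200110", "missing_date"),
        ("20200101", "garbage", "missing_date"),
    ])
    def test_partial_or_missing_dates_excluded(self, start, event, reason):
        rec = compute_tto(parse_date(start), parse_date(event))
        assert not rec.included and rec.exclusion_reason == reason

    def test_exclusion_bookkeeping_conserved(self, small_dataset):
        records = onset_records(small_dataset)
        n_inc = sum(r.included for r in records)
        n_exc = sum(not r.included for r in records)
        assert n_inc + n_exc == len(records)
        for r in records:
            assert r.included == (r.exclusion_reason == "none")
            if r.included:
                assert r.tto_days > 0

    def test_onset_times_match_generator(self, small_quarter, small_dataset):
        _, truth = small_quarter
        records = {r.primaryid: r for r in onset_records(small_dataset)}
        by_case = dict(zip(truth.caseids, truth.tto_days))
        dup_case = {}  # surviving primaryid -> caseid
        for r in records.values():
            caseid = r.primaryid[:-1]  # generator ids are caseid*10+version
            expected = by_case.get(caseid, math.nan)
            if r.included:
                assert r.tto_days == expected


class TestFitWeibull:
    def test_grid_search_oracle(self):
        data = [1, 2, 3, 4, 5, 8, 13, 21, 34, 55]
        betas = np.arange(0.05, 10.0, 1e-3)
        best = (-np.inf, None, None)
        t = np.asarray(data, float)
        for b in betas:
            alpha = (np.mean(t ** b)) ** (1 / b)
            ll = (len(t) * math.log(b) - len(t) * b * math.log(alpha)
                  + (b - 1) * np.sum(np.log(t)) - np.sum((t / alpha) ** b))
            if ll > best[0]:
                best = (ll, alpha, b)
        fit = fit_weibull(data)
        assert fit.beta == pytest.approx(best[2], abs=5e-3)
        assert fit.alpha == pytest.approx(best[1], abs=5e-2)

    def test_matches_scipy_mle(self):
        rng = np.random.default_rng(2)
        data = 50 * rng.weibull(1.4, 400)
        fit = fit_weibull(data)
        shape, loc, scale = sps.weibull_min.fit(data, floc=0)
        assert fit.beta == pytest.approx(shape, rel=1e-4)
        assert fit.alpha == pytest.approx(scale, rel=1e-4)

    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(3)
        data = 120 * rng.weibull(0.65, 5000)
        fit = fit_weibull(data)
        lo, hi = fit.beta_ci
        assert lo <= 0.65 <= hi

    def test_exponential_is_shape_one(self):
        rng = np.random.default_rng(4)
        data = rng.exponential(30, 5000)
        fit = fit_weibull(data)
        lo, hi = fit.beta_ci
        assert lo <= 1.0 <= hi

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        data = list(100 * rng.weibull(0.8, 200))
        f1, f2 = fit_weibull(data), fit_weibull(data)
        assert f1.alpha == f2.alpha and f1.beta == f2.beta

    def test_recovery_and_coverage_over_replicates(self):
        """Mean shape estimate within 2% and CI coverage in [90%, 99%]."""
        rng = np.random.default_rng(6)
        for true_beta in (0.5, 1.0, 2.0):
            est, covered = [], 0
            for _ in range(100):
                data = 100 * rng.weibull(true_beta, 1000)
                fit = fit_weibull(data)
                est.append(fit.beta)
                lo, hi = fit.beta_ci
                covered += lo <= true_beta <= hi
            assert abs(np.mean(est) - true_beta) / true_beta < 0.02
            assert 90 <= covered <= 99

    def test_too_few_records_error(self):
        with pytest.raises(ValueError, match="at least"):
            fit_weibull([1, 2, 3])

    def test_degenerate_sample_error(self):
        with pytest.raises(ValueError, match="identical"):
            fit_weibull([5.0] * 20)


class TestClassifyFailure:
    @pytest.mark.parametrize("beta, ci, expected", [
        (0.649, (0.643, 0.656), "early"),
        (1.963, (1.220, 2.707), "wear_out"),
        (1.05, (0.8, 1.3), "random"),
        (0.95, (0.8, 1.05), "random"),
    ])
    def test_modes(self, beta, ci, expected):
        fit = WeibullFit(alpha=100, beta=beta, alpha_ci=(90, 110),
                         beta_ci=ci, n=100, loglik=0.0)
        assert classify_failure(fit) == expected

    def test_consistent_with_random_fits(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            data = 50 * rng.weibull(rng.uniform(0.4, 2.5), 300)
            fit = fit_weibull(data)
            mode = classify_failure(fit)
            lo, hi = fit.beta_ci
            if lo <= 1 <= hi:
                assert mode == "random"
            elif hi < 1:
                assert mode == "early"
            else:
                assert mode == "wear_out"


class TestSummaries:
    def test_median_iqr_by_hand(self):
        assert median_iqr([1, 2, 3]) == (2, 1.5, 2.5)
        assert median_iqr([4]) == (4, 4, 4)

    def test_median_iqr_matches_sorted_interpolation_oracle(self):
        rng = np.random.default_rng(8)
        t = 120 * rng.weibull(0.7, 501)
        med, q1, q3 = median_iqr(t)
        s = np.sort(t)

        def type7(q):
            h = (len(s) - 1) * q
            lo = int(math.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert med == pytest.approx(type7(0.5), abs=1e-12)
        assert q1 == pytest.approx(type7(0.25), abs=1e-12)
        assert q3 == pytest.approx(type7(0.75), abs=1e-12)


class TestCumulativeIncidence:
    def test_small_example(self):
        curves = cumulative_incidence({"g": np.array([1.0, 2.0, 3.0])})
        at2 = curves[(curves["group"] == "g") & (curves["time"] == 2.0)]
        assert at2["cuminc"].iloc[0] == pytest.approx(2 / 3)

    def test_equals_ecdf_without_censoring(self):
        rng = np.random.default_rng(9)
        t = 60 * rng.weibull(0.9, 400)
        curves = cumulative_incidence({"g": t})
        for _, row in curves.iterrows():
            ecdf = np.mean(t <= row["time"])
            assert row["cuminc"] == pytest.approx(ecdf, abs=1e-12)
        # right-continuous, non-decreasing, reaches 1
        vals = curves["cuminc"].to_numpy()
        assert (np.diff(vals) >= 0).all() and vals[-1] == pytest.approx(1.0)


class TestLogrank:
    def test_identical_groups_null(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        stat, df, p = logrank_test({"a": g, "b": g.copy()})
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        # 3 vs 3 fully separated: chi2 ~ 5.05, the most extreme labeling
        stat, df, p = logrank_test(
            {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([101.0, 102.0, 103.0])}
        )
        assert p < 0.05
        # 5 vs 5 separation pushes the asymptotic p below 1%
        _, _, p5 = logrank_test(
            {"a": np.arange(1.0, 6.0), "b": np.arange(101.0, 106.0)}
        )
        assert p5 < 0.01

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(10)
        a = 30 * rng.weibull(1.0, 25)
        b = 60 * rng.weibull(1.0, 25)
        stat, _, p = logrank_test({"a": a, "b": b})
        pooled = np.concatenate([a, b])
        perm_stats = []
        for _ in range(2000):
            perm = rng.permutation(pooled)
            s, _, _ = logrank_test({"a": perm[:25], "b": perm[25:]})
            perm_stats.append(s)
        p_perm = np.mean(np.asarray(perm_stats) >= stat)
        assert abs(p - p_perm) < 0.05

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            groups = {k: 50 * rng.weibull(0.8, 40) for k in ("a", "b", "c")}
            _, _, p = logrank_test(groups)
            rejections += p < 0.05
        # binomial 95% band around 0.05 at 200 replicates: [8, 24] is wide;
        # accept anything within +/- 3 sd of the nominal level
        sd = math.sqrt(n_rep * 0.05 * 0.95)
        assert abs(rejections - 0.05 * n_rep) <= 3 * sd

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test({"a": np.array([1.0]), "b": np.array([])})
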