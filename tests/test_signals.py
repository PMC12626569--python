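"""Disproportionality estimators, the combined rule and risk stratification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from faerspv.signals import (ContingencyTable, PriorConfig, SignalMetrics,
                             SignalThresholds, bcpnn_ic, combined_signal,
                             contingency, evaluate_pair,
                             fit_gamma_poisson_mixture, mgps_ebgm, prr_chi2,
                             ror, stratify_risk)

T = ContingencyTable(5, 95, 100, 9800)


class TestContingency:
    def test_enumeration(self, small_dataset, small_quarter):
        _, truth = small_quarter
        for drug, (a, b, c, d) in truth.pair_counts().items():
            t = contingency(small_dataset, drug)
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
            assert t.n == small_dataset.n_total_reports

    def test_absent_drug_errors(self, small_dataset):
        with pytest.raises(ValueError, match="absent"):
            contingency(small_dataset, "no-such-drug")


class TestRor:
    def test_worked_example(self):
        point, lo, hi, corrected = ror(T)
        assert point == pytest.approx(5.1579, abs=1e-4)
        assert lo == pytest.approx(2.054, abs=2e-3)
        assert hi == pytest.approx(12.951, abs=2e-2)
        assert not corrected

    def test_independence_is_one(self):
        point, *_ = ror(ContingencyTable(10, 90, 100, 900))
        assert point == pytest.approx(1.0)

    def test_zero_cell_corrected_and_flagged(self):
        point, lo, hi, corrected = ror(ContingencyTable(0, 100, 100, 9800))
        assert corrected and math.isfinite(point) and 0 < lo < point < hi


class TestPrrChi2:
    def test_worked_example(self):
        prr, chi2 = prr_chi2(T)
        assert prr == pytest.approx(4.95, abs=1e-10)
        assert chi2 == pytest.approx(11.572, abs=2e-3)

    def test_chi2_matches_scipy_yates(self):
        for t in (T, ContingencyTable(3, 50, 20, 400), ContingencyTable(8, 2, 5, 30)):
            obs = [[t.a, t.b], [t.c, t.d]]
            expected = sps.chi2_contingency(obs, correction=True)[0]
            assert prr_chi2(t)[1] == pytest.approx(expected, rel=1e-12)

    def test_independence_floors_to_zero(self):
        _, chi2 = prr_chi2(ContingencyTable(10, 90, 100, 900))
        assert chi2 == 0.0

    def test_a_zero_gives_prr_zero(self):
        prr, _ = prr_chi2(ContingencyTable(0, 100, 100, 9800))
        assert prr == 0.0

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="a\\+b"):
            prr_chi2(ContingencyTable(0, 0, 10, 10))


class TestBcpnn:
    def test_simplified_observed_component(self):
        ic, ic025 = bcpnn_ic(T, variant="simplified")
        assert ic == pytest.approx(math.log2(5 * 10000 / (100 * 105)), abs=1e-12)
        assert ic == pytest.approx(2.2515, abs=1e-4)
        assert ic025 < ic

    def test_independence_large_n_near_zero(self):
        t = ContingencyTable(1000, 9000, 99000, 891000)
        for variant in ("simplified", "bate"):
            ic, _ = bcpnn_ic(t, variant=variant)
            assert abs(ic) < 0.01

    def test_shrinkage_dominates_rare_pair(self):
        # a=1 with tiny margins in a huge database: IC025 must go negative
        t = ContingencyTable(1, 9, 99, 10**6)
        _, ic025 = bcpnn_ic(t, variant="bate")
        assert ic025 < 0

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            bcpnn_ic(ContingencyTable(0, 0, 10, 10))


class TestMgps:
    def test_closed_form_worked_example(self):
        (ebgm, ebgm05), = mgps_ebgm([T])
        assert ebgm == pytest.approx(4.7619, abs=1e-4)
        assert 0 < ebgm05 < ebgm

    def test_expected_counts_give_unit_ebgm(self):
        tables = [ContingencyTable(10, 90, 990, 8910),
                  ContingencyTable(50, 450, 950, 8550)]
        for ebgm, _ in mgps_ebgm(tables):
            assert ebgm == pytest.approx(1.0, abs=1e-9)

    def test_em_posterior_orders(self):
        rng = np.random.default_rng(7)
        e = np.exp(rng.normal(1, 1, 400))
        a = rng.poisson(e)  # all null pairs
        tables = [ContingencyTable(ai, 100, ei * 100, 10000) for ai, ei in zip(a, e)]
        # synthetic-margin tables only feed (a, E) into the EM machinery
        out = mgps_ebgm(tables, variant="em")
        for ebgm, ebgm05 in out:
            assert ebgm05 <= ebgm


class TestFormulaIdentities:
    tables = st.tuples(*[st.integers(1, 60)] * 4).map(lambda c: ContingencyTable(*c))

    @given(tables)
    def test_ror_prr_identity(self, t):
        """ROR = PRR * [(a+b)/b] / [(c+d)/d] on strictly positive tables."""
        r, *_ = ror(t)
        prr, _ = prr_chi2(t)
        identity = prr * ((t.a + t.b) / t.b) / ((t.c + t.d) / t.d)
        assert r == pytest.approx(identity, abs=1e-12, rel=1e-12)

    def test_monotone_in_a_with_margins_fixed(self):
        # grow a while holding both margins: b,c shrink, d grows
        metrics = []
        for a in range(5, 40, 5):
            t = ContingencyTable(a, 100 - a, 120 - a, 9680 + a)
            r = evaluate_pair(t).metrics
            metrics.append((r.ror, r.prr, r.ic, r.ebgm))
        arr = np.array(metrics)
        assert (np.diff(arr, axis=0) > 0).all()


class TestCombinedRule:
    def _metrics(self, **kw):
        base = dict(ror=5, ror_ci_low=2, ror_ci_high=10, prr=4, chi2=20,
                    ic=2, ic025=0.5, ebgm=4, ebgm05=2.5, n_reports=10)
        base.update(kw)
        return SignalMetrics(**base)

    def test_all_four_pass(self):
        assert combined_signal("x", self._metrics()).combined_positive

    @pytest.mark.parametrize("kw", [
        {"ic025": -0.1}, {"ebgm05": 1.9}, {"n_reports": 2},
        {"prr": 1.5}, {"chi2": 3.0}, {"ror_ci_low": 0.9},
    ])
    def test_single_failure_vetoes(self, kw):
        res = combined_signal("x", self._metrics(**kw))
        assert not res.combined_positive
        assert res.combined_positive == all(res.criteria_flags.values())

    def test_injected_association_detected(self, small_dataset):
        res = evaluate_pair(contingency(small_dataset, "dienogest"), "dienogest")
        # true reporting ratio 8 with ~30 exposed events: a clear signal
        assert res.combined_positive


class TestStratification:
    @staticmethod
    def _positives(n, seed=0):
        rng = np.random.default_rng(seed)
        rors = rng.permutation(np.linspace(2, 90, n))
        out = []
        for i, r in enumerate(rors):
            m = SignalMetrics(ror=float(r), ror_ci_low=0.75 * r, ror_ci_high=2 * r,
                              prr=r, chi2=50, ic=2, ic025=1, ebgm=r, ebgm05=3,
                              n_reports=10 + i)
            out.append(combined_signal(f"drug{i:03d}", m))
        return out

    @pytest.mark.parametrize(
        "n, expected",
        [(135, (6, 21, 40, 68)), (100, (5, 15, 30, 50)), (3, (0, 0, 1, 2))],
    )
    def test_level_sizes(self, n, expected):
        levels = [r.risk_level for r in stratify_risk(self._positives(n))]
        got = tuple(levels.count(x) for x in "ABCD")
        assert got == expected

    def test_partition_and_contiguity(self):
        ranked = stratify_risk(self._positives(57, seed=3))
        assert len(ranked) == 57
        order = [r.risk_level for r in ranked]  # already rank-sorted
        assert order == sorted(order)  # A..D contiguous in rank
        rors = [r.metrics.ror for r in ranked]
        assert rors == sorted(rors, reverse=True)

    def test_requires_positives(self):
        m = SignalMetrics(ror=1, ror_ci_low=0.5, ror_ci_high=2, prr=1, chi2=0,
                          ic=0, ic025=-1, ebgm=1, ebgm05=0.5, n_reports=5)
        neg = combined_signal("x", m)
        with pytest.raises(ValueError):
            stratify_risk([neg])

    def test_empty_input(self):
        assert stratify_risk([]) == []


def test_mixture_fit_failure_carries_parameters():
    with pytest.raises((RuntimeError, ValueError)):
        fit_gamma_poisson_mixture(np.array([1.0]), np.array([0.0]))
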