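"""ROR / IC estimation and the joint signal criterion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvscreen.contingency import ContingencyTable
from pvscreen.disproportionality import (
    compute_ic,
    compute_ror,
    compute_statistics,
    evaluate_signal,
    run_screen,
    signal_frame,
)
from pvscreen.faers_io import deduplicate
from pvscreen.synthetic_data import default_config, generate_reports
from pvscreen.vocabulary import SEIZURE_SET_NAME, DrugDictionary


def table(a, b, c, d):
    return ContingencyTable("drug", "set", a, b, c, d)


class TestRor:
    def test_symmetric_table_is_null(self):
        assert compute_ror(table(10, 10, 10, 10)).ror == pytest.approx(1.0)

    def test_point_and_wald_interval(self):
        # frozen by direct arithmetic: ror = 20·9800/(80·100) = 24.5,
        # se = √(1/20+1/80+1/100+1/9800), CI = exp(ln 24.5 ∓ 1.96·se)
        est = compute_ror(table(20, 80, 100, 9800))
        assert est.ror == pytest.approx(24.5, rel=1e-12)
        assert est.low == pytest.approx(14.44799580557242, rel=1e-12)
        assert est.high == pytest.approx(41.54555469683144, rel=1e-12)

    def test_zero_cell_with_continuity_is_finite(self):
        est = compute_ror(table(0, 10, 10, 100), continuity=True)
        expected = (0.5 * 100.5) / (10.5 * 10.5)
        assert est.ror == pytest.approx(expected)
        assert 0 < est.low < est.ror < est.high < math.inf

    def test_zero_a_without_continuity(self):
        est = compute_ror(table(0, 10, 10, 100))
        assert est.ror == 0.0
        assert est.low == 0.0 and est.high == math.inf

    def test_degenerate_background_fatal(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_ror(table(5, 0, 0, 0))

    def test_small_grid_matches_direct_arithmetic(self):
        """Cells 1..8 exhaustively vs an independent vectorized evaluation."""
        grid = np.arange(1, 9)
        a, b, c, d = (g.ravel() for g in np.meshgrid(grid, grid, grid, grid, indexing="ij"))
        direct = a * d / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        low = np.exp(np.log(direct) - 1.96 * se)
        for i in range(0, len(a), 7):  # stride keeps the unit test quick
            est = compute_ror(table(int(a[i]), int(b[i]), int(c[i]), int(d[i])))
            assert est.ror == pytest.approx(direct[i], rel=1e-12)
            assert est.low == pytest.approx(low[i], rel=1e-12)


class TestIc:
    def test_zero_when_observed_equals_expected(self):
        # E = (a+b)(a+c)/n = 100·100/1000 = 10 = a, so log2(10.5/10.5) = 0
        assert compute_ic(table(10, 90, 90, 810)).ic == 0.0

    def test_shrinkage_point_estimate(self):
        # E = 100·120/10000 = 1.2; ic = log2(20.5/1.7), frozen independently
        est = compute_ic(table(20, 80, 100, 9800))
        assert est.ic == pytest.approx(3.5920172582551064, rel=1e-12)
        assert est.low < est.ic < est.high

    def test_credibility_bound_formulas(self):
        t = table(7, 13, 20, 60)
        est = compute_ic(t)
        s = 7.5
        assert est.low == pytest.approx(est.ic - 3.3 * s**-0.5 - 2 * s**-1.5)
        assert est.high == pytest.approx(est.ic + 2.4 * s**-0.5 - 0.5 * s**-1.5)

    def test_shrinkage_vanishes_at_scale(self):
        """At fixed observed/expected ratio, IC → log2(O/E) as a grows."""
        # margins chosen so E = a/3 exactly at every scale
        for k in (10_000, 100_000):
            a, b, c, d = 3 * k, 27 * k, 7 * k, 63 * k
            t = table(a, b, c, d)
            expected = (a + b) * (a + c) / t.n_total
            assert compute_ic(t).ic == pytest.approx(math.log2(a / expected), abs=0.01)


class TestSignalCriteria:
    @pytest.mark.parametrize(
        ("a", "ror_low", "ic", "ic_low", "expected"),
        [
            (2, 5.0, 2.0, 2.0, False),  # below minimum case count
            (100, 1.2, 0.8, 0.1, True),  # all criteria strictly met
            (50, 0.99, 0.8, 0.1, False),  # ROR bound fails
            (50, 1.2, 0.0, 0.1, False),  # IC not strictly positive
            (50, 1.2, 0.8, 0.0, False),  # IC bound not strictly positive
            (3, 1.01, 0.01, 0.01, True),  # boundary case count passes
        ],
    )
    def test_joint_rule(self, a, ror_low, ic, ic_low, expected):
        assert evaluate_signal(a, ror_low, ic, ic_low) is expected

    @given(
        a=st.integers(0, 50),
        ror_low=st.floats(0.0, 10.0),
        ic=st.floats(-3.0, 3.0),
        ic_low=st.floats(-3.0, 3.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_never_signals_when_any_criterion_fails(self, a, ror_low, ic, ic_low):
        if a < 3 or ror_low <= 1 or ic <= 0 or ic_low <= 0:
            assert not evaluate_signal(a, ror_low, ic, ic_low)
        else:
            assert evaluate_signal(a, ror_low, ic, ic_low)

    def test_statistics_object_consistent(self):
        s = compute_statistics(table(20, 80, 100, 9800))
        assert s.ror_low <= s.ror <= s.ror_high
        assert s.ic_low <= s.ic <= s.ic_high
        assert s.is_signal == evaluate_signal(s.a, s.ror_low, s.ic, s.ic_low)


@pytest.fixture(scope="module")
def planted_screen(dictionary, seizure_set):
    config = default_config(
        n_cases=20_000, seed=31,
        planted_lambda={"N06AX12": {SEIZURE_SET_NAME: 8.0}},
    )
    cases = deduplicate(generate_reports(config)[0])
    return run_screen(cases, dictionary, seizure_set)


class TestRunScreen:
    def test_planted_drug_ranks_first_and_signals(self, planted_screen):
        top = planted_screen.signals[0]
        assert top.drug == "N06AX12"
        assert top.is_signal

    def test_ranking_is_descending_ror(self, planted_screen):
        rors = [s.ror for s in planted_screen.signals]
        assert rors == sorted(rors, reverse=True)

    def test_null_drugs_rarely_signal(self, planted_screen):
        null = [s for s in planted_screen.signals if s.drug != "N06AX12"]
        assert sum(s.is_signal for s in null) <= max(1, int(0.05 * len(null)) + 1)

    def test_zero_case_drugs_reported_separately(self, planted_screen, dictionary):
        screened = {s.drug for s in planted_screen.signals}
        assert screened.isdisjoint(planted_screen.zero_case_drugs)
        assert screened | set(planted_screen.zero_case_drugs) == set(dictionary.atc_codes)

    def test_single_drug_dictionary(self, seizure_set):
        config = default_config(n_cases=500, seed=2)
        cases = deduplicate(generate_reports(config)[0])
        d = DrugDictionary({"bupropion": "N06AX12"}, {"N06AX12": "Bupropion"})
        result = run_screen(cases, d, seizure_set)
        assert len(result.signals) + len(result.zero_case_drugs) == 1

    def test_deterministic_rerun(self, dictionary, seizure_set):
        config = default_config(n_cases=2000, seed=17)
        cases = deduplicate(generate_reports(config)[0])
        frame1 = signal_frame(run_screen(cases, dictionary, seizure_set), dictionary)
        frame2 = signal_frame(run_screen(cases, dictionary, seizure_set), dictionary)
        assert frame1.to_csv() == frame2.to_csv()


def test_null_table_wald_calibration():
    """Multinomial resampling of a null table: P(ror_low > 1) stays ≤ ~2.5%."""
    rng = np.random.default_rng(424242)
    probs = np.array([0.002, 0.048, 0.038, 0.912])  # independent drug/event margins
    n = 20_000
    draws = rng.multinomial(n, probs, size=2000)
    hits = 0
    for a, b, c, d in draws:
        if min(a, b, c, d) == 0:
            continue
        est = compute_ror(table(int(a), int(b), int(c), int(d)))
        hits += est.low > 1.0
    assert hits / 2000 <= 0.05 + 0.02
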