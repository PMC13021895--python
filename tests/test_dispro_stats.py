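import math
import random

import pytest
from scipy.stats import chi2_contingency

from pvdispro.contingency import ContingencyTable
from pvdispro.dispro_stats import (
    BcpnnPriors,
    SignalStatistics,
    Thresholds,
    compute_all,
    compute_bcpnn,
    compute_chi2,
    compute_ebgm,
    compute_prr,
    compute_ror,
    evaluate_signal,
)


def oracle_stats(a, b, c, d, priors=BcpnnPriors()):
    """Independent high-precision evaluation of all five statistics."""
    import mpmath as mp

    with mp.workdps(50):
        a, b, c, d = map(mp.mpf, (a, b, c, d))
        n = a + b + c + d
        se = mp.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ror = a * d / (b * c)
        ror_ci = (ror * mp.exp(-mp.mpf("1.96") * se), ror * mp.exp(mp.mpf("1.96") * se))
        prr = (a / (a + b)) / (c / (c + d))
        se_prr = mp.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        prr_ci = (prr * mp.exp(-mp.mpf("1.96") * se_prr),
                  prr * mp.exp(mp.mpf("1.96") * se_prr))
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        ic = mp.log(a * n / ((a + b) * (a + c)), 2)
        g, ai, bj, al, be = map(
            mp.mpf,
            (priors.gamma_ij, priors.alpha_i, priors.beta_j, priors.alpha, priors.beta),
        )
        gamma = g * (n + al) * (n + be) / ((a + b + ai) * (a + c + bj))
        e_ic = mp.log(
            (a + g) * (n + al) * (n + be) / ((n + gamma) * (a + b + ai) * (a + c + bj)),
            2,
        )
        v_ic = (
            (n - a + gamma - g) / ((a + g) * (1 + n + gamma))
            + (n - (a + b) + al - ai) / ((a + b + ai) * (1 + n + al))
            + (n - (a + c) + be - bj) / ((a + c + bj) * (1 + n + be))
        ) / mp.log(2) ** 2
        ic025 = e_ic - 2 * mp.sqrt(v_ic)
        ebgm = a * n / ((a + b) * (a + c))
        ebgm_ci = (ebgm * mp.exp(-mp.mpf("1.96") * se),
                   ebgm * mp.exp(mp.mpf("1.96") * se))
        return {
            "ror": ror, "ror_lo": ror_ci[0], "ror_hi": ror_ci[1],
            "prr": prr, "prr_lo": prr_ci[0], "prr_hi": prr_ci[1],
            "chi2": chi2,
            "ic": ic, "ic_expect": e_ic, "ic_var": v_ic, "ic025": ic025,
            "ebgm": ebgm, "ebgm05": ebgm_ci[0], "ebgm95": ebgm_ci[1],
        }


def random_tables(n, seed=7, lo=3, hi=10**6):
    rnd = random.Random(seed)
    out = []
    for _ in range(n):
        out.append(ContingencyTable(*(rnd.randint(lo, hi) for _ in range(4))))
    return out


class TestWorkedExamples:
    def test_ror_independence(self):
        assert compute_ror(ContingencyTable(10, 90, 100, 900))[0] == pytest.approx(1.0)

    def test_ror_hand_value(self):
        assert compute_ror(ContingencyTable(20, 80, 100, 900))[0] == pytest.approx(2.25)

    def test_ror_below_min_a_not_applicable(self):
        assert math.isnan(compute_ror(ContingencyTable(2, 8, 10, 80))[0])

    def test_zero_cell_not_applicable(self):
        assert math.isnan(compute_ror(ContingencyTable(5, 0, 10, 80))[0])

    def test_prr_symmetry(self):
        assert compute_prr(ContingencyTable(25, 25, 25, 25))[0] == pytest.approx(1.0)

    def test_prr_hand_value(self):
        assert compute_prr(ContingencyTable(20, 80, 100, 900))[0] == pytest.approx(2.0)

    def test_chi2_zero_at_independence(self):
        t = ContingencyTable(10, 90, 100, 900)
        assert compute_chi2(t) == 0.0
        assert compute_chi2(t, yates=True) == 0.0

    def test_chi2_hand_value(self):
        assert compute_chi2(ContingencyTable(20, 80, 100, 900)) == pytest.approx(
            9.353741496, rel=1e-9
        )

    def test_chi2_transpose_invariant(self):
        t = ContingencyTable(20, 80, 100, 900)
        tt = ContingencyTable(20, 100, 80, 900)
        assert compute_chi2(t) == pytest.approx(compute_chi2(tt))

    def test_chi2_agrees_with_scipy(self):
        for t in random_tables(50, seed=3, lo=5, hi=5000):
            table = [[t.a, t.b], [t.c, t.d]]
            assert compute_chi2(t) == pytest.approx(
                chi2_contingency(table, correction=False).statistic, rel=1e-10
            )
            assert compute_chi2(t, yates=True) == pytest.approx(
                chi2_contingency(table, correction=True).statistic, rel=1e-10
            )

    def test_bcpnn_prior_cancellation_at_balanced_table(self):
        ic, e_ic, v_ic, ic025 = compute_bcpnn(ContingencyTable(25, 25, 25, 25))
        assert ic == pytest.approx(0.0)
        assert e_ic == pytest.approx(0.0, abs=1e-15)
        assert v_ic > 0
        assert ic025 < e_ic

    def test_ic_zero_at_independence(self):
        ic, *_ = compute_bcpnn(ContingencyTable(10, 90, 100, 900))
        assert ic == pytest.approx(0.0)

    def test_ebgm_independence_and_hand_value(self):
        assert compute_ebgm(ContingencyTable(10, 90, 100, 900))[0] == pytest.approx(1.0)
        assert compute_ebgm(ContingencyTable(20, 80, 100, 900))[0] == pytest.approx(
            20 * 1100 / (120 * 100)
        )


class TestOracleEquivalence:
    def test_all_statistics_match_high_precision_oracle(self):
        worst = 0.0
        for t in random_tables(300, seed=11):
            s = compute_all(t)
            exact = oracle_stats(t.a, t.b, t.c, t.d)
            for name, value in exact.items():
                got = getattr(s, name)
                # unit floor: log-scale statistics pass through zero
                rel = abs(got - float(value)) / max(abs(float(value)), 1.0)
                worst = max(worst, rel)
        assert worst < 1e-12

    def test_ebgm_equals_two_to_the_ic(self):
        for t in random_tables(200, seed=13):
            s = compute_all(t)
            assert s.ebgm == pytest.approx(2.0 ** s.ic, rel=1e-13)

    def test_ci_upper_is_log_symmetric(self):
        for t in random_tables(100, seed=17):
            s = compute_all(t)
            assert s.ror_hi == pytest.approx(s.ror**2 / s.ror_lo, rel=1e-10)
            assert s.ebgm95 == pytest.approx(s.ebgm**2 / s.ebgm05, rel=1e-10)

    def test_monotone_in_a(self):
        prev = None
        for a in range(3, 200, 7):
            s = compute_all(ContingencyTable(a, 500, 300, 5000))
            if prev is not None:
                assert s.ror > prev.ror
                assert s.prr > prev.prr
                assert s.ic > prev.ic
                assert s.ebgm > prev.ebgm
            prev = s


class TestSignalDecision:
    def test_printed_strong_row_is_signal(self):
        # stats as printed for a strongly associated immune-disorder row
        stats = SignalStatistics(
            a=4571, ror=6.23, ror_lo=6.05, ror_hi=6.42,
            prr=5.88, prr_lo=5.77, prr_hi=6.0,
            ic025=2.5, ebgm=5.85, ebgm05=5.7,
        )
        assert evaluate_signal(stats).signal is True

    def test_printed_null_row_is_not_signal(self):
        stats = SignalStatistics(
            a=231, ror=0.98, ror_lo=0.86, ror_hi=1.12,
            prr=0.98, prr_lo=0.85, prr_hi=1.12,
            ic025=-0.21, ebgm=0.98, ebgm05=0.88,
        )
        decision = evaluate_signal(stats)
        assert decision.signal is False
        assert not decision.flags["ror"] and not decision.flags["bcpnn"]

    def test_boundary_semantics(self):
        # >= for point thresholds, strict > for CI bounds
        at_boundary = SignalStatistics(
            a=3, ror=2.0, ror_lo=1.0, prr=2.0, prr_lo=1.0,
            ic025=0.0, ebgm05=2.0,
        )
        decision = evaluate_signal(at_boundary)
        assert decision.signal is False
        just_above = SignalStatistics(
            a=3, ror=2.0, ror_lo=1.0001, prr=2.0, prr_lo=1.0001,
            ic025=0.0001, ebgm05=2.0001,
        )
        assert evaluate_signal(just_above).signal is True

    def test_nan_statistics_fail_their_criterion(self):
        s = compute_all(ContingencyTable(2, 8, 10, 80))
        assert math.isnan(s.ror) and s.signal is False

    def test_min_a_gates_everything(self):
        s = compute_all(ContingencyTable(200, 80, 100, 900),
                        th=Thresholds(min_a=500))
        assert not s.flags["min_a"] and not s.signal

    def test_chi2_not_part_of_criterion(self):
        s = compute_all(ContingencyTable(10, 90, 100, 900))  # chi2 == 0
        assert "chi2" not in s.flags


def test_priors_must_be_positive():
    with pytest.raises(ValueError):
        BcpnnPriors(gamma_ij=0)
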