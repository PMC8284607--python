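import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutacc.fluctuation import (
    FluctuationExperiment,
    MutationRateEstimate,
    grid_search_mle,
    luria_delbruck_pmf,
    mss_mle,
    plating_correction,
    rate_ratio,
    read_fluctuation_tsv,
)
from mutacc.simulate import simulate_fluctuation


class TestPmf:
    def test_m_zero_is_point_mass_at_zero(self):
        p = luria_delbruck_pmf(0.0, 5)
        assert p[0] == 1.0 and np.all(p[1:] == 0)

    def test_p0_is_exp_minus_m(self):
        assert luria_delbruck_pmf(1.0, 0)[0] == pytest.approx(math.exp(-1))
        assert luria_delbruck_pmf(2.5, 3)[0] == pytest.approx(math.exp(-2.5))

    def test_p1_one_recursion_step(self):
        # p_1 = (m/1) * p_0 / 2
        p = luria_delbruck_pmf(1.0, 1)
        assert p[1] == pytest.approx(math.exp(-1) / 2)

    def test_p2_two_recursion_steps_by_hand(self):
        # p_2 = (m/2) * (p_0/3 + p_1/2)
        m = 1.3
        p = luria_delbruck_pmf(m, 2)
        p0 = math.exp(-m)
        p1 = m * p0 / 2
        assert p[2] == pytest.approx((m / 2) * (p0 / 3 + p1 / 2))

    def test_negative_m_rejected(self):
        with pytest.raises(ValueError):
            luria_delbruck_pmf(-0.1, 5)

    @pytest.mark.parametrize("m", [0.5, 2.0, 5.0])
    def test_mass_deficit_shrinks_like_m_over_kmax(self, m):
        # the heavy ~m/k^2 tail leaves a deficit of about m/kmax
        d1 = 1.0 - luria_delbruck_pmf(m, 2000).sum()
        d2 = 1.0 - luria_delbruck_pmf(m, 4000).sum()
        assert 0 < d2 < d1 < 2 * m / 2000
        assert d1 / d2 == pytest.approx(2.0, rel=0.1)

    def test_all_probabilities_non_negative(self):
        assert np.all(luria_delbruck_pmf(3.7, 500) >= 0)


class TestMle:
    def test_all_zero_counts_give_zero_with_one_sided_ci(self):
        est = mss_mle(FluctuationExperiment((0,) * 12, N_t=1e7))
        assert est.m_hat == 0.0
        assert est.ci95[0] == 0.0 and est.ci95[1] > 0

    def test_matches_grid_search_oracle(self):
        exp = FluctuationExperiment((0, 1, 0, 3, 12, 0, 2, 1, 0, 5, 0, 1), N_t=1e7)
        est = mss_mle(exp, correct_plating=False)
        fine = np.linspace(est.m_hat * 0.9, est.m_hat * 1.1, 40_001)
        oracle = grid_search_mle(exp, grid=fine)
        assert abs(est.m_hat - oracle) <= 1e-4

    def test_recovers_simulated_m_within_5_percent(self):
        exp = simulate_fluctuation(
            mu=2 / (1_000_000 - 100), N0=100, N_t=1_000_000,
            n_cultures=10_000, epsilon=1.0, seed=3,
        )
        est = mss_mle(exp, kmax_cap=5000)
        assert est.m_hat == pytest.approx(2.0, rel=0.05)
        assert est.ci95[0] < 2.0 < est.ci95[1]

    def test_culture_order_invariant_but_doubling_counts_is_not(self):
        counts = (0, 2, 0, 1, 7, 0, 0, 3, 1, 0, 0, 2)
        a = mss_mle(FluctuationExperiment(counts, N_t=1e7))
        b = mss_mle(FluctuationExperiment(counts[::-1], N_t=1e7))
        assert a.m_hat == pytest.approx(b.m_hat, abs=1e-12)
        doubled = mss_mle(FluctuationExperiment(tuple(2 * c for c in counts), N_t=1e7))
        assert abs(doubled.m_hat - a.m_hat) > 0.05

    def test_ci_coverage_at_least_90_percent(self):
        n_rep, hits, valid = 200, 0, 0
        for seed in range(n_rep):
            exp = simulate_fluctuation(
                mu=1 / (100_000 - 100), N0=100, N_t=100_000,
                n_cultures=12, epsilon=1.0, seed=seed,
            )
            est = mss_mle(exp, kmax_cap=5000)
            lo, hi = est.ci95
            if math.isfinite(lo) and math.isfinite(hi):
                valid += 1
                hits += lo <= 1.0 <= hi
        assert valid >= 0.95 * n_rep
        assert hits / valid >= 0.90

    def test_rate_conventions(self):
        exp = FluctuationExperiment((0, 1, 2, 0, 1, 3), N_t=1e7)
        per_culture = mss_mle(exp, rate_convention="per_culture")
        per_division = mss_mle(exp, rate_convention="per_division")
        assert per_division.rate == pytest.approx(per_culture.rate / math.log(2))


class TestPlatingCorrection:
    def test_full_plating_is_identity(self):
        assert plating_correction(1.0) == 1.0

    def test_known_value_at_0_6(self):
        # (0.6 - 1) / (0.6 * ln 0.6) = 1.3054...
        assert plating_correction(0.6) == pytest.approx(
            (-0.4) / (0.6 * math.log(0.6))
        )

    def test_correction_recovers_true_m_at_small_m(self):
        exp = simulate_fluctuation(
            mu=0.5 / (25_000_000 - 2500), N0=2500, N_t=25_000_000,
            n_cultures=4000, epsilon=0.6, seed=8,
        )
        est = mss_mle(exp, correct_plating=True, kmax_cap=5000)
        assert est.m_hat == pytest.approx(0.5, rel=0.10)
        assert est.m_obs < est.m_hat  # thinning reduces the observed m


class TestRateRatio:
    def _est(self, rate, lo=None, hi=None):
        m = rate * 1e7
        lo = lo if lo is not None else m * 0.8
        hi = hi if hi is not None else m * 1.25
        return MutationRateEstimate(m, rate, (lo, hi), 0.0, m, 1.0, 1e7)

    def test_identical_estimates_give_one(self):
        a = self._est(3e-8)
        assert rate_ratio(a, a).ratio == pytest.approx(1.0)

    def test_seventy_fold(self):
        assert rate_ratio(self._est(7e-7), self._est(1e-8)).ratio == pytest.approx(70.0)

    def test_zero_denominator_suggests_p0_bound(self):
        a = self._est(3e-8)
        zero = MutationRateEstimate(0.0, 0.0, (0.0, 0.1), 0.0, 0.0, 1.0, 1e7)
        with pytest.raises(ValueError, match="p0"):
            rate_ratio(a, zero)

    def test_simulated_ratio_within_interval(self):
        a = mss_mle(simulate_fluctuation(10 / 1e6, 100, 1_000_000, 2000, seed=21),
                    kmax_cap=5000)
        b = mss_mle(simulate_fluctuation(2 / 1e6, 100, 1_000_000, 2000, seed=22),
                    kmax_cap=5000)
        rr = rate_ratio(a, b)
        assert rr.ci95[0] < 5.0 < rr.ci95[1]


class TestIO:
    def test_strain_table_roundtrip(self, tmp_path):
        p = tmp_path / "wells.tsv"
        p.write_text("strain\tcount\nwt\t0\nwt\t2\nmut\t5\nmut\t9\n")
        exps = read_fluctuation_tsv(p, N_t=2.4e7, epsilon=0.6)
        assert exps["wt"].counts == (0, 2)
        assert exps["mut"].counts == (5, 9)
        assert exps["mut"].epsilon == 0.6


@settings(deadline=None, derandomize=True, max_examples=15)
@given(st.floats(0.05, 4.0))
def test_pmf_matches_naive_recursion(m):
    """The vectorized recursion agrees with a literal transcription."""
    kmax = 30
    p = luria_delbruck_pmf(m, kmax)
    naive = [math.exp(-m)]
    for k in range(1, kmax + 1):
        naive.append((m / k) * sum(naive[i] / (k - i + 1) for i in range(k)))
    assert np.allclose(p, naive, rtol=1e-12, atol=1e-300)
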