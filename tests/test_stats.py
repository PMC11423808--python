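"""Statistical operators against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortiquant import stats


def enumerate_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of arrangements."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(sample_a, sample_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in sample_a for y in sample_b
        )

    u_obs = u_stat(a, b)
    mean_u = n_a * len(b) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        sel = set(combo)
        ua = u_stat(
            [pooled[i] for i in sel], [pooled[i] for i in range(len(pooled)) if i not in sel]
        )
        if abs(ua - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def t_sf_by_integration(t, df):
    """Independent upper-tail of the t distribution by numeric integration."""
    from scipy.integrate import quad

    norm = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    dens = lambda x: norm * (1 + x * x / df) ** (-(df + 1) / 2)
    val, _ = quad(dens, t, np.inf, limit=200)
    return val


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = stats.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(4):
            a = rng.permutation(12)[:5].tolist()
            b = [x for x in range(12) if x not in a][:5]
            res = stats.mann_whitney_u(a, b)
            assert res.p_value == pytest.approx(enumerate_mw_p(a, b), abs=1e-9)

    def test_identical_multisets_degenerate_limit(self):
        res = stats.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n^2 / 2
        assert res.p_value > 0.95

    def test_all_tied_values(self):
        res = stats.mann_whitney_u([2, 2], [2, 2, 2])
        assert res.p_value == 1.0 and res.flags["degenerate"]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_u([], [1.0])

    def test_exact_and_asymptotic_agree_on_tie_free_samples(self):
        rng = np.random.default_rng(9)
        from scipy.stats import mannwhitneyu

        for _ in range(5):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            exact = stats.mann_whitney_u(a, b)
            assert exact.method == "exact"
            approx = mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(exact.p_value - approx) < 0.02

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.lists(st.integers(0, 50), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 50), min_size=1, max_size=8),
    )
    def test_swap_symmetry(self, a, b):
        r1 = stats.mann_whitney_u(a, b)
        r2 = stats.mann_whitney_u(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_null_type_one_error_calibrated(self):
        rate = stats.null_rejection_rate(n_reps=600, n_per_group=10, seed=4)
        assert 0.02 < rate < 0.08


class TestPairedT:
    def test_known_differences(self):
        res = stats.paired_t_test([2.0, 3.0, 4.0, 5.0], [1.0, 1.0, 1.0, 1.0])
        assert res.statistic == pytest.approx(3.873, abs=1e-3)
        assert res.p_value == pytest.approx(0.0305, abs=5e-4)

    def test_p_matches_numeric_integration(self):
        res = stats.paired_t_test([2.0, 3.0, 4.0, 5.0], [1.0, 1.0, 1.0, 1.0])
        expected = 2.0 * t_sf_by_integration(res.statistic, df=3)
        assert res.p_value == pytest.approx(expected, abs=1e-4)

    def test_antisymmetry(self):
        a = [1.0, 4.0, 2.0, 8.0]
        b = [0.5, 5.0, 1.0, 6.0]
        r1 = stats.paired_t_test(a, b)
        r2 = stats.paired_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_pairing_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            stats.paired_t_test([1.0, 2.0], [1.0, 2.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            stats.paired_t_test([1.0], [2.0])


class TestPolarHistogram:
    def test_worked_example(self):
        s = stats.polar_histogram([-170.0, -100.0, 10.0, 100.0], bin_deg=90.0)
        assert s.posterior_count == 3 and s.anterior_count == 1
        assert s.posterior_pct == pytest.approx(75.0)
        assert s.counts.sum() == 4

    def test_point_mass_single_bin(self):
        s = stats.polar_histogram([0.0] * 7, bin_deg=15.0)
        assert (s.counts > 0).sum() == 1
        assert s.posterior_pct == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stats.polar_histogram([], bin_deg=15.0)

    def test_bin_must_divide_360(self):
        with pytest.raises(ValueError):
            stats.polar_histogram([0.0], bin_deg=50.0)

    def test_right_closed_bins(self):
        s = stats.polar_histogram([180.0, -179.9], bin_deg=90.0)
        assert s.counts[0] == 1 and s.counts[-1] == 1

    @settings(deadline=None, max_examples=25)
    @given(
        thetas=st.lists(
            st.floats(-179.9, 180.0, allow_nan=False), min_size=1, max_size=30
        ),
        seed=st.integers(0, 100),
    )
    def test_order_invariance_and_percentage_sum(self, thetas, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(thetas))
        s1 = stats.polar_histogram(thetas, bin_deg=30.0)
        s2 = stats.polar_histogram(shuffled, bin_deg=30.0)
        assert np.array_equal(s1.counts, s2.counts)
        assert s1.anterior_pct + s1.posterior_pct == pytest.approx(100.0)
        assert s1.counts.sum() == len(thetas)

    def test_plot_renders(self, tmp_path):
        s = stats.polar_histogram([10.0, -120.0, 170.0], bin_deg=30.0)
        p = stats.plot_polar_histogram(s, tmp_path / "polar.png")
        assert p.exists() and p.stat().st_size > 0
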