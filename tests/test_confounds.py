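"""ECG confound controls: windowed amplitudes, paired tests, RM-ANCOVA."""

import itertools

import numpy as np
import pytest
from scipy import stats

from hepsleep.confounds import (
    ConfoundError,
    compare_conditions_scalar,
    pearson_contrast_correlation,
    rm_ancova_condition,
    window_mean_amplitude,
)
from hepsleep.hep import HEPAverage


def _average(data, times_ms, labels):
    return HEPAverage(
        mean=np.asarray(data, dtype=float),
        sem=np.zeros_like(np.asarray(data, dtype=float)),
        n_trials=10,
        condition="phasic",
        times_ms=np.asarray(times_ms, dtype=float),
        labels=labels,
    )


class TestWindowMean:
    def test_constant_waveform_returns_constant(self):
        avg = _average(np.full((2, 100), 3.5), np.arange(100), ["a", "b"])
        assert window_mean_amplitude(avg, (10, 50)) == pytest.approx(3.5)

    def test_linear_ramp_returns_midpoint(self):
        t = np.arange(101, dtype=float)
        avg = _average((t * 0.1)[None, :], t, ["a"])
        assert window_mean_amplitude(avg, (0, 100), ["a"]) == pytest.approx(
            5.0
        )

    def test_random_matrix_matches_direct_submatrix_mean(self, rng):
        t = np.linspace(-200, 800, 257)
        data = rng.normal(size=(4, 257))
        avg = _average(data, t, ["w", "x", "y", "z"])
        win = (350.0, 650.0)
        mask = (t >= win[0]) & (t <= win[1])
        expected = data[[1, 3]][:, mask].mean()
        got = window_mean_amplitude(avg, win, ["x", "z"])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_empty_channel_set_rejected(self):
        avg = _average(np.zeros((2, 10)), np.arange(10), ["a", "b"])
        with pytest.raises(ConfoundError):
            window_mean_amplitude(avg, (0, 5), [])


class TestPairedComparison:
    def test_identical_vectors_are_degenerate(self):
        x = np.arange(8.0)
        out = compare_conditions_scalar(x, x.copy())
        assert out.test == "degenerate"
        assert out.statistic == 0.0 and out.p_value == 1.0

    def test_normal_differences_take_t_branch_and_match_formula(self, rng):
        x = rng.normal(10, 2, 15)
        y = x - rng.normal(0.5, 0.3, 15)
        out = compare_conditions_scalar(x, y)
        assert out.test == "paired_t"
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert out.statistic == pytest.approx(t_ref, rel=1e-12)
        assert out.effect_size == pytest.approx(
            d.mean() / d.std(ddof=1), rel=1e-12
        )

    def test_heavy_tailed_differences_take_wilcoxon_branch(self, rng):
        d = rng.standard_cauchy(20) * 5
        x = np.zeros(20) + d
        out = compare_conditions_scalar(x, np.zeros(20))
        assert out.test == "wilcoxon"

    def test_wilcoxon_exact_p_matches_enumeration_for_n8(self):
        # heavy-tailed, fixed vector; exact null enumerated over all
        # 2^8 sign assignments of the |d| ranks
        d = np.array([0.1, 0.2, 0.15, 0.12, 90.0, 0.18, -0.11, 0.16])
        out = compare_conditions_scalar(d, np.zeros_like(d))
        assert out.test == "wilcoxon"
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        null = []
        for signs in itertools.product([0, 1], repeat=8):
            w = sum(r for s, r in zip(signs, ranks) if s)
            null.append(w)
        null = np.asarray(null, dtype=float)
        # two-sided exact p on the signed-rank statistic
        lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
        p_exact = np.mean((null <= lo) | (null >= hi))
        assert out.p_value == pytest.approx(p_exact, rel=1e-9)

    def test_branch_is_deterministic_in_input(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        first = compare_conditions_scalar(x, y)
        second = compare_conditions_scalar(x, y)
        assert first == second


class TestRMAncova:
    def test_zero_covariate_reduces_to_squared_paired_t(self, rng):
        a = rng.normal(1.0, 1.0, 12)
        b = rng.normal(0.0, 1.0, 12)
        out = rm_ancova_condition(a, b, np.zeros(12))
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert not out.covariate_defined
        assert out.f_condition == pytest.approx(t_ref**2, rel=1e-9)
        assert out.p_condition == pytest.approx(p_ref, rel=1e-9)
        assert out.df == (1, 11)

    def test_identical_conditions_give_null_f(self, rng):
        a = rng.normal(size=10)
        cov = rng.normal(size=10)
        out = rm_ancova_condition(a, a.copy(), cov)
        assert out.f_condition == pytest.approx(0.0, abs=1e-20)
        assert out.p_condition == pytest.approx(1.0)

    def test_df_matches_two_level_within_design(self, rng):
        n = 20
        out = rm_ancova_condition(
            rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)
        )
        assert out.df == (1, 18)

    def test_partial_eta_squared_recovery_in_simulation(self):
        # known adjusted effect: d_i = delta + beta*x_i + eps
        rng = np.random.default_rng(3)
        n, delta, beta, sd = 24, 0.8, 0.5, 1.0
        etas, f_exp = [], []
        for _ in range(200):
            x = rng.normal(0, 1, n)
            d = delta + beta * (x - x.mean()) + rng.normal(0, sd, n)
            out = rm_ancova_condition(d, np.zeros(n), x)
            etas.append(out.partial_eta_sq)
        # population partial eta^2 for the intercept:
        # F ~ n*delta^2/sd^2 -> eta2 = F/(F+df)
        f_pop = n * delta**2 / sd**2
        eta_pop = f_pop / (f_pop + (n - 2))
        assert np.mean(etas) == pytest.approx(eta_pop, abs=0.07)

    def test_requires_minimum_subjects(self):
        with pytest.raises(ConfoundError):
            rm_ancova_condition(np.ones(3), np.zeros(3), np.zeros(3))


class TestContrastCorrelation:
    def test_identical_vectors_give_r_one(self, rng):
        x = rng.normal(size=10)
        out = pearson_contrast_correlation(x, x.copy())
        assert out["r"] == pytest.approx(1.0)

    def test_orthogonal_centered_vectors_give_r_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson_contrast_correlation(x, y)["r"] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        out = pearson_contrast_correlation(x, y)
        ref = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert out["r"] == pytest.approx(ref, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfoundError):
            pearson_contrast_correlation(np.ones(5), np.arange(5.0))
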