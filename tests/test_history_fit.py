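"""Reward-history models: closed forms, oracle equivalence, grid recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from striatd.history_fit import (DeltaRuleScan, LeakyIntegratorScan,
                                 default_alpha_grid, default_tau_grid,
                                 delta_rule_values, leaky_rate,
                                 rpe_coding_fraction, scan_alpha, scan_tau,
                                 tercile_labels)
from striatd.signal_ops import AlignedResponse


class TestLeakyRate:
    def test_no_rewards_zero(self):
        np.testing.assert_array_equal(
            leaky_rate([], 10.0, [1.0, 5.0, 100.0]), 0.0)

    def test_single_reward_closed_form(self):
        out = leaky_rate([0.0], 7.0, [7.0, 14.0])
        np.testing.assert_allclose(out, [np.exp(-1), np.exp(-2)])

    def test_left_limit_excludes_simultaneous_reward(self):
        # evaluating exactly at a reward time sees only *prior* rewards
        out = leaky_rate([0.0, 10.0], 10.0, [10.0])
        assert out[0] == pytest.approx(np.exp(-1.0))

    def test_poisson_long_run_mean(self):
        # renewal theory: stationary mean of the integrated rate = lambda*tau
        rng = np.random.default_rng(0)
        lam, tau = 0.2, 30.0
        times = np.cumsum(rng.exponential(1 / lam, 20_000))
        ev = np.linspace(times[500], times[-1], 5_000)
        mean_rate = leaky_rate(times, tau, ev).mean()
        assert mean_rate == pytest.approx(lam * tau, rel=0.05)

    @given(split=st.integers(1, 19))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_additivity_over_reward_subsets(self, split):
        rng = np.random.default_rng(3)
        rewards = np.sort(rng.uniform(0, 100, 20))
        ev = np.linspace(0, 120, 50)
        full = leaky_rate(rewards, 15.0, ev)
        part = (leaky_rate(rewards[:split], 15.0, ev)
                + leaky_rate(rewards[split:], 15.0, ev))
        np.testing.assert_allclose(full, part, atol=1e-12)

    def test_monotone_in_tau(self):
        rewards = np.arange(0.0, 200.0, 20.0)
        v10 = leaky_rate(rewards, 10.0, [205.0])
        v100 = leaky_rate(rewards, 100.0, [205.0])
        assert v100 > v10

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            leaky_rate([5.0, 1.0], 10.0, [6.0])


class TestDeltaRule:
    def test_alpha_zero_constant(self):
        v = delta_rule_values([1, 0, 1, 1], 0.0, 0.3)
        np.testing.assert_array_equal(v, 0.3)

    def test_alpha_one_tracks_previous_outcome(self):
        out = [1, 0, 1, 1, 0]
        v = delta_rule_values(out, 1.0, 0.0)
        np.testing.assert_array_equal(v[1:], out[:-1])

    def test_hand_iteration(self):
        v = delta_rule_values([1, 1], 0.5, 0.0)
        np.testing.assert_allclose(v, [0.0, 0.5])

    def test_closed_form_oracle(self):
        # V_t = (1-a)^t V0 + a * sum_k (1-a)^k r_{t-1-k}
        rng = np.random.default_rng(7)
        r = rng.integers(0, 2, 1000)
        alpha, v0 = 0.13, 0.4
        v = delta_rule_values(r, alpha, v0)
        for t in (0, 1, 17, 999):
            closed = (1 - alpha) ** t * v0 + alpha * sum(
                (1 - alpha) ** k * r[t - 1 - k] for k in range(t))
            assert abs(v[t] - closed) < 1e-12

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            delta_rule_values([0, 2], 0.5)


class TestScanTau:
    def test_noiseless_construction_recovery(self):
        rng = np.random.default_rng(5)
        rewards = np.sort(rng.uniform(0, 5000, 200))
        rate = leaky_rate(rewards, 60.0, rewards)
        responses = 1.0 - 0.5 * rate
        grid = np.sort(np.append(default_tau_grid(), 60.0))
        fit = scan_tau(responses, rewards, rewards, grid)
        assert fit.best_param == 60.0
        assert fit.best_objective == pytest.approx(-1.0)

    def test_pure_noise_flagged_by_permutation(self):
        rng = np.random.default_rng(6)
        rewards = np.sort(rng.uniform(0, 5000, 150))
        responses = rng.standard_normal(150)
        fit = scan_tau(responses, rewards, rewards, n_perm=200, seed=1)
        assert abs(fit.best_objective) < 0.5
        assert fit.p_value > 0.05

    def test_single_point_grid(self):
        rng = np.random.default_rng(2)
        rewards = np.sort(rng.uniform(0, 1000, 50))
        responses = rng.standard_normal(50)
        fit = scan_tau(responses, rewards, rewards, tau_grid=[42.0])
        assert fit.best_param == 42.0

    def test_constant_responses_rejected(self):
        with pytest.raises(ValueError):
            scan_tau(np.ones(20), np.arange(20.0), np.arange(20.0))

    def test_estimator_wrapper(self):
        rng = np.random.default_rng(5)
        rewards = np.sort(rng.uniform(0, 5000, 200))
        responses = 1.0 - 0.5 * leaky_rate(rewards, 60.0, rewards)
        grid = np.sort(np.append(default_tau_grid(), 60.0))
        est = LeakyIntegratorScan(tau_grid=grid).fit((rewards, rewards),
                                                     responses)
        assert est.best_tau_ == 60.0
        assert est.best_objective_ == pytest.approx(-1.0)
        params = est.get_params()
        assert "tau_grid" in params and "n_perm" in params


class TestScanAlpha:
    def test_construction_recovery_within_grid_step(self):
        rng = np.random.default_rng(9)
        outcomes = rng.integers(0, 2, 400)
        v = delta_rule_values(outcomes, 0.3)
        responses = 1.0 - v[outcomes == 1]
        fit = scan_alpha(responses, outcomes)
        assert abs(fit.best_param - 0.3) <= 0.01

    def test_degenerate_grid_rejected(self):
        rng = np.random.default_rng(10)
        outcomes = rng.integers(0, 2, 100)
        responses = rng.standard_normal(int(outcomes.sum()))
        with pytest.raises(ValueError):
            scan_alpha(responses, outcomes, alpha_grid=[0.0])

    def test_high_alpha_noisy_recovery(self):
        # responses anti-generated with alpha*=0.9: best alpha stays high
        rng = np.random.default_rng(11)
        best = []
        for rep in range(30):
            outcomes = rng.integers(0, 2, 300)
            v = delta_rule_values(outcomes, 0.9)
            clean = 1.0 - v[outcomes == 1]
            noisy = clean + rng.standard_normal(len(clean)) * (
                0.25 * clean.std())
            best.append(scan_alpha(noisy, outcomes).best_param)
        assert np.median(best) >= 0.8

    def test_estimator_wrapper(self):
        rng = np.random.default_rng(12)
        outcomes = rng.integers(0, 2, 300)
        v = delta_rule_values(outcomes, 0.4)
        responses = 1.0 - v[outcomes == 1]
        est = DeltaRuleScan().fit(outcomes, responses)
        assert abs(est.best_alpha_ - 0.4) <= 0.01


class TestTerciles:
    def test_exact_split(self):
        labels = tercile_labels(np.arange(1, 10))
        assert list(labels) == ["low"] * 3 + ["mid"] * 3 + ["high"] * 3

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            tercile_labels(np.ones(9))

    def test_uniform_draw_balance(self):
        rng = np.random.default_rng(1)
        labels = tercile_labels(rng.uniform(size=100))
        counts = sorted(np.unique(labels, return_counts=True)[1])
        assert counts[0] >= 32 and counts[-1] <= 35

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            tercile_labels([1.0, 2.0])


def _make_session(slope, n, noise_sd, rng, n_bins=20, sig_bins=(5, 10)):
    rates = rng.uniform(0, 2, n)
    Y = rng.standard_normal((n, n_bins)) * noise_sd
    Y[:, sig_bins[0]: sig_bins[1]] += slope * rates[:, None]
    aligned = AlignedResponse(window=(-0.5, 1.4), snippets=Y, fs=10.0)
    return aligned, rates


class TestRpeCodingFraction:
    def test_power_at_signal_bins(self):
        rng = np.random.default_rng(3)
        sessions = [_make_session(-0.5, 200, 0.1, rng) for _ in range(5)]
        out = rpe_coding_fraction(sessions)
        assert np.all(out["fraction"][5:10] == 1.0)
        assert np.all(out["mean_slope_sign"][5:10] == -1.0)

    def test_type_one_error_calibration(self):
        # with shuffled rates the per-bin significant fraction matches the
        # nominal threshold
        rng = np.random.default_rng(4)
        sessions = []
        for _ in range(400):
            aligned, rates = _make_session(0.0, 30, 1.0, rng, n_bins=5,
                                           sig_bins=(0, 0))
            sessions.append((aligned, rng.permutation(rates)))
        out = rpe_coding_fraction(sessions, p_thresh=0.01)
        # 400 sessions x 5 bins = 2000 tests; binomial 99.9% band
        assert out["fraction"].mean() == pytest.approx(0.01, abs=0.012)

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(5)
        aligned, rates = _make_session(-0.5, 50, 0.0, rng)
        out = rpe_coding_fraction([(aligned, rates)])
        assert np.all(out["fraction"][5:10] == 1.0)

    def test_too_few_snippets_rejected(self):
        rng = np.random.default_rng(6)
        aligned, rates = _make_session(0.0, 2, 1.0, rng)
        with pytest.raises(ValueError):
            rpe_coding_fraction([(aligned, rates)])
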