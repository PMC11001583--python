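"""Recurrent actor-critic: ops, environment contract, gradients, RPEs."""

import numpy as np
import pytest

from striatd.rnn_agent import (Agent, AgentConfig, EnvState, compute_gae,
                               encode_inputs, env_step, extract_rpe,
                               gamma_from_tau, ppo_policy_loss, train_agent,
                               value_targets)
from striatd.rnn_agent import _loss_and_output_grads
from striatd.task_sim import EventStream, TaskConfig, \
    generate_pavlovian_session

TINY = AgentConfig(tau_list=(0.2, 1.0), dt=0.05, units_per_subnet=4, T=12,
                   seed=3, n_background=1, n_cues=2, n_shared_cue_dims=2)


class TestGammaFromTau:
    def test_closed_forms(self):
        assert gamma_from_tau(2.0, 0.05) == pytest.approx(np.exp(-0.025))
        assert gamma_from_tau(1.0, 1.0) == pytest.approx(np.exp(-1))
        assert gamma_from_tau(1e12, 0.05) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_tau(-1.0, 0.05)
        with pytest.raises(ValueError):
            gamma_from_tau(1.0, 0.0)


class TestEncodeInputs:
    def test_background_only_without_events(self):
        stream = EventStream.from_records([(0.0, "pellet", None)])
        cfg = AgentConfig()
        X, _ = encode_inputs(stream, cfg)
        assert np.array_equal(np.unique(X[:, :-3]), [0.0])
        assert np.array_equal(np.unique(X[:, -3:]), [1.0])

    def test_cue_dims_during_presentation(self):
        stream = EventStream.from_records([
            (10.0, "cue_onset", 1), (12.6, "cue_offset", 1),
        ])
        cfg = AgentConfig()
        X, t0 = encode_inputs(stream, cfg)
        s = int((10.0 - t0) / cfg.dt) + 1
        row = X[s]
        assert row[1 + 1] == 1.0          # its one-hot dim
        assert row[1] == 0.0 and row[3] == 0.0  # other one-hots silent
        assert np.all(row[4: 4 + 17] == 1.0)    # shared dims
        n_active = int((X[:, 2] == 1).sum())
        assert n_active == pytest.approx(2.6 / cfg.dt, abs=1)

    def test_click_value_single_step(self):
        stream = EventStream.from_records([(5.0, "reward_click", None)])
        cfg = AgentConfig()
        X, _ = encode_inputs(stream, cfg)
        click_col = X[:, 0]
        assert click_col.max() == 5.0
        assert (click_col > 0).sum() == 1

    def test_overlapping_cues_rejected(self):
        stream = EventStream.from_records([
            (0.0, "cue_onset", 0), (2.6, "cue_offset", 0),
            (1.0, "cue_onset", 1), (3.6, "cue_offset", 1),
        ])
        with pytest.raises(ValueError):
            encode_inputs(stream, AgentConfig())


class TestEnvStep:
    def test_no_poke_never_costs(self):
        s = EnvState()
        total = 0.0
        for _ in range(10):
            r, s = env_step(s, 0)
            total += r
        assert total == 0.0

    def test_consecutive_poke_costs(self):
        s = EnvState()
        rewards = []
        for _ in range(3):
            r, s = env_step(s, 1)
            rewards.append(r)
        np.testing.assert_allclose(rewards, [-0.003, -0.0003, -0.0003])

    def test_click_collected_by_first_poke(self):
        s = EnvState()
        r, s = env_step(s, 0, click_now=True)
        assert r == 0.0 and s.pending_reward
        r, s = env_step(s, 0)
        assert r == 0.0
        r, s = env_step(s, 1)
        assert r == pytest.approx(1.0 - 0.003)
        r, s = env_step(s, 1)  # reward collectable only once
        assert r == pytest.approx(-0.0003)

    def test_poke_at_click_step_collects(self):
        r, _ = env_step(EnvState(), 1, click_now=True)
        assert r == pytest.approx(0.997)


class TestGaeAndTargets:
    def test_hand_example(self):
        np.testing.assert_allclose(compute_gae([1, 0, 0], 1.0, 0.5),
                                   [1.0, 0.0, 0.0])

    def test_zero_deltas(self):
        np.testing.assert_allclose(compute_gae(np.zeros(5), 0.9, 0.98), 0.0)

    def test_gamlam_zero_identity(self):
        d = np.array([0.3, -0.2, 0.9])
        np.testing.assert_allclose(compute_gae(d, 0.0, 0.98), d)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(1000)
        g, lam = 0.97, 0.98
        A = compute_gae(d, g, lam)
        T = len(d)
        for t in (0, 1, 500, 998, 999):
            brute = sum((g * lam) ** (k - t) * d[k] for k in range(t, T))
            assert abs(A[t] - brute) < 1e-10

    def test_value_targets_brute_force(self):
        rng = np.random.default_rng(1)
        r = rng.standard_normal(1000)
        g, boot = 0.95, 0.7
        out = value_targets(r, boot, g)
        T = len(r)
        for t in (0, 3, 999):
            brute = sum(g ** (k - t) * r[k] for k in range(t, T)) \
                + g ** (T - t) * boot
            assert abs(out[t] - brute) < 1e-10

    def test_one_step_consistency(self):
        rng = np.random.default_rng(2)
        r = rng.standard_normal(200)
        g, boot = 0.9, 0.3
        out = value_targets(r, boot, g)
        np.testing.assert_allclose(out[:-1], r[:-1] + g * out[1:],
                                   atol=1e-10)
        assert out[-1] == pytest.approx(r[-1] + g * boot)

    def test_single_delayed_reward(self):
        r = np.zeros(10)
        r[4] = 1.0  # received at horizon k=5 after t=0 (r_{t+1} convention)
        out = value_targets(r, 0.0, 0.5)
        assert out[0] == pytest.approx(0.5 ** 4)

    def test_gamma_one_plain_sum(self):
        r = np.ones(10)
        out = value_targets(r, 2.0, 1.0)
        assert out[0] == pytest.approx(12.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_gae([], 0.9, 0.98)
        with pytest.raises(ValueError):
            value_targets([], 0.0, 0.9)


class TestPpoLoss:
    @pytest.mark.parametrize("rho,A,expected", [
        (1.0, 0.7, 0.7),
        (2.0, 1.0, 1.2),
        (0.5, -1.0, -0.8),
    ])
    def test_hand_values(self, rho, A, expected):
        assert ppo_policy_loss([rho], [A], 0.2) == pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            ppo_policy_loss([0.0], [1.0], 0.2)


class TestGradients:
    def test_analytic_matches_numerical(self):
        """BPTT gradients of the full loss agree with central differences."""
        agent = Agent(TINY)
        rng = np.random.default_rng(0)
        T = TINY.T
        X = rng.standard_normal((T, TINY.input_dim)) * 0.5
        h0 = np.zeros_like(agent.h)
        c0 = np.zeros_like(agent.c)
        fwd = agent.forward_sequence(X, rng=np.random.default_rng(1),
                                     h0=h0, c0=c0)
        actions = fwd["actions"]
        adv = rng.standard_normal(T)
        targets = rng.standard_normal((T, TINY.n_subnets))
        # jitter old log-probs so the clipping branches are exercised
        old_logp = (np.log(fwd["probs"][np.arange(T), actions])
                    + rng.standard_normal(T) * 0.1)

        def loss():
            f = agent.forward_sequence(X, actions=actions, h0=h0, c0=c0)
            comps, _, _ = _loss_and_output_grads(
                TINY, f["values"], f["probs"], actions, old_logp, adv,
                targets)
            return comps["loss"]

        f = agent.forward_sequence(X, actions=actions, h0=h0, c0=c0)
        comps, dv, dz = _loss_and_output_grads(
            TINY, f["values"], f["probs"], actions, old_logp, adv, targets)
        grads = agent.backward_sequence(X, f, dv, dz)
        eps = 1e-6
        rng2 = np.random.default_rng(42)
        for k, p in agent.params.items():
            flat_idx = rng2.choice(p.size, size=min(p.size, 8),
                                   replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[k][idx]
                assert ana == pytest.approx(num, rel=2e-4, abs=1e-9), k


@pytest.fixture(scope="module")
def short_stream():
    task = TaskConfig(task_kind="pavlovian", n_per_type=4, seed=21)
    stream, _ = generate_pavlovian_session(task)
    return stream


class TestTraining:
    def test_zero_learning_rate_freezes_policy(self, short_stream):
        cfg = AgentConfig(T=200, seed=5, learning_rate=0.0,
                          units_per_subnet=8)
        agent, log = train_agent(cfg, short_stream, n_updates=3)
        ref = Agent(cfg)
        for k in agent.params:
            np.testing.assert_allclose(agent.params[k], ref.params[k],
                                       atol=1e-12)

    def test_deterministic_given_seed(self, short_stream):
        cfg = AgentConfig(T=200, seed=6, units_per_subnet=8)
        a1, log1 = train_agent(cfg, short_stream, n_updates=3)
        a2, log2 = train_agent(cfg, short_stream, n_updates=3)
        for k in a1.params:
            np.testing.assert_array_equal(a1.params[k], a2.params[k])
        np.testing.assert_array_equal(log1["loss"], log2["loss"])

    def test_stream_too_short_rejected(self, short_stream):
        cfg = AgentConfig(T=100_000, seed=1)
        with pytest.raises(ValueError):
            train_agent(cfg, short_stream, n_updates=10)


class TestExtractRpe:
    def test_reconstruction_identity(self, short_stream):
        cfg = AgentConfig(seed=7, units_per_subnet=8)
        agent = Agent(cfg)
        out = extract_rpe(agent, short_stream, seed=3)
        g = cfg.gammas
        recon = (out["rewards_at"][1:, None]
                 + g[None, :] * out["values"][1:] - out["values"][:-1])
        np.testing.assert_allclose(out["rpe"][1:], recon, atol=1e-12)

    def test_untrained_click_rpe_positive_all_pools(self, short_stream):
        # an unpredicted click collected by a poke drives r = ~1, which
        # dominates the small value terms of the untrained network
        cfg = AgentConfig(seed=8, units_per_subnet=8)
        agent = Agent(cfg)
        out = extract_rpe(agent, short_stream, seed=3)
        collected = np.flatnonzero(out["rewards_at"] > 0.5)
        assert len(collected) > 0
        assert np.all(out["rpe"][collected, :] > 0)

    def test_constant_value_algebra(self):
        # with r = 0 and constant V the definition gives (gamma - 1) V
        g = 0.97
        V = 0.8
        rpe = 0.0 + g * V - V
        assert rpe == pytest.approx((g - 1) * V)
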