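"""Reward shaping, network contracts, exploration, and the training loop."""

import numpy as np
import pytest

from octfocus.agent import (
    AgentConfig,
    DDPGAgent,
    ReplayBuffer,
    Transition,
    evaluate,
    explore_step,
    noise_sigma_at,
    reward_focus,
    train,
)
from octfocus.environment import SimulatedOCTEnv
from octfocus.nn import DTYPE
from octfocus.registration import ed_metric
from octfocus.preprocess import normalize_pair


class TestRewardFocus:
    def test_identical_inputs_give_zero(self):
        a = np.sin(np.linspace(0, 6, 80)) + 2
        assert reward_focus(a, a, Nb=5) == 0.0

    def test_window_absorbs_pure_roll(self):
        a = np.sin(np.linspace(0, 6, 80)) + 2
        assert reward_focus(a, np.roll(a, 4), Nb=8) == pytest.approx(0.0, abs=1e-12)

    def test_nb_zero_equals_direct_ed(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(60) + 1, rng.random(60) + 1
        pair = normalize_pair(a, b)
        direct = ed_metric(pair.ref_norm, pair.tgt_norm)
        assert reward_focus(a, b, Nb=0) == pytest.approx(direct, abs=1e-12)
        # brute force over the window confirms the minimum sits at b = 0
        assert reward_focus(a, b, Nb=6) >= direct

    def test_never_positive_and_scale_invariant(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(50) + 1, rng.random(50) + 2
        r = reward_focus(a, b, Nb=4)
        assert r <= 0
        assert reward_focus(3 * a, 3 * b, Nb=4) == pytest.approx(r, abs=1e-12)

    def test_window_tolerance_ordering(self):
        """Shifts inside the window are forgiven; shifts beyond it are
        penalized."""
        a = np.exp(-0.5 * ((np.arange(100) - 50) / 4.0) ** 2)
        inside = reward_focus(a, np.roll(a, 5), Nb=8)
        outside = reward_focus(a, np.roll(a, 20), Nb=8)
        assert inside > outside


class TestNetworks:
    def test_actor_output_bounded_and_deterministic(self, tiny_agent, params):
        rng = np.random.default_rng(2)
        obs = rng.standard_normal((8, params.n_depth_pixels))
        a1, a2 = tiny_agent.act(obs), tiny_agent.act(obs)
        assert a1 == a2
        assert -1 < a1 < 1

    def test_actor_parameter_count_matches_architecture(self):
        """Hand-computed size of the published actor for M = 4, depth 512:
        conv(8->16,k3)+conv(16->32,k3) then 126 pooled positions into the
        128-64-32-1 head."""
        cfg = AgentConfig(train_steps=1)
        agent = DDPGAgent(cfg, 512)
        n = sum(p.size for _, _, p in agent.actor.parameters())
        expected = (
            (8 * 16 * 3 + 16)
            + (16 * 32 * 3 + 32)
            + (32 * 126 * 128 + 128)
            + (128 * 64 + 64)
            + (64 * 32 + 32)
            + (32 * 1 + 1)
        )
        assert n == expected

    def test_critic_uses_action(self, tiny_agent, params):
        rng = np.random.default_rng(3)
        obs = rng.standard_normal((8, params.n_depth_pixels))
        q0 = tiny_agent.critic_value(obs, -0.5)
        q1 = tiny_agent.critic_value(obs, 0.5)
        assert np.isfinite(q0) and np.isfinite(q1)
        assert q0 != q1

    def test_critic_batch_equals_per_sample(self, tiny_agent, params):
        rng = np.random.default_rng(4)
        obs = rng.standard_normal((3, 8, params.n_depth_pixels)).astype(DTYPE)
        act = np.array([[-0.3], [0.0], [0.4]], dtype=DTYPE)
        e = tiny_agent.critic_embed(obs)
        q_batch = tiny_agent.critic_head(np.concatenate([e, act], axis=1))[:, 0]
        q_single = [tiny_agent.critic_value(obs[i], float(act[i, 0])) for i in range(3)]
        np.testing.assert_allclose(q_batch, q_single, rtol=1e-5)


class TestTransitionsAndBuffer:
    def test_transition_rejects_positive_reward(self):
        with pytest.raises(ValueError):
            Transition(observation=np.zeros((2, 4)), action=0.1, reward=0.5)

    def test_buffer_ring_overwrite_and_sampling(self):
        buf = ReplayBuffer(capacity=5)
        for i in range(8):
            buf.add(Transition(np.full((1, 2), i), action=0.0, reward=-float(i)))
        assert len(buf) == 5
        obs, act, rew = buf.sample(16, np.random.default_rng(0))
        assert obs.shape == (16, 1, 2)
        assert set(-rew[:, 0].astype(int)) <= {3, 4, 5, 6, 7}


class TestExploration:
    def test_noise_schedule_endpoints(self):
        cfg = AgentConfig(train_steps=100, noise_anneal_steps=80,
                          noise_sigma_start=0.3, noise_sigma_end=0.02)
        assert noise_sigma_at(cfg, 0) == 0.3
        assert noise_sigma_at(cfg, 40) == pytest.approx(0.16)
        assert noise_sigma_at(cfg, 80) == pytest.approx(0.02)
        assert noise_sigma_at(cfg, 99) == pytest.approx(0.02)

    def test_explore_step_counts_and_pure_action(self, tiny_agent, phantom, params):
        env = SimulatedOCTEnv(phantom, params, rng=0)
        obs = env.reset()
        rng = np.random.default_rng(1)
        ts = explore_step(env, tiny_agent, obs, noise_sigma=0.0,
                          n_noise_profiles=1, rng=rng)
        assert len(ts) == 1
        assert ts[0].action == pytest.approx(tiny_agent.act(obs.astype(DTYPE)), abs=1e-6)
        ts5 = explore_step(env, tiny_agent, obs, noise_sigma=0.2,
                           n_noise_profiles=5, rng=rng)
        assert len(ts5) == 5
        assert all(t.observation is ts5[0].observation for t in ts5)
        assert all(-1 < t.action < 1 for t in ts5)
        assert all(t.reward <= 0 for t in ts5)


class TestTrainingLoop:
    def test_critic_regresses_frozen_buffer(self, tiny_agent, params):
        """With a frozen buffer, repeated critic updates drive the MSE to
        the empirical reward regression (monotone decrease in trend)."""
        rng = np.random.default_rng(5)
        obs = rng.standard_normal((40, 8, params.n_depth_pixels)).astype(DTYPE)
        act = rng.uniform(-1, 1, (40, 1))
        rew = -np.abs(act - 0.2)  # a simple reward surface
        losses = [tiny_agent.update_critic(obs, act, rew) for _ in range(150)]
        assert np.mean(losses[-10:]) < 0.2 * np.mean(losses[:10])

    def test_short_training_is_deterministic(self, phantom, params):
        def run():
            cfg = AgentConfig.desk(train_steps=8, rng_seed=3, batch_size=8,
                                   n_noise_profiles_per_step=2, buffer_capacity=100)
            agent = DDPGAgent(cfg, params.n_depth_pixels)
            env = SimulatedOCTEnv(phantom, params, rng=21)
            curve = train(agent, env)
            return curve, agent

        c1, a1 = run()
        c2, a2 = run()
        assert c1["mean_reward"].tolist() == c2["mean_reward"].tolist()
        assert c1["critic_loss"].equals(c2["critic_loss"])
        obs = np.random.default_rng(0).standard_normal((8, params.n_depth_pixels))
        assert a1.act(obs) == a2.act(obs)

    def test_evaluate_reports_mean_abs_error(self, tiny_agent, phantom, params):
        env = SimulatedOCTEnv(phantom, params, rng=31)
        res = evaluate(tiny_agent, env, n_episodes=5)
        assert res["errors"].shape == (5,)
        assert res["mean_abs_error_D"] == pytest.approx(res["errors"].mean())
        assert 0 <= res["mean_abs_error_D"] < 1.1


class TestCheckpoint:
    def test_save_load_roundtrip(self, tiny_agent, params, tmp_path):
        path = tmp_path / "agent.npz"
        tiny_agent.save(path)
        loaded = DDPGAgent.load(path)
        assert loaded.config == tiny_agent.config
        rng = np.random.default_rng(6)
        obs = rng.standard_normal((8, params.n_depth_pixels))
        assert loaded.act(obs) == tiny_agent.act(obs)
        assert loaded.critic_value(obs, 0.3) == pytest.approx(
            tiny_agent.critic_value(obs, 0.3), rel=1e-6
        )
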