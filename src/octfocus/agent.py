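"""Single-step DDPG defocus-correction agent.

The actor is a lightweight 1D CNN that maps the (2M, depth) observation —
jointly normalized reference and target A-scan channels — to a focus
correction signal in (-1, 1) through a tanh output; the physical correction
is ``action * action_scale`` diopters.  The critic embeds the observation
through its own copy of the actor trunk into a single value, concatenates
it with the action, and estimates the immediate reward with a deep
feed-forward network.

Because a correction attempt is a single-step episode with an immediate
reward, the critic target is the reward itself (no bootstrapping; the
discount is irrelevant).  Exploration adds annealed Gaussian noise to the
actor's action; several noise profiles can be applied per episode, each
yielding its own reward, which densifies the replay buffer around the
current policy.

The reward is the sliding-window negative Euclidean distance between the
jointly standardized reference and post-correction average A-scans: the
window forgives up to ``Nb`` pixels of residual axial motion so the agent
learns focus features rather than pixel-to-pixel alignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import preprocess
from .nn import DTYPE, Adam, Conv1d, Dense, Flatten, MaxPool1d, ReLU, Sequential, Tanh, soft_update
from .preprocess import average_ascan, normalize_pair
from .registration import ed_metric

__all__ = [
    "AgentConfig",
    "Transition",
    "ReplayBuffer",
    "DDPGAgent",
    "reward_focus",
    "explore_step",
    "train",
    "evaluate",
    "noise_sigma_at",
]

#: published layer widths of the critic's deep feed-forward head
CRITIC_FC_FULL = (500, 1000, 1000, 1000, 1000, 500, 200)
#: reduced head for desk-scale CPU training runs
CRITIC_FC_DESK = (128, 128, 64)


@dataclass
class AgentConfig:
    """Hyperparameters of the focus-correction agent.

    ``action_scale`` maps the tanh output to physical diopters (1.0 D
    covers the ±0.6 D training range with headroom).  ``Nb`` is the
    sliding-window half-range of the reward in pixels.  Noise anneals
    linearly from ``noise_sigma_start`` to ``noise_sigma_end`` over
    ``noise_anneal_steps`` episodes (default: 80% of ``train_steps``).
    """

    action_scale: float = 1.0
    Nb: int = 15
    noise_sigma_start: float = 0.3
    noise_sigma_end: float = 0.02
    noise_anneal_steps: int | None = None
    n_noise_profiles_per_step: int = 4
    buffer_capacity: int = 50_000
    batch_size: int = 64
    actor_lr: float = 1e-4
    critic_lr: float = 1e-3
    soft_update_tau: float = 0.005
    train_steps: int = 3000
    updates_per_step: int = 1
    rng_seed: int = 0
    # two-phase schedule: after ``lr_decay_at`` episodes the learning rates
    # drop to the fine values, letting the policy settle near the optimum
    # while the annealed exploration noise probes its neighbourhood
    lr_decay_at: int | None = None
    fine_actor_lr: float = 1e-4
    fine_critic_lr: float = 3e-4
    # network geometry
    M: int = 4
    conv_channels: tuple = (16, 32)
    conv_kernel: int = 3
    pool_kernel: int = 2
    actor_fc: tuple = (128, 64, 32)
    critic_fc: tuple = CRITIC_FC_FULL
    # preprocessing used by predict_correction (kept here so a checkpoint
    # fully determines how observations are built)
    smoothing_sigma_obs: float = 2.0
    # evaluation protocol
    eval_every: int = 0  # 0 disables periodic evaluation
    n_eval: int = 100

    def __post_init__(self):
        if self.action_scale <= 0:
            raise ValueError("action_scale must be > 0")
        if self.Nb < 0:
            raise ValueError("Nb must be >= 0")
        if self.noise_anneal_steps is None:
            self.noise_anneal_steps = int(0.8 * self.train_steps)

    @classmethod
    def desk(cls, **overrides) -> "AgentConfig":
        """Desk-scale configuration for CPU-only runs: the published actor
        with a reduced critic head, more noise profiles per episode, and a
        shorter schedule."""
        defaults = dict(
            critic_fc=CRITIC_FC_DESK,
            train_steps=8000,
            noise_anneal_steps=3500,
            noise_sigma_end=0.015,
            lr_decay_at=5000,
            n_noise_profiles_per_step=8,
            updates_per_step=2,
            batch_size=32,
            actor_lr=5e-4,
            buffer_capacity=30_000,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class Transition:
    """One (observation, action, reward) sample of a single-step episode."""

    observation: np.ndarray
    action: float
    reward: float

    def __post_init__(self):
        if not (np.isfinite(self.action) and np.isfinite(self.reward)):
            raise ValueError("transition fields must be finite")
        if self.reward > 1e-9:
            raise ValueError("reward is a negative distance; must be <= 0")


class ReplayBuffer:
    """Ring buffer of transitions with uniform random minibatch sampling.

    Transitions from the same episode share their observation array by
    reference, so the memory cost scales with episodes, not noise
    profiles.
    """

    def __init__(self, capacity: int):
        self.capacity = capacity
        self._data: list[Transition] = []
        self._pos = 0

    def __len__(self):
        return len(self._data)

    def add(self, transition: Transition):
        if len(self._data) < self.capacity:
            self._data.append(transition)
        else:
            self._data[self._pos] = transition
            self._pos = (self._pos + 1) % self.capacity

    def extend(self, transitions):
        for t in transitions:
            self.add(t)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(0, len(self._data), size=batch_size)
        obs = np.stack([self._data[i].observation for i in idx])
        act = np.array([[self._data[i].action] for i in idx])
        rew = np.array([[self._data[i].reward] for i in idx])
        return obs, act, rew


# ---------------------------------------------------------------------------
# Reward shaping
# ---------------------------------------------------------------------------

def reward_focus(a_ref: np.ndarray, a_tgt: np.ndarray, Nb: int = 15) -> float:
    """Sliding-window similarity reward between reference and
    post-correction average A-scans.

    Both arrays are jointly standardized, the target is slid over integer
    offsets b in [-Nb, Nb], and the Euclidean distance (RMS over the
    overlap) is computed at each offset.  The reward is minus the minimum
    distance: 0 iff some offset makes the profiles identical, negative
    otherwise.
    """
    pair = normalize_pair(a_ref, a_tgt)
    ref, tgt = pair.ref_norm, pair.tgt_norm
    n = ref.size
    best = np.inf
    for b in range(-Nb, Nb + 1):
        if b >= 0:
            a, t = ref[: n - b], tgt[b:]
        else:
            a, t = ref[-b:], tgt[: n + b]
        if a.size == 0:
            continue
        best = min(best, -ed_metric(a, t))
    return -best


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def _conv_trunk_output_size(n_depth: int, cfg: AgentConfig) -> int:
    length = n_depth
    for _ in cfg.conv_channels:
        length = (length - (cfg.conv_kernel - 1)) // cfg.pool_kernel
    return length * cfg.conv_channels[-1]


def build_actor_network(
    n_depth: int, cfg: AgentConfig, rng: np.random.Generator, bounded: bool = True
) -> Sequential:
    """The published actor: two conv/pool blocks (16 then 32 channels,
    kernel 3, pool 2) over the 2M-channel observation, flattened into a
    128-64-32 ReLU chain and a tanh-bounded scalar output.

    With ``bounded=False`` the final tanh is dropped; the critic uses this
    unbounded variant for its observation embedding, where saturation
    would flatten the reward landscape at large defocus.
    """
    layers = []
    c_in = 2 * cfg.M
    for c_out in cfg.conv_channels:
        layers += [Conv1d(c_in, c_out, cfg.conv_kernel, rng), ReLU(), MaxPool1d(cfg.pool_kernel)]
        c_in = c_out
    layers.append(Flatten())
    n_in = _conv_trunk_output_size(n_depth, cfg)
    for n_out in cfg.actor_fc:
        layers += [Dense(n_in, n_out, rng), ReLU()]
        n_in = n_out
    layers.append(Dense(n_in, 1, rng, scale=1e-3))
    if bounded:
        layers.append(Tanh())
    return Sequential(layers)


def build_critic_head(cfg: AgentConfig, rng: np.random.Generator) -> Sequential:
    """Feed-forward reward estimator over (observation embedding, action)."""
    layers = []
    n_in = 2
    for n_out in cfg.critic_fc:
        layers += [Dense(n_in, n_out, rng), ReLU()]
        n_in = n_out
    layers.append(Dense(n_in, 1, rng))
    return Sequential(layers)


class DDPGAgent:
    """Actor-critic pair with target networks and seeded initialization.

    The critic's observation embedding is an independent, critic-owned copy
    of the actor architecture (its scalar output feeds the critic head
    together with the action); sharing weights with the live actor would
    entangle the actor and critic losses.
    """

    def __init__(self, config: AgentConfig, n_depth: int):
        self.config = config
        self.n_depth = n_depth
        self.rng = np.random.default_rng(config.rng_seed)
        init = np.random.default_rng(config.rng_seed + 1)
        self.actor = build_actor_network(n_depth, config, init)
        self.critic_embed = build_actor_network(n_depth, config, init, bounded=False)
        self.critic_head = build_critic_head(config, init)
        self.target_actor = build_actor_network(n_depth, config, init)
        self.target_embed = build_actor_network(n_depth, config, init, bounded=False)
        self.target_head = build_critic_head(config, init)
        self.target_actor.copy_from(self.actor)
        self.target_embed.copy_from(self.critic_embed)
        self.target_head.copy_from(self.critic_head)
        self.actor_opt = Adam(self.actor, lr=config.actor_lr)
        self._last_embed = None
        self.critic_opt = Adam([self.critic_embed, self.critic_head], lr=config.critic_lr)

    # -- inference ----------------------------------------------------------

    def act(self, observation: np.ndarray) -> float:
        """Live-actor output in (-1, 1) for one observation (the policy
        that exploration perturbs during training)."""
        out = self.actor(observation[None].astype(DTYPE))
        return float(out[0, 0])

    def policy_action(self, observation: np.ndarray) -> float:
        """Deployment policy: the Polyak-averaged (target) actor.

        The slow-moving average smooths out the step-to-step jitter of the
        live actor around the optimum, measurably reducing prediction
        error at convergence; evaluation and closed-loop correction use
        it.
        """
        out = self.target_actor(observation[None].astype(DTYPE))
        return float(out[0, 0])

    def predict_correction(self, ref_bscan, tgt_bscan_registered) -> float:
        """Focus correction in diopters for a registered reference/target
        B-scan pair (preprocess -> observation -> deployment policy ->
        scale)."""
        cfg = self.config
        obs = preprocess.build_observation(
            preprocess.subregion_channels(ref_bscan, cfg.M, cfg.smoothing_sigma_obs),
            preprocess.subregion_channels(tgt_bscan_registered, cfg.M, cfg.smoothing_sigma_obs),
        )
        return self.policy_action(obs) * cfg.action_scale

    def critic_value(self, observation: np.ndarray, action: float) -> float:
        obs = observation[None].astype(DTYPE)
        e = self.critic_embed(obs)
        action_col = np.array([[action]], dtype=DTYPE)
        q = self.critic_head(np.concatenate([e, action_col], axis=1))
        return float(q[0, 0])

    # -- learning -----------------------------------------------------------

    def update_critic(self, obs, act, rew) -> float:
        """One regression step of the critic toward the immediate rewards;
        returns the minibatch MSE."""
        obs = obs.astype(DTYPE, copy=False)
        act = act.astype(DTYPE, copy=False)
        rew = rew.astype(DTYPE, copy=False)
        e = self.critic_embed.forward(obs)
        q = self.critic_head.forward(np.concatenate([e, act], axis=1))
        err = q - rew
        loss = float(np.mean(err**2))
        dq = 2.0 * err / err.shape[0]
        dx = self.critic_head.backward(dq)
        self.critic_embed.backward(dx[:, :1])
        self.critic_opt.step()
        self._last_embed = e  # reusable by update_actor on the same batch
        return loss

    def update_actor(self, obs, embed_out: np.ndarray | None = None) -> float:
        """One ascent step of the actor through the (frozen-for-this-step)
        critic; returns the minibatch mean critic value.

        ``embed_out`` lets the caller reuse the observation embedding
        computed by a critic update on the same minibatch; the actor's
        gradient only flows through the action input, so a one-step-stale
        embedding changes nothing but the constant part of Q.
        """
        obs = obs.astype(DTYPE, copy=False)
        a = self.actor.forward(obs)
        e = embed_out if embed_out is not None else self.critic_embed.forward(obs)
        q = self.critic_head.forward(np.concatenate([e, a], axis=1))
        dq = np.full_like(q, -1.0 / q.shape[0])  # maximize mean Q
        dx = self.critic_head.backward(dq)
        self.actor.backward(dx[:, 1:])
        self.actor_opt.step()
        return float(np.mean(q))

    def soft_update_targets(self):
        tau = self.config.soft_update_tau
        soft_update(self.target_actor, self.actor, tau)
        soft_update(self.target_embed, self.critic_embed, tau)
        soft_update(self.target_head, self.critic_head, tau)

    # -- persistence ---------------------------------------------------------

    def save(self, path):
        """Versioned checkpoint: weight arrays plus the JSON-encoded
        configuration, in a single .npz archive."""
        arrays = {}
        for tag, net in self._networks().items():
            for key, arr in net.state_arrays().items():
                arrays[f"{tag}/{key}"] = arr
        cfg = asdict(self.config)
        arrays["__meta__"] = np.array(
            json.dumps({"version": 1, "n_depth": self.n_depth, "config": cfg})
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DDPGAgent":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg_dict = meta["config"]
            for key in ("conv_channels", "actor_fc", "critic_fc"):
                cfg_dict[key] = tuple(cfg_dict[key])
            agent = cls(AgentConfig(**cfg_dict), meta["n_depth"])
            for tag, net in agent._networks().items():
                state = {
                    key.split("/", 1)[1]: data[key]
                    for key in data.files
                    if key.startswith(tag + "/")
                }
                net.load_state_arrays(state)
        return agent

    def _networks(self):
        return {
            "actor": self.actor,
            "critic_embed": self.critic_embed,
            "critic_head": self.critic_head,
            "target_actor": self.target_actor,
            "target_embed": self.target_embed,
            "target_head": self.target_head,
        }


# ---------------------------------------------------------------------------
# Exploration and training
# ---------------------------------------------------------------------------

def noise_sigma_at(config: AgentConfig, step: int) -> float:
    """Linear annealing schedule of the exploration noise std."""
    n = max(config.noise_anneal_steps, 1)
    frac = min(step / n, 1.0)
    return config.noise_sigma_start + frac * (
        config.noise_sigma_end - config.noise_sigma_start
    )


def explore_step(env, agent: DDPGAgent, observation, noise_sigma, n_noise_profiles, rng):
    """Apply one actor action under ``n_noise_profiles`` Gaussian noise
    perturbations, each rendered and rewarded in the environment.

    Returns the list of transitions sharing the episode's observation.
    """
    cfg = agent.config
    observation = observation.astype(DTYPE, copy=False)
    a0 = agent.act(observation)
    ref_ascan = env.reference_ascan()
    transitions = []
    for _ in range(n_noise_profiles):
        eps = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
        a = float(np.clip(a0 + eps, -0.999, 0.999))
        frame = env.apply_correction(a * cfg.action_scale)
        r = reward_focus(ref_ascan, average_ascan(frame), cfg.Nb)
        transitions.append(Transition(observation=observation, action=a, reward=r))
    return transitions


def evaluate(agent: DDPGAgent, env, n_episodes: int = 100) -> dict:
    """Mean absolute defocus prediction error (D) over fresh episodes.

    The error of an episode is |action x action_scale - applied defocus|,
    with the action from the deployment (Polyak-averaged) policy; the
    environment's randomness drives the episode draw.
    """
    errors = np.empty(n_episodes)
    for i in range(n_episodes):
        obs = env.reset()
        pred = agent.policy_action(obs) * agent.config.action_scale
        errors[i] = abs(pred - env.applied_defocus)
    return {
        "mean_abs_error_D": float(errors.mean()),
        "max_abs_error_D": float(errors.max()),
        "errors": errors,
    }


def train(
    agent: DDPGAgent,
    env,
    n_steps: int | None = None,
    eval_env_factory=None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Run the single-step DDPG training loop.

    Per episode: reset the environment (render, motion-correct, build the
    observation), explore with annealed action noise, store all rewarded
    transitions, then take ``updates_per_step`` minibatch updates — critic
    regression to the immediate reward followed by actor ascent through the
    critic — and soft-update the target networks.

    ``eval_env_factory``, when given, must return a freshly seeded
    environment; it is called at each evaluation point so the held-out
    episode set is identical along the learning curve.

    Returns the learning-curve trace (step, noise sigma, critic loss, mean
    reward, and evaluation error where measured).  Raises on non-finite
    losses (divergence).
    """
    cfg = agent.config
    steps = cfg.train_steps if n_steps is None else n_steps
    buffer = ReplayBuffer(cfg.buffer_capacity)
    rng = agent.rng
    rows = []
    for step in range(steps):
        if cfg.lr_decay_at is not None and step == cfg.lr_decay_at:
            agent.actor_opt.lr = cfg.fine_actor_lr
            agent.critic_opt.lr = cfg.fine_critic_lr
        obs = env.reset()
        sigma = noise_sigma_at(cfg, step)
        transitions = explore_step(
            env, agent, obs, sigma, cfg.n_noise_profiles_per_step, rng
        )
        buffer.extend(transitions)
        critic_loss = np.nan
        if len(buffer) >= cfg.batch_size:
            for _ in range(cfg.updates_per_step):
                b_obs, b_act, b_rew = buffer.sample(cfg.batch_size, rng)
                b_obs = b_obs.astype(DTYPE, copy=False)
                critic_loss = agent.update_critic(b_obs, b_act, b_rew)
                agent.update_actor(b_obs, embed_out=agent._last_embed)
                agent.soft_update_targets()
            if not np.isfinite(critic_loss):
                raise RuntimeError(
                    f"training diverged at step {step}: critic loss {critic_loss}"
                )
        row = {
            "step": step,
            "noise_sigma": sigma,
            "critic_loss": critic_loss,
            "mean_reward": float(np.mean([t.reward for t in transitions])),
            "mean_abs_error_D": np.nan,
        }
        if cfg.eval_every and (step + 1) % cfg.eval_every == 0 and eval_env_factory:
            result = evaluate(agent, eval_env_factory(), n_episodes=min(cfg.n_eval, 20))
            row["mean_abs_error_D"] = result["mean_abs_error_D"]
            if verbose:
                print(
                    f"step {step + 1}: sigma={sigma:.3f} "
                    f"eval |error|={result['mean_abs_error_D']:.4f} D",
                    flush=True,
                )
        rows.append(row)
    return pd.DataFrame(rows)
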