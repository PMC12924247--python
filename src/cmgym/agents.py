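"""Deep Q-learning agents for the two migration hypotheses.

The gradient-driven hypothesis uses a single-level DQN whose policy
network is a small CNN — two convolutional layers and a fully-connected
layer — mapping the 2-channel observation to the 8 action values, trained
with Adam (beta1 0.9, beta2 0.999, lr 1e-4), batch 64, a target network
synced every 1000 gradient steps and a greedy factor (probability of the
argmax action) scheduled linearly from 0.3 to 0.95 over the epochs.

The collective-behavior hypothesis uses a two-level hierarchical DQN: a
meta-controller (fully connected, hidden layers 512/1024/1024) picks a
subgoal pair from the secondary neighbors based on the migrating cell's
current position; the controller shares the CNN shape above and learns
primitive moves toward the subgoal/destination on intrinsic rewards of
+10 per achieved subgoal and +100 at the destination (batch 32, greedy
factor 0.8 -> 0.95).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np

from cmgym.errors import ConfigurationError
from cmgym.nn import Adam, Conv2d, Flatten, Linear, ReLU, Sequential
from cmgym.rendering import Observation
from cmgym.rewards import RewardBreakdown


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class DQNConfig:
    n_actions: int = 8
    conv_channels: tuple[int, int] = (16, 32)
    conv_kernels: tuple[int, int] = (8, 4)
    conv_strides: tuple[int, int] = (4, 2)
    fc_units: int = 256
    mlp_hidden: tuple[int, ...] = (64, 64)  # for vector observations
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 64
    target_update_every: int = 1000
    epochs: int = 900
    greedy_start: float = 0.3
    greedy_end: float = 0.95
    gamma: float = 0.99
    replay_capacity: int = 100_000
    #: training-side reward normalization (TD targets only); the classic
    #: DQN recipe clips/rescales rewards so rare large penalties do not
    #: dominate the squared loss.  Environment rewards are untouched.
    reward_scale: float = 1.0
    #: gradient updates per environment step
    updates_per_step: int = 1
    #: Huber-loss transition point; rare -1000 overlap penalties produce
    #: huge TD errors, and the classic DQN recipe bounds their gradient
    huber_delta: float = 1.0
    #: double-DQN target (online argmax, target evaluation)
    double_dqn: bool = True
    #: n-step TD returns (1 = classic one-step target)
    n_step: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.greedy_start <= self.greedy_end <= 1:
            raise ConfigurationError("need 0 <= greedy_start <= greedy_end <= 1")


@dataclass
class HDQNConfig:
    meta_hidden: tuple[int, int, int] = (512, 1024, 1024)
    meta_learning_rate: float = 1e-4
    meta_gamma: float = 0.99
    controller: DQNConfig = field(default_factory=lambda: DQNConfig(
        batch_size=32, greedy_start=0.8, greedy_end=0.95))
    controller_horizon: int = 25  # steps before the meta re-selects a subgoal
    epochs: int = 900
    seed: int = 0


# ---------------------------------------------------------------------------
# replay / policies / schedules
# ---------------------------------------------------------------------------


class ReplayBuffer:
    """FIFO transition store with uniform sampling."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self._data: list = []
        self._pos = 0

    def push(self, obs, action, reward, next_obs, done) -> None:
        item = (obs, action, reward, next_obs, done)
        if len(self._data) < self.capacity:
            self._data.append(item)
        else:
            self._data[self._pos] = item
        self._pos = (self._pos + 1) % self.capacity

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(len(self._data), size=batch_size)
        obs, act, rew, nxt, done = zip(*(self._data[int(i)] for i in idx))
        return (np.stack(obs), np.asarray(act), np.asarray(rew, float),
                np.stack(nxt), np.asarray(done, float))

    def __len__(self):
        return len(self._data)


def _as_array(obs) -> np.ndarray:
    if isinstance(obs, Observation):
        return obs.stack.astype(np.float32)
    return np.asarray(obs, dtype=np.float32)


def _reward_value(r) -> float:
    if isinstance(r, RewardBreakdown):
        return r.total
    return float(r)


class QPolicy:
    """Action-value network with greedy and epsilon-greedy action selection."""

    def __init__(self, net: Sequential, n_actions: int, obs_offset: float = 0.0):
        self.net = net
        self.n_actions = n_actions
        # image observations live in [0, 1]; centering them conditions the
        # first layer (the depth background would otherwise bias every unit)
        self.obs_offset = obs_offset

    def q_values(self, obs_batch: np.ndarray) -> np.ndarray:
        return self.net.forward(obs_batch.astype(np.float64) - self.obs_offset)

    def act(self, obs) -> int:
        q = self.q_values(_as_array(obs)[None])
        return int(np.argmax(q[0]))

    def act_epsilon(self, obs, greedy_factor: float, rng: np.random.Generator) -> int:
        if rng.uniform() < greedy_factor:
            return self.act(obs)
        return int(rng.integers(self.n_actions))

    def clone(self) -> "QPolicy":
        import copy
        twin = copy.deepcopy(self)
        return twin

    def save(self, path: str, extra: dict | None = None) -> str:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "weights": self.net.get_weights(),
                         "n_actions": self.n_actions, "extra": extra or {}}, fh)
        return path


def build_policy_network(input_shape, n_actions: int = 8,
                         config: DQNConfig | None = None, seed: int = 0) -> QPolicy:
    """Build the policy network for image (2xHxW) or vector observations."""
    config = config or DQNConfig(n_actions=n_actions)
    rng = np.random.default_rng(seed)
    input_shape = tuple(input_shape)
    if len(input_shape) == 3:
        c, h, w = input_shape
        if c != 2:
            raise ValueError(f"expected a 2-channel observation, got {c} channels")
        if h < 8 or w < 8:
            raise ValueError("observation must be at least 8x8")
        layers: list = []
        ch_in = c
        for ch_out, k, s in zip(config.conv_channels, config.conv_kernels,
                                config.conv_strides):
            layers += [Conv2d(ch_in, ch_out, k, s, rng), ReLU()]
            h = (h - k) // s + 1
            w = (w - k) // s + 1
            ch_in = ch_out
        layers += [Flatten(), Linear(ch_in * h * w, config.fc_units, rng), ReLU(),
                   Linear(config.fc_units, n_actions, rng)]
    elif len(input_shape) == 1:
        layers = []
        n_in = input_shape[0]
        for n_h in config.mlp_hidden:
            layers += [Linear(n_in, n_h, rng), ReLU()]
            n_in = n_h
        layers += [Linear(n_in, n_actions, rng)]
    else:
        raise ValueError(f"unsupported observation shape {input_shape}")
    offset = 0.5 if len(input_shape) == 3 else 0.0
    return QPolicy(Sequential(layers), n_actions, obs_offset=offset)


def greedy_schedule(epoch: int, total_epochs: int, start: float = 0.3,
                    end: float = 0.95) -> float:
    """Linear schedule of the greedy (exploitation) probability."""
    if not 0 <= epoch <= total_epochs:
        raise ValueError("epoch must be in [0, total_epochs]")
    if total_epochs == 0:
        return end
    return start + (end - start) * epoch / total_epochs


# ---------------------------------------------------------------------------
# DQN training
# ---------------------------------------------------------------------------


class _DQNLearner:
    """Online/target network pair with TD updates on replayed batches."""

    def __init__(self, input_shape, config: DQNConfig):
        self.config = config
        self.policy = build_policy_network(input_shape, config.n_actions,
                                           config, seed=config.seed)
        self.target = build_policy_network(input_shape, config.n_actions,
                                           config, seed=config.seed)
        self.target.net.set_weights(self.policy.net.get_weights())
        self.optimizer = Adam(self.policy.net, lr=config.learning_rate,
                              beta1=config.adam_beta1, beta2=config.adam_beta2)
        self.buffer = ReplayBuffer(config.replay_capacity)
        self.updates = 0

    def update(self, rng: np.random.Generator) -> float | None:
        cfg = self.config
        if len(self.buffer) < cfg.batch_size:
            return None
        obs, act, rew, nxt, done = self.buffer.sample(cfg.batch_size, rng)
        q_next_target = self.target.q_values(nxt)
        if cfg.double_dqn:
            a_star = self.policy.q_values(nxt).argmax(axis=1)
            q_next = q_next_target[np.arange(len(a_star)), a_star]
        else:
            q_next = q_next_target.max(axis=1)
        y = rew + cfg.gamma ** cfg.n_step * (1.0 - done) * q_next
        q = self.policy.q_values(obs)
        td = q[np.arange(len(act)), act] - y
        # Huber gradient: linear tails bound the influence of outlier errors
        dloss = np.clip(td, -cfg.huber_delta, cfg.huber_delta)
        grad = np.zeros_like(q)
        grad[np.arange(len(act)), act] = 2.0 * dloss / len(act)
        self.policy.net.backward(grad)
        self.optimizer.step()
        self.updates += 1
        if self.updates % cfg.target_update_every == 0:
            self.target.net.set_weights(self.policy.net.get_weights())
        return float(np.mean(td ** 2))


class _NStepComposer:
    """Rolls single-step transitions into n-step ones within an episode."""

    def __init__(self, n: int, gamma: float, buffer: ReplayBuffer):
        self.n, self.gamma, self.buffer = n, gamma, buffer
        self.window: list = []

    def push(self, obs, action, reward, next_obs, done) -> None:
        self.window.append([obs, action, reward, next_obs, done])
        for k, item in enumerate(self.window[:-1]):
            item[2] += self.gamma ** (len(self.window) - 1 - k) * reward
        if len(self.window) == self.n:
            o, a, r, _, _ = self.window.pop(0)
            self.buffer.push(o, a, r, next_obs, done)
        if done:
            self.flush(next_obs)

    def flush(self, final_obs) -> None:
        for o, a, r, _, _ in self.window:
            self.buffer.push(o, a, r, final_obs, True)
        self.window = []


def train_dqn(env, config: DQNConfig | None = None):
    """Train a DQN policy under the gradient hypothesis.

    Returns (policy, learning_curve) with one entry of episode return per
    epoch (an epoch is one episode rollout plus its gradient updates).
    """
    if getattr(env, "hypothesis", "gradient") != "gradient":
        raise ConfigurationError("train_dqn expects an environment with the gradient hypothesis")
    config = config or DQNConfig()
    rng = np.random.default_rng(config.seed)
    obs0 = _as_array(env.reset())
    learner = _DQNLearner(obs0.shape, config)
    curve = []
    for epoch in range(config.epochs):
        greedy = greedy_schedule(epoch, max(config.epochs - 1, 1),
                                 config.greedy_start, config.greedy_end)
        obs = _as_array(env.reset())
        composer = _NStepComposer(config.n_step, config.gamma, learner.buffer)
        done, ep_return = False, 0.0
        while not done:
            a = learner.policy.act_epsilon(obs, greedy, rng)
            res = env.step(a)
            r = _reward_value(res.reward)
            nxt = _as_array(res.observation)
            composer.push(obs, a, r * config.reward_scale, nxt, res.done)
            for _ in range(config.updates_per_step):
                learner.update(rng)
            obs, done = nxt, res.done
            ep_return += r
        curve.append(ep_return)
    return learner.policy, curve


# ---------------------------------------------------------------------------
# hierarchical DQN
# ---------------------------------------------------------------------------


def _meta_features(env, pair: tuple[str, str]) -> np.ndarray:
    """Meta-controller input: migrating position, candidate pair positions
    and the distance to target, scaled by the scene half-extent."""
    t = env._table
    scale = max(float(env.camera.extent or 1.0), 1.0)

    def pos(name):
        return t.loc[t["name"] == name, ["x", "y", "z"]].to_numpy(float)[0] / scale

    mig = pos(env.migrating)
    a, b = pos(pair[0]), pos(pair[1])
    d = env.distance_to_target() / scale
    return np.concatenate([mig, a, b, [d]])


def meta_select_subgoal(state_features_fn, candidates, meta_policy,
                        greedy_factor: float, rng: np.random.Generator):
    """Epsilon-greedy subgoal choice over candidate pairs.

    ``state_features_fn`` maps a candidate pair to its feature vector.
    Returns (pair, features).  Empty candidate lists are the caller's
    fallback case (the final target becomes the goal).
    """
    if not candidates:
        raise ValueError("meta_select_subgoal needs a non-empty candidate list")
    feats = np.stack([state_features_fn(c) for c in candidates])
    if rng.uniform() < greedy_factor:
        q = meta_policy.net.forward(feats)[:, 0]
        k = int(np.argmax(q))
    else:
        k = int(rng.integers(len(candidates)))
    return candidates[k], feats[k]


def _build_meta_net(n_features: int, hidden, lr: float, seed: int):
    rng = np.random.default_rng(seed)
    layers: list = []
    n_in = n_features
    for n_h in hidden:
        layers += [Linear(n_in, n_h, rng), ReLU()]
        n_in = n_h
    layers += [Linear(n_in, 1, rng)]
    net = Sequential(layers)
    return QPolicy(net, 1), Adam(net, lr=lr)


def train_hdqn(env, config: HDQNConfig | None = None):
    """Train the two-level hierarchical DQN under the subgoal hypothesis.

    Returns (meta_policy, controller_policy, learning_curve).
    """
    if getattr(env, "hypothesis", None) != "subgoal":
        raise ConfigurationError("train_hdqn expects an environment with the subgoal hypothesis")
    config = config or HDQNConfig()
    ctrl_cfg = replace(config.controller, epochs=config.epochs, seed=config.seed)
    rng = np.random.default_rng(config.seed)

    obs0 = _as_array(env.reset())
    learner = _DQNLearner(obs0.shape, ctrl_cfg)
    n_feat = 10  # 3 (migrating) + 3 + 3 (pair) + 1 (distance)
    meta_policy, meta_opt = _build_meta_net(
        n_feat, config.meta_hidden, config.meta_learning_rate, config.seed + 1)
    meta_replay: list = []
    curve = []

    for epoch in range(config.epochs):
        greedy = greedy_schedule(epoch, max(config.epochs - 1, 1),
                                 ctrl_cfg.greedy_start, ctrl_cfg.greedy_end)
        obs = _as_array(env.reset())
        done, ep_return = False, 0.0
        while not done:
            candidates = env.secondary_neighbor_pairs()
            if candidates:
                pair, feat = meta_select_subgoal(
                    lambda c: _meta_features(env, c), candidates,
                    meta_policy, greedy, rng)
                env.set_subgoal(pair)
            else:
                # final-leg fallback: pursue the destination directly
                pair, feat = None, None
                env.active_subgoal = None
            option_return, steps_in_option = 0.0, 0
            while not done and steps_in_option < config.controller_horizon:
                a = learner.policy.act_epsilon(obs, greedy, rng)
                res = env.step(a)
                r = _reward_value(res.reward)
                nxt = _as_array(res.observation)
                learner.buffer.push(obs, a, r, nxt, res.done)
                learner.update(rng)
                obs, done = nxt, res.done
                option_return += r
                ep_return += r
                steps_in_option += 1
                if res.info.get("subgoal_achieved"):
                    break
            if feat is not None:
                nxt_candidates = [] if done else env.secondary_neighbor_pairs()
                nxt_feats = (np.stack([_meta_features(env, c) for c in nxt_candidates])
                             if nxt_candidates else None)
                meta_replay.append((feat, option_return, nxt_feats, done))
                _meta_update(meta_policy, meta_opt, meta_replay, config, rng)
        curve.append(ep_return)
    return meta_policy, learner.policy, curve


def _meta_update(meta_policy, meta_opt, replay, config: HDQNConfig,
                 rng: np.random.Generator, batch: int = 32):
    if len(replay) < batch:
        return
    idx = rng.integers(len(replay), size=batch)
    feats, targets = [], []
    for i in idx:
        feat, ret, nxt_feats, done = replay[int(i)]
        y = ret
        if not done and nxt_feats is not None:
            y += config.meta_gamma * float(meta_policy.net.forward(nxt_feats)[:, 0].max())
        feats.append(feat)
        targets.append(y)
    X = np.stack(feats)
    y = np.asarray(targets)
    q = meta_policy.net.forward(X)[:, 0]
    grad = (2.0 * (q - y) / batch)[:, None]
    meta_policy.net.backward(grad)
    meta_opt.step()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EpisodeTrace:
    """Per-timestep record of one evaluation episode."""

    positions: np.ndarray       # (T, 3)
    actions: list
    rewards: list
    distances: np.ndarray       # (T,) distance to target after each step
    success: bool               # destination reward paid


@dataclass
class EnsembleResult:
    runs: list
    mean_distance_curve: np.ndarray
    sd_band: np.ndarray

    @property
    def success_rate(self) -> float:
        return float(np.mean([r.success for r in self.runs]))


def run_episode(env, policy, meta_policy=None, horizon: int = 25) -> EpisodeTrace:
    """One greedy episode; with a meta policy, subgoals are re-selected
    greedily on achievement or after ``horizon`` controller steps."""
    obs = env.reset()
    rng = np.random.default_rng(env.seed)
    positions, actions, rewards, distances = [], [], [], []
    done = False
    steps_in_option = horizon  # force an initial selection
    while not done:
        if meta_policy is not None and steps_in_option >= horizon:
            candidates = env.secondary_neighbor_pairs()
            if candidates:
                pair, _ = meta_select_subgoal(
                    lambda c: _meta_features(env, c), candidates,
                    meta_policy, 1.0, rng)
                env.set_subgoal(pair)
            else:
                env.active_subgoal = None
            steps_in_option = 0
        a = policy.act(obs)
        res = env.step(a)
        obs, done = res.observation, res.done
        positions.append(res.info["position"])
        actions.append(a)
        rewards.append(_reward_value(res.reward))
        distances.append(res.info["distance_to_target"])
        steps_in_option += 1
        if meta_policy is not None and res.info.get("subgoal_achieved"):
            steps_in_option = horizon
    return EpisodeTrace(
        positions=np.asarray(positions), actions=actions, rewards=rewards,
        distances=np.asarray(distances), success=env.destination_paid,
    )


def evaluate_policy(env, policy, meta_policy=None, n_runs: int = 5,
                    seeds=None) -> EnsembleResult:
    """Run greedy evaluation episodes and band their distance curves.

    Curves of unequal length are aligned on the episode step and padded
    with their final value before the mean and the ±1 sd band are taken.
    """
    if seeds is None:
        seeds = [env.seed + 1000 + k for k in range(n_runs)]
    runs = []
    base_seed = env.seed
    for s in seeds[:n_runs]:
        env.seed = s
        runs.append(run_episode(env, policy, meta_policy))
    env.seed = base_seed
    env.reset()
    t_max = max(len(r.distances) for r in runs)
    padded = np.stack([
        np.concatenate([r.distances, np.full(t_max - len(r.distances),
                                             r.distances[-1])])
        for r in runs
    ])
    return EnsembleResult(
        runs=runs,
        mean_distance_curve=padded.mean(axis=0),
        sd_band=padded.std(axis=0, ddof=0),
    )
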