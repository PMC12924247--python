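import numpy as np
import pytest

from cmgym.agents import (
    DQNConfig,
    ReplayBuffer,
    build_policy_network,
    evaluate_policy,
    greedy_schedule,
    meta_select_subgoal,
    train_dqn,
)
from cmgym.errors import ConfigurationError
from cmgym.nn import Conv2d, Flatten, Linear, ReLU, Sequential


class ChainEnv:
    """Deterministic 5-state chain MDP with one-hot observations.

    Action 1 moves right (terminal +10 at the end), action 0 moves left;
    every non-terminal step costs -1.  The optimal policy always moves
    right, which value iteration certifies exactly.
    """

    hypothesis = "gradient"

    def __init__(self, n=5):
        self.n = n
        self.seed = 0

    def reset(self):
        self.s, self.t = 0, 0
        return self._obs()

    def _obs(self):
        o = np.zeros(self.n)
        o[self.s] = 1.0
        return o

    def step(self, a):
        self.t += 1
        self.s = min(self.s + 1, self.n - 1) if a == 1 else max(self.s - 1, 0)
        reward = 10.0 if self.s == self.n - 1 else -1.0
        done = self.s == self.n - 1 or self.t >= 20

        class R:
            pass

        res = R()
        res.observation, res.reward, res.done, res.info = self._obs(), reward, done, {}
        return res

    def value_iteration_policy(self, gamma=0.9):
        v = np.zeros(self.n)
        for _ in range(200):
            nv = v.copy()
            for s in range(self.n - 1):
                q = []
                for a, s2 in ((0, max(s - 1, 0)), (1, min(s + 1, self.n - 1))):
                    r = 10.0 if s2 == self.n - 1 else -1.0
                    q.append(r + gamma * (0 if s2 == self.n - 1 else v[s2]))
                nv[s] = max(q)
            v = nv
        policy = []
        for s in range(self.n - 1):
            q = []
            for a, s2 in ((0, max(s - 1, 0)), (1, min(s + 1, self.n - 1))):
                r = 10.0 if s2 == self.n - 1 else -1.0
                q.append(r + gamma * (0 if s2 == self.n - 1 else v[s2]))
            policy.append(int(np.argmax(q)))
        return policy


class TestPolicyNetwork:
    def test_image_head_maps_to_8_actions(self):
        pol = build_policy_network((2, 64, 64), 8, seed=0)
        q = pol.q_values(np.zeros((1, 2, 64, 64)))
        assert q.shape == (1, 8)

    def test_smaller_images_supported(self):
        pol = build_policy_network((2, 32, 32), 8, seed=0)
        assert pol.q_values(np.zeros((1, 2, 32, 32))).shape == (1, 8)

    def test_seeded_builds_identical(self):
        x = np.random.default_rng(0).uniform(size=(1, 2, 32, 32))
        q1 = build_policy_network((2, 32, 32), 8, seed=3).q_values(x)
        q2 = build_policy_network((2, 32, 32), 8, seed=3).q_values(x)
        assert np.array_equal(q1, q2)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            build_policy_network((3, 64, 64), 8)

    def test_parameter_count_reported(self):
        pol = build_policy_network((2, 32, 32), 8, seed=0)
        assert pol.net.n_parameters() > 0


class TestNumericalGradients:
    def test_conv_net_backward_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = Sequential([
            Conv2d(2, 3, 4, 2, rng), ReLU(), Conv2d(3, 4, 3, 1, rng), ReLU(),
            Flatten(), Linear(4 * 3 * 3, 5, rng),
        ])
        x = rng.normal(size=(2, 2, 12, 12))
        tgt = rng.normal(size=(2, 5))
        out = net.forward(x)
        net.backward(2 * (out - tgt))
        analytic = [g.copy() for g in net.grads]

        def loss():
            return float(((net.forward(x) - tgt) ** 2).sum())

        eps = 1e-6
        for pi, p in enumerate(net.params):
            flat = p.ravel()
            for idx in rng.integers(flat.size, size=5):
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(analytic[pi].ravel()[idx], rel=1e-4, abs=1e-7)


class TestSchedulesAndReplay:
    @pytest.mark.parametrize("epoch,expected", [(0, 0.3), (100, 0.95), (50, 0.625)])
    def test_linear_greedy_schedule(self, epoch, expected):
        assert greedy_schedule(epoch, 100, 0.3, 0.95) == pytest.approx(expected)

    def test_default_batch_size_is_64(self):
        assert DQNConfig().batch_size == 64

    def test_replay_fifo_and_sampling(self):
        buf = ReplayBuffer(capacity=5)
        for k in range(8):
            buf.push(np.array([k]), 0, float(k), np.array([k + 1]), False)
        assert len(buf) == 5
        obs, act, rew, nxt, done = buf.sample(64, np.random.default_rng(0))
        assert len(act) == 64
        assert rew.min() >= 3.0  # the oldest transitions were evicted

    def test_controller_defaults(self):
        from cmgym.agents import HDQNConfig
        cfg = HDQNConfig()
        assert cfg.controller.batch_size == 32
        assert cfg.controller.greedy_start == pytest.approx(0.8)
        assert cfg.meta_hidden == (512, 1024, 1024)


class TestDQNOnChainMDP:
    def test_matches_value_iteration(self):
        """Learned greedy policy equals the value-iteration optimum."""
        env = ChainEnv()
        cfg = DQNConfig(n_actions=2, mlp_hidden=(32, 32), learning_rate=1e-3,
                        batch_size=32, target_update_every=100, epochs=60,
                        gamma=0.9, seed=0)
        policy, curve = train_dqn(env, cfg)
        assert len(curve) == 60
        learned = [policy.act(np.eye(env.n)[s]) for s in range(env.n - 1)]
        assert learned == env.value_iteration_policy(gamma=0.9)

    def test_target_network_only_changes_at_sync(self):
        from cmgym.agents import _DQNLearner
        cfg = DQNConfig(n_actions=2, mlp_hidden=(8,), batch_size=4,
                        target_update_every=10, seed=0)
        learner = _DQNLearner((3,), cfg)
        rng = np.random.default_rng(0)
        for k in range(6):
            learner.buffer.push(np.ones(3) * k, k % 2, 1.0, np.ones(3), False)
        w_target = [w.copy() for w in learner.target.net.get_weights()]
        w_online = [w.copy() for w in learner.policy.net.get_weights()]
        learner.update(rng)  # update 1 of 10: no sync yet
        assert all(np.array_equal(a, b) for a, b in
                   zip(w_target, learner.target.net.get_weights()))
        assert not all(np.array_equal(a, b) for a, b in
                       zip(w_online, learner.policy.net.get_weights()))

    def test_hypothesis_mismatch_rejected(self, corridor_series):
        from cmgym import create
        env = create(corridor_series, "Cpaaa", "ABarpaapp", hypothesis="subgoal")
        with pytest.raises(ConfigurationError):
            train_dqn(env, DQNConfig(epochs=1))


class TestMetaSelection:
    @staticmethod
    def _policy(seed=0):
        from cmgym.agents import _build_meta_net
        return _build_meta_net(4, (8,), 1e-3, seed)[0]

    def test_single_candidate_always_chosen(self):
        pol = self._policy()
        rng = np.random.default_rng(0)
        pair, feat = meta_select_subgoal(lambda c: np.zeros(4), [("a", "b")], pol, 0.0, rng)
        assert pair == ("a", "b")

    def test_fully_greedy_takes_argmax(self):
        pol = self._policy()
        cands = [("a", "b"), ("c", "d"), ("e", "f")]
        feats = {c: np.full(4, i, float) for i, c in enumerate(cands)}
        q = pol.net.forward(np.stack([feats[c] for c in cands]))[:, 0]
        rng = np.random.default_rng(0)
        pair, _ = meta_select_subgoal(lambda c: feats[c], cands, pol, 1.0, rng)
        assert pair == cands[int(np.argmax(q))]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            meta_select_subgoal(lambda c: np.zeros(4), [], self._policy(), 1.0,
                                np.random.default_rng(0))

    def test_features_include_migrating_position(self, corridor_series):
        from cmgym import create
        from cmgym.agents import _meta_features
        env = create(corridor_series, "Cpaaa", "ABarpaapp", hypothesis="subgoal")
        env.reset()
        pair = env.secondary_neighbor_pairs()[0]
        feat = _meta_features(env, pair)
        scale = env.camera.extent
        assert np.allclose(feat[:3] * scale, env._mig_pos)


class TestEvaluation:
    @staticmethod
    def _scripted_policy():
        class P:
            def act(self, obs):
                return 0
        return P()

    def test_five_runs_five_traces(self, corridor_series):
        from cmgym import create
        env = create(corridor_series, "Cpaaa", "ABarpaapp", seed=0)
        res = evaluate_policy(env, self._scripted_policy(), n_runs=5)
        assert len(res.runs) == 5

    def test_same_seed_runs_have_zero_sd(self, corridor_series):
        from cmgym import create
        env = create(corridor_series, "Cpaaa", "ABarpaapp", seed=0)
        res = evaluate_policy(env, self._scripted_policy(), n_runs=3, seeds=[7, 7, 7])
        assert np.allclose(res.sd_band, 0.0)

    def test_mean_curve_spans_episode(self, corridor_series):
        from cmgym import create
        env = create(corridor_series, "Cpaaa", "ABarpaapp", seed=0)
        res = evaluate_policy(env, self._scripted_policy(), n_runs=2)
        assert len(res.mean_distance_curve) == max(len(r.distances) for r in res.runs)
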