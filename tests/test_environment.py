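import numpy as np
import pytest

from cmgym import create
from cmgym.environment import SpeedModel, sample_step_size
from cmgym.errors import ConfigurationError, EpisodeStateError
from cmgym.rewards import RewardConfig


@pytest.fixture
def env(corridor_series):
    return create(corridor_series, "Cpaaa", "ABarpaapp", hypothesis="gradient", seed=0)


@pytest.fixture
def subgoal_env(corridor_series):
    return create(corridor_series, "Cpaaa", "ABarpaapp", hypothesis="subgoal", seed=0)


class TestCreate:
    def test_budget_is_90_percent_of_window(self, corridor_series, env):
        window_steps = corridor_series.n_frames - 1
        assert env.budget_steps == int(np.floor(0.9 * window_steps))

    def test_v_avg_from_initial_distance(self, corridor_series, env):
        ft = corridor_series.frame_table(0)
        p = ft[ft.name == "Cpaaa"][["x", "y", "z"]].to_numpy(float)[0]
        q = ft[ft.name == "ABarpaapp"][["x", "y", "z"]].to_numpy(float)[0]
        d0 = np.linalg.norm(p - q)
        assert env.speed.v_avg == pytest.approx(d0 / (corridor_series.n_frames - 1))

    def test_missing_cell_rejected(self, corridor_series):
        with pytest.raises(ValueError):
            create(corridor_series, "Nope", "ABarpaapp")

    def test_bad_hypothesis_rejected(self, corridor_series):
        with pytest.raises(ConfigurationError):
            create(corridor_series, "Cpaaa", "ABarpaapp", hypothesis="magic")


class TestReset:
    def test_observation_shape_default_64(self, env):
        assert env.reset().shape == (2, 64, 64)

    def test_two_resets_identical(self, env):
        a, b = env.reset(), env.reset()
        assert np.array_equal(a.stack, b.stack)

    def test_reset_after_partial_episode_restores_state(self, env):
        env.reset()
        s0 = env.get_state()
        for a in (0, 1, 2):
            env.step(a)
        env.reset()
        s1 = env.get_state()
        assert s1.frame_index == s0.frame_index and s1.steps_elapsed == 0
        assert s1.cell_table.equals(s0.cell_table)


class TestStepSize:
    def test_samples_bounded_within_20_percent(self):
        rng = np.random.default_rng(0)
        sm = SpeedModel(v_avg=2.0, noise_halfwidth=0.2)
        draws = np.array([sample_step_size(sm, rng) for _ in range(2000)])
        assert draws.min() >= 0.8 * 2.0 and draws.max() <= 1.2 * 2.0

    def test_mean_within_1_percent(self):
        rng = np.random.default_rng(1)
        sm = SpeedModel(v_avg=2.0)
        draws = [sample_step_size(sm, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(2.0, rel=0.01)

    def test_zero_halfwidth_degenerate(self):
        rng = np.random.default_rng(0)
        assert sample_step_size(SpeedModel(2.0, 0.0), rng) == 2.0


class TestStep:
    def test_action_space_has_8_directions(self, env):
        assert env.action_space.n == 8

    def test_zero_noise_step_toward_inplane_target(self, corridor_series):
        env = create(corridor_series, "Cpaaa", "ABarpaapp",
                     speed_noise_halfwidth=0.0, seed=0)
        env.reset()
        d0 = env.distance_to_target()
        res = env.step(0)  # +x, straight down the corridor
        # target jitters by <= ~jitter_sd per frame on top of the step
        assert res.info["distance_to_target"] == pytest.approx(
            d0 - env.speed.v_avg, abs=0.8)

    def test_stability_pays_100_and_finishes(self, corridor_series):
        env = create(corridor_series, "Cpaaa", "ABarpaapp", seed=0)
        env.reset()
        paid = None
        done = False
        while not done:
            res = env.step(0)
            done = res.done
            if res.reward.r_destination:
                paid = res.reward.r_destination
        assert paid == 100.0 and env.destination_paid

    def test_budget_exhaustion_without_stability(self, corridor_series):
        env = create(corridor_series, "Cpaaa", "ABarpaapp", seed=0)
        env.reset()
        done, total_dest = False, 0.0
        while not done:
            res = env.step(4)  # walk away from the target
            total_dest += res.reward.r_destination
            done = res.done
        assert total_dest == 0.0
        assert env.steps_elapsed == env.budget_steps

    def test_step_after_done_rejected(self, corridor_series):
        env = create(corridor_series, "Cpaaa", "ABarpaapp", seed=0)
        env.reset()
        while not env.step(4).done:
            pass
        with pytest.raises(EpisodeStateError):
            env.step(0)

    def test_invalid_action_rejected(self, env):
        env.reset()
        with pytest.raises(ValueError):
            env.step(8)

    def test_environment_cells_replay_series_exactly(self, corridor_series, env):
        env.reset()
        env.step(3)
        state = env.get_state()
        replay = corridor_series.frame_table(state.frame_index)
        for name in replay.name:
            if name == "Cpaaa":
                continue
            a = state.cell_table[state.cell_table.name == name][["x", "y", "z"]]
            b = replay[replay.name == name][["x", "y", "z"]]
            assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_bit_reproducible_given_seed_and_actions(self, corridor_series):
        actions = [0, 1, 0, 7, 0, 0, 2, 0]
        outs = []
        for _ in range(2):
            env = create(corridor_series, "Cpaaa", "ABarpaapp", seed=5)
            env.reset()
            outs.append([env.step(a) for a in actions])
        for r1, r2 in zip(*outs):
            assert np.array_equal(r1.observation.stack, r2.observation.stack)
            assert r1.reward.total == r2.reward.total

    def test_distance_info_matches_recomputation(self, env):
        env.reset()
        res = env.step(0)
        state = env.get_state()
        t = state.cell_table
        p = t[t.name == "Cpaaa"][["x", "y", "z"]].to_numpy(float)[0]
        q = t[t.name == "ABarpaapp"][["x", "y", "z"]].to_numpy(float)[0]
        assert res.info["distance_to_target"] == pytest.approx(np.linalg.norm(p - q))

    def test_gradient_variant_has_no_subgoal_term(self, env):
        env.reset()
        res = env.step(0)
        assert res.reward.r_subgoal == 0.0
        assert res.reward.r_gradient < 0.0


class TestGetState:
    def test_counts_steps(self, env):
        env.reset()
        assert env.get_state().steps_elapsed == 0
        for k in range(3):
            env.step(0)
        assert env.get_state().steps_elapsed == 3

    def test_snapshot_isolation(self, env):
        env.reset()
        snap = env.get_state()
        snap.cell_table.loc[:, "x"] = -999.0
        res = env.step(0)
        assert np.isfinite(res.info["distance_to_target"])
        assert env.get_state().cell_table.x.min() > -999.0


class TestSubgoal:
    def test_valid_pair_annotated_white(self, subgoal_env):
        subgoal_env.reset()
        pairs = subgoal_env.secondary_neighbor_pairs()
        assert pairs
        subgoal_env.set_subgoal(pairs[0])
        ann = subgoal_env.annotations()
        assert all(ann[c] == "subgoal" for c in pairs[0])

    def test_direct_neighbor_pair_rejected(self, subgoal_env):
        subgoal_env.reset()
        from cmgym.neighbors import neighbors_of
        direct = sorted(neighbors_of(subgoal_env._table, "Cpaaa"))
        with pytest.raises(ValueError):
            subgoal_env.set_subgoal((direct[0], direct[1]))

    def test_subgoal_requires_subgoal_hypothesis(self, env):
        env.reset()
        with pytest.raises(ConfigurationError):
            env.set_subgoal(("a", "b"))

    def test_subgoal_pays_10_once(self, corridor_series):
        env = create(corridor_series, "Cpaaa", "ABarpaapp",
                     hypothesis="subgoal", seed=0)
        env.reset()
        pairs = env.secondary_neighbor_pairs()
        # chase the nearest-ahead pair by walking the corridor
        t = env._table
        x_of = {n: float(t[t.name == n].x.iloc[0]) for n in set(sum(pairs, ()))}
        pair = min(pairs, key=lambda p: abs(x_of[p[0]] - x_of[p[1]])
                   + min(x_of[p[0]], x_of[p[1]]))
        env.set_subgoal(pair)
        paid = []
        done = False
        while not done:
            res = env.step(0)
            paid.append(res.reward.r_subgoal)
            done = res.done
        assert sum(paid) in (0.0, 10.0)  # at most one payment
        assert max(paid, default=0.0) in (0.0, 10.0)


class TestOracleWalk:
    def test_straight_walk_reaches_stability_within_budget(self, corridor_series):
        """A 'walk straight at the target' policy succeeds on the corridor."""
        env = create(corridor_series, "Cpaaa", "ABarpaapp",
                     speed_noise_halfwidth=0.0, seed=0)
        env.reset()
        done = False
        while not done:
            t = env._table
            p = t[t.name == "Cpaaa"][["x", "y", "z"]].to_numpy(float)[0]
            q = t[t.name == "ABarpaapp"][["x", "y", "z"]].to_numpy(float)[0]
            ang = np.degrees(np.arctan2(q[1] - p[1], q[0] - p[0])) % 360
            done = env.step(int(round(ang / 45)) % 8).done
        assert env.destination_paid
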