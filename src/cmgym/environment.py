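"""Gym-style tissue environment.

Environment cells replay their recorded (or synthetic) positions frame by
frame while the migrating cell is moved by agent actions: one of eight
compass directions in the XY plane (45° apart, z held; a 26-direction 3-D
action set is available via ``action_mode="xyz26"``), with a step size
drawn from the observed average speed ±20% truncated-normal noise.  The
per-step reward is the three-part formulation of :mod:`cmgym.rewards`,
under either the gradient-driven or the collective/subgoal-driven
hypothesis.  Episodes end when the destination reward is paid, the time
budget (90% of the observed migration time) is exhausted, or the series
runs out of frames.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cmgym.errors import ConfigurationError, EpisodeStateError
from cmgym.lineage_io import EmbryoSeries, migration_window
from cmgym.neighbors import neighbors_of, pair_ratio, secondary_neighbors
from cmgym.rendering import Camera, Observation, Palette, build_observation, rasterize
from cmgym.rewards import (
    RewardBreakdown,
    RewardConfig,
    destination_reward,
    gradient_reward,
    pair_reward,
    subgoal_reward,
)


class Discrete:
    """Minimal Gym-style discrete action space."""

    def __init__(self, n: int):
        self.n = n

    def contains(self, a) -> bool:
        return isinstance(a, (int, np.integer)) and 0 <= int(a) < self.n

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.n))

    def __repr__(self):
        return f"Discrete({self.n})"


class BoxSpace:
    """Minimal Gym-style box observation space descriptor."""

    def __init__(self, low: float, high: float, shape: tuple[int, ...]):
        self.low, self.high, self.shape = low, high, shape

    def __repr__(self):
        return f"Box({self.low}, {self.high}, {self.shape})"


@dataclass(frozen=True)
class ActionSpec:
    index: int
    direction: np.ndarray  # unit 3-vector
    step_size: float


@dataclass
class SpeedModel:
    """Average per-step speed with ±20% truncated-normal randomness."""

    v_avg: float
    noise_halfwidth: float = 0.2

    def __post_init__(self):
        if self.v_avg <= 0:
            raise ValueError("v_avg must be > 0")
        if not 0 <= self.noise_halfwidth < 1:
            raise ValueError("noise_halfwidth must be in [0, 1)")


def sample_step_size(speed: SpeedModel, rng: np.random.Generator) -> float:
    """Draw v_avg * (1 + delta), delta ~ N(0, hw/2) truncated to [-hw, +hw]."""
    hw = speed.noise_halfwidth
    if hw == 0:
        return speed.v_avg
    while True:
        delta = rng.normal(0.0, hw / 2.0)
        if -hw <= delta <= hw:
            return speed.v_avg * (1.0 + delta)


def _directions(mode: str) -> np.ndarray:
    if mode == "xy8":
        ang = np.deg2rad(np.arange(8) * 45.0)
        return np.stack([np.cos(ang), np.sin(ang), np.zeros(8)], axis=1)
    if mode == "xyz26":
        dirs = [np.array([i, j, k], float)
                for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                if (i, j, k) != (0, 0, 0)]
        return np.stack([d / np.linalg.norm(d) for d in dirs])
    raise ConfigurationError(f"unknown action mode {mode!r}")


@dataclass
class TissueState:
    """Read-only snapshot of the environment."""

    frame_index: int
    cell_table: pd.DataFrame
    migrating: str
    target: str
    active_subgoal: tuple[str, str] | None
    stable_counter: int
    steps_elapsed: int
    budget_steps: int


@dataclass
class StepResult:
    observation: Observation
    reward: RewardBreakdown
    done: bool
    info: dict = field(default_factory=dict)


class TissueEnvironment:
    """Replayed tissue with an agent-controlled migrating cell.

    Use :func:`create` (or the constructor) and then the Gym verbs
    ``reset`` / ``step`` / ``render`` / ``get_state`` / ``set_subgoal``.
    """

    def __init__(
        self,
        series: EmbryoSeries,
        migrating: str,
        target: str,
        reward_config: RewardConfig | None = None,
        hypothesis: str = "gradient",
        seed: int = 0,
        image_size: int = 64,
        action_mode: str = "xy8",
        neighbor_model="voronoi",
        palette: Palette | None = None,
        speed_noise_halfwidth: float = 0.2,
        camera_mode: str = "fixed",
        camera_extent: float | None = None,
    ):
        if hypothesis not in ("gradient", "subgoal"):
            raise ConfigurationError(f"hypothesis must be 'gradient' or 'subgoal', got {hypothesis!r}")
        series.validate()
        cells = series.cells()
        for name in (migrating, target):
            if name not in cells:
                raise ValueError(f"cell {name!r} not present in series")
        self.series = series
        self.migrating = migrating
        self.target = target
        self.config = reward_config or RewardConfig()
        self.hypothesis = hypothesis
        self.seed = seed
        self.neighbor_model = neighbor_model
        self.palette = palette or Palette()
        self._dirs = _directions(action_mode)
        self.action_space = Discrete(len(self._dirs))
        self.observation_space = BoxSpace(0.0, 1.0, (2, image_size, image_size))

        lo, hi = migration_window(series, migrating, target)
        self.window = (lo, hi)
        window_steps = hi - lo
        if window_steps < 1:
            raise ValueError("migration window must span at least one step")
        self.budget_steps = int(np.floor(self.config.time_budget_fraction * window_steps))

        start = series.frame_table(lo)
        p_mig = start.loc[start["name"] == migrating, ["x", "y", "z"]].to_numpy(float)[0]
        p_tgt = start.loc[start["name"] == target, ["x", "y", "z"]].to_numpy(float)[0]
        self.initial_distance = float(np.linalg.norm(p_mig - p_tgt))
        self.speed = SpeedModel(
            v_avg=self.initial_distance / window_steps,
            noise_halfwidth=speed_noise_halfwidth,
        )
        self._start_pos = p_mig

        # eggshell clamp: series bounding box inflated by one mean radius
        t = series.table
        mean_r = float(t["diameter"].mean()) / 2.0
        self._bbox_lo = t[["x", "y", "z"]].min().to_numpy(float) - mean_r
        self._bbox_hi = t[["x", "y", "z"]].max().to_numpy(float) + mean_r

        # fixed per-episode camera focused on the migration field: the
        # migrating cell's recorded positions and the target, with margin
        if camera_mode not in ("fixed", "follow"):
            raise ConfigurationError(f"camera_mode must be 'fixed' or 'follow', got {camera_mode!r}")
        self.camera_mode = camera_mode
        mt = t[t["name"].isin([migrating, target])]
        mig_lo = mt[["x", "y", "z"]].min().to_numpy(float)
        mig_hi = mt[["x", "y", "z"]].max().to_numpy(float)
        center = (mig_lo + mig_hi) / 2.0
        half = float(np.max(mig_hi[:2] - mig_lo[:2]) / 2.0)
        if camera_extent is None:
            # follow mode keeps the target inside the field of view from the start
            camera_extent = (half + 2.0 * mean_r) if camera_mode == "fixed" \
                else self.initial_distance * 0.85 + mean_r
        self.camera = Camera(
            target_position=tuple(center),
            distance=float(self._bbox_hi[2] - center[2] + 10.0),
            image_size=image_size,
            extent=float(camera_extent),
        )
        # frame tables are replayed many times per training run; cache them
        self._frame_cache: dict[int, pd.DataFrame] = {
            f: series.frame_table(f) for f in range(lo, hi + 1)
        }
        self.reset()

    # -- episode management -------------------------------------------

    def reset(self) -> Observation:
        """Restore frame index, counters, subgoal and RNG; return initial obs."""
        self.rng = np.random.default_rng(self.seed)
        self.frame_index = self.window[0]
        self.steps_elapsed = 0
        self.stable_counter = 0
        self.subgoal_stable_counter = 0
        self.destination_paid = False
        self.active_subgoal: tuple[str, str] | None = None
        self._subgoal_paid = False
        self.done = False
        self._mig_pos = self._start_pos.copy()
        self._table = self._compose_table(self.frame_index)
        return self._observe()

    def _compose_table(self, frame: int) -> pd.DataFrame:
        table = self._frame_cache[frame].copy()
        mask = table["name"] == self.migrating
        table.loc[mask, ["x", "y", "z"]] = self._mig_pos
        return table.reset_index(drop=True)

    def annotations(self) -> dict:
        ann = {self.migrating: "migrating", self.target: "target"}
        if self.active_subgoal is not None:
            for s in self.active_subgoal:
                ann[s] = "subgoal"
        return ann

    def _observe(self) -> Observation:
        if self.camera_mode == "follow":
            # camera tracks the migrating cell (egocentric top view)
            self.camera.target_position = tuple(self._mig_pos)
        gray, depth = rasterize(self._table, self.camera, self.palette, self.annotations())
        return build_observation(gray, depth)

    def _target_pos(self) -> np.ndarray:
        t = self._table
        return t.loc[t["name"] == self.target, ["x", "y", "z"]].to_numpy(float)[0]

    def distance_to_target(self) -> float:
        return float(np.linalg.norm(self._mig_pos - self._target_pos()))

    # -- the Gym verbs -------------------------------------------------

    def step(self, action_index: int) -> StepResult:
        if self.done:
            raise EpisodeStateError("step() called on a finished episode; call reset()")
        if not self.action_space.contains(action_index):
            raise ValueError(f"invalid action index {action_index!r}")

        step_size = sample_step_size(self.speed, self.rng)
        self._mig_pos = np.clip(
            self._mig_pos + step_size * self._dirs[int(action_index)],
            self._bbox_lo, self._bbox_hi,
        )
        self.frame_index += 1
        self.steps_elapsed += 1
        self._table = self._compose_table(self.frame_index)

        neigh = neighbors_of(self._table, self.migrating, self.neighbor_model)
        breakdown = RewardBreakdown()
        breakdown.r_neighbor = sum(
            pair_reward(pair_ratio(self._table, self.migrating, n), self.config)
            for n in neigh
        )

        # destination stability
        self.stable_counter = self.stable_counter + 1 if self.target in neigh else 0
        breakdown.r_destination = destination_reward(
            self.stable_counter, self.steps_elapsed, self.budget_steps,
            self.config, already_paid=self.destination_paid,
        )
        if breakdown.r_destination:
            self.destination_paid = True

        subgoal_achieved = False
        if self.hypothesis == "gradient":
            breakdown.r_gradient = gradient_reward(
                self.distance_to_target(), self.initial_distance, self.config
            )
        elif self.active_subgoal is not None:
            both = set(self.active_subgoal) <= neigh
            self.subgoal_stable_counter = self.subgoal_stable_counter + 1 if both else 0
            subgoal_achieved = self.subgoal_stable_counter >= self.config.subgoal_stable_steps
            breakdown.r_subgoal = subgoal_reward(
                subgoal_achieved, self.config, already_paid=self._subgoal_paid
            )
            if breakdown.r_subgoal:
                self._subgoal_paid = True

        self.done = (
            self.destination_paid
            or self.steps_elapsed >= self.budget_steps
            or self.frame_index >= self.window[1]
        )
        info = {
            "distance_to_target": self.distance_to_target(),
            "neighbors": neigh,
            "step_size": step_size,
            "subgoal": self.active_subgoal,
            "subgoal_achieved": subgoal_achieved,
            "destination_paid": self.destination_paid,
            "position": self._mig_pos.copy(),
        }
        return StepResult(self._observe(), breakdown, self.done, info)

    def get_state(self) -> TissueState:
        """Deep snapshot; mutating it does not affect the environment."""
        return TissueState(
            frame_index=self.frame_index,
            cell_table=self._table.copy(),
            migrating=self.migrating,
            target=self.target,
            active_subgoal=copy.copy(self.active_subgoal),
            stable_counter=self.stable_counter,
            steps_elapsed=self.steps_elapsed,
            budget_steps=self.budget_steps,
        )

    def set_subgoal(self, pair: tuple[str, str]) -> None:
        """Activate a subgoal pair chosen from secondary neighbors."""
        if self.hypothesis != "subgoal":
            raise ConfigurationError("subgoals are only available under the subgoal hypothesis")
        sec = secondary_neighbors(self._table, self.migrating, self.neighbor_model)
        bad = [c for c in pair if c not in sec]
        if bad:
            raise ValueError(
                f"subgoal cells must be secondary neighbors of {self.migrating!r}; "
                f"not secondary: {', '.join(bad)}"
            )
        self.active_subgoal = (pair[0], pair[1])
        self._subgoal_paid = False
        self.subgoal_stable_counter = 0

    def secondary_neighbor_pairs(self) -> list[tuple[str, str]]:
        """Candidate subgoal pairs from the current secondary neighbors."""
        sec = sorted(secondary_neighbors(self._table, self.migrating, self.neighbor_model))
        return [(a, b) for i, a in enumerate(sec) for b in sec[i + 1:]]

    def render(self, mode: str = "rgb_array"):
        """Observation stack ("rgb_array") or the current gray channel."""
        obs = self._observe()
        if mode == "rgb_array":
            return obs.stack
        if mode == "gray":
            return obs.gray
        raise ValueError(f"unknown render mode {mode!r}")


def create(series: EmbryoSeries, migrating: str, target: str,
           reward_config: RewardConfig | None = None,
           hypothesis: str = "gradient", seed: int = 0, **kwargs) -> TissueEnvironment:
    """Create a tissue environment (Gym ``Create()`` verb)."""
    return TissueEnvironment(
        series, migrating, target, reward_config=reward_config,
        hypothesis=hypothesis, seed=seed, **kwargs,
    )
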