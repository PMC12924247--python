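"""The three-part reward formulation of the tissue environment.

The per-step reward is a sum of feedback from three models:

- **Neighbor Distance**: for each direct neighbor of the migrating cell, a
  penalty based on the center-distance / radius-sum ratio.  Ratios below
  ``ratio_low`` (cells interpenetrating) cost ``overlap_penalty`` (-1000);
  within the acceptable band [ratio_low, ratio_high] = [0.3, 0.8] the
  penalty rises linearly from -1 to 0; above the band there is no penalty.
- **Destination**: +100, paid once, the first time the migrating cell has
  been a neighbor of the target for ``stable_steps`` (5) consecutive steps,
  provided this happens within the episode time budget (90% of the
  observed migration time).
- A hypothesis-specific term: a dense **gradient** penalty proportional to
  the current distance to the target (gradient-driven hypothesis), or a
  sparse **subgoal** bonus of +10 per achieved subgoal pair
  (collective-behavior hypothesis).  The two are mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cmgym.errors import ConfigurationError
from cmgym.neighbors import neighbors_of, pair_ratio


@dataclass
class RewardConfig:
    ratio_low: float = 0.3
    ratio_high: float = 0.8
    overlap_penalty: float = -1000.0
    destination_reward: float = 100.0
    subgoal_reward: float = 10.0
    stable_steps: int = 5
    subgoal_stable_steps: int = 1
    time_budget_fraction: float = 0.90
    gradient_coeff: float = 1.0

    def __post_init__(self):
        if not 0 < self.ratio_low < self.ratio_high:
            raise ConfigurationError("need 0 < ratio_low < ratio_high")
        if self.stable_steps < 1:
            raise ConfigurationError("stable_steps must be >= 1")
        if not 0 < self.time_budget_fraction <= 1:
            raise ConfigurationError("time_budget_fraction must be in (0, 1]")
        if self.gradient_coeff < 0:
            raise ConfigurationError("gradient_coeff must be >= 0")


@dataclass
class RewardBreakdown:
    """Per-step reward decomposition; total is the sum of the components."""

    r_neighbor: float = 0.0
    r_destination: float = 0.0
    r_gradient: float = 0.0
    r_subgoal: float = 0.0

    @property
    def total(self) -> float:
        return self.r_neighbor + self.r_destination + self.r_gradient + self.r_subgoal


def pair_reward(ratio: float, config: RewardConfig | None = None) -> float:
    """Single-neighbor distance penalty R_Ni as a function of the pair ratio."""
    config = config or RewardConfig()
    if ratio < 0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    if ratio < config.ratio_low:
        return config.overlap_penalty
    if ratio <= config.ratio_high:
        # -1 at ratio_low rising linearly to 0 at ratio_high
        return -(config.ratio_high - ratio) / (config.ratio_high - config.ratio_low)
    return 0.0


def neighbor_distance_reward(frame_table, cell: str, model="voronoi",
                             config: RewardConfig | None = None) -> float:
    """R_N: sum of pair_reward over all direct neighbors of ``cell``."""
    config = config or RewardConfig()
    total = 0.0
    for n in neighbors_of(frame_table, cell, model):
        total += pair_reward(pair_ratio(frame_table, cell, n), config)
    return total


def destination_reward(stable_counter: int, step_index: int, budget_steps: int,
                       config: RewardConfig | None = None,
                       already_paid: bool = False) -> float:
    """Destination bonus: pays once when stability is first reached in budget.

    ``stable_counter`` is the number of consecutive steps (including the
    current one) the migrating cell has been a neighbor of the target; it is
    the caller's job to reset it to 0 on non-neighbor steps.
    """
    config = config or RewardConfig()
    if stable_counter < 0 or step_index < 0:
        raise ValueError("counters must be >= 0")
    if already_paid:
        return 0.0
    if stable_counter >= config.stable_steps and step_index <= budget_steps:
        return config.destination_reward
    return 0.0


def gradient_reward(distance_now: float, distance_initial: float,
                    config: RewardConfig | None = None) -> float:
    """Dense gradient penalty -c * d/d0 (more negative when farther away)."""
    config = config or RewardConfig()
    if distance_now < 0 or distance_initial < 0:
        raise ValueError("distances must be >= 0")
    if distance_initial == 0:
        raise ValueError("distance_initial must be > 0")
    return -config.gradient_coeff * distance_now / distance_initial


def subgoal_reward(subgoal_achieved: bool, config: RewardConfig | None = None,
                   already_paid: bool = False) -> float:
    """Intermediate bonus the first time the active subgoal pair is reached."""
    config = config or RewardConfig()
    if subgoal_achieved and not already_paid:
        return config.subgoal_reward
    return 0.0


def total_reward(components: RewardBreakdown) -> float:
    """Sum the breakdown; the two hypothesis terms are mutually exclusive."""
    if components.r_gradient != 0.0 and components.r_subgoal != 0.0:
        raise ConfigurationError("gradient and subgoal rewards cannot both be active")
    return components.total
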