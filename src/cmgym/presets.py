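"""Canonical configurations for desk-scale (scaled-down) experiments.

The published-scale setup — 900 epochs, 64x64 observations, multi-hour
training — is far beyond a single desktop CPU, so the package ships one
fixed scaled-down world and agent configuration pair per hypothesis:
a 20-cell corridor scenario with a 20-minute migration window, 32x32
observations from a migrating-cell-centered camera, and small conv heads.
The stronger chemotactic coefficient (gradient_coeff=10) compensates for
the ~100x shorter training; all other reward constants are untouched.
"""

from __future__ import annotations

from cmgym.agents import DQNConfig, HDQNConfig
from cmgym.environment import TissueEnvironment
from cmgym.lineage_io import EmbryoSeries
from cmgym.rewards import RewardConfig
from cmgym.synthetic import ScenarioSpec


def scaled_scenario_spec(seed: int = 1) -> ScenarioSpec:
    """20-cell corridor scenario, 20 frames of 60 s (20-minute migration)."""
    return ScenarioSpec(n_cells=20, total_time=1200.0, seed=seed)


def scaled_env_kwargs() -> dict:
    return dict(image_size=32, camera_mode="follow", camera_extent=32.0)


def scaled_reward_config(hypothesis: str = "gradient") -> RewardConfig:
    if hypothesis == "gradient":
        return RewardConfig(gradient_coeff=10.0)
    return RewardConfig()


def scaled_environment(series: EmbryoSeries, migrating: str, target: str,
                       hypothesis: str = "gradient", seed: int = 0) -> TissueEnvironment:
    return TissueEnvironment(
        series, migrating, target,
        reward_config=scaled_reward_config(hypothesis),
        hypothesis=hypothesis, seed=seed, **scaled_env_kwargs(),
    )


def scaled_dqn_config(seed: int = 0) -> DQNConfig:
    """Desk-scale DQN: small conv head, 175 epochs, 3-step TD."""
    return DQNConfig(
        conv_channels=(8, 16), conv_kernels=(4, 3), conv_strides=(2, 2),
        fc_units=128, learning_rate=1e-3, batch_size=64,
        target_update_every=250, epochs=175, huber_delta=10.0, n_step=3,
        seed=seed,
    )


def scaled_hdqn_config(seed: int = 0) -> HDQNConfig:
    """Desk-scale H-DQN: controller batch 32, greedy 0.8 -> 0.95."""
    controller = DQNConfig(
        conv_channels=(8, 16), conv_kernels=(4, 3), conv_strides=(2, 2),
        fc_units=128, learning_rate=1e-3, batch_size=32,
        target_update_every=150, greedy_start=0.8, greedy_end=0.95,
        huber_delta=10.0, n_step=5, updates_per_step=2,
    )
    return HDQNConfig(
        meta_hidden=(64, 128, 128), controller=controller,
        epochs=200, controller_horizon=25, seed=seed,
    )
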