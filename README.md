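# cmgym

A Gym-style reinforcement-learning framework for data-driven modelling of
**cell migration** in developing embryos. A migrating cell is treated as an
RL agent inside a 3-D tissue environment reconstructed from nucleus-tracking
time series (per-frame records of lineage name, position and nucleus size,
as produced by *C. elegans* lineage-tracing pipelines). By formulating
migration as a Markov decision process, competing mechanistic hypotheses —
*is the cell pulled by a chemotactic gradient, or passed along by collective
neighbor behavior?* — become alternative reward structures whose trained
agents can be compared against the observed migration.

The worked case is the **Cpaaa intercalation**: the C-lineage cell Cpaaa
migrates between two rows of ABarp cells until it becomes a stable neighbor
of ABarpaapp.

## The model

**Tissue environment.** Environment cells replay their recorded (or
synthetic) positions frame by frame; the migrating cell is moved by agent
actions: one of 8 compass directions in the XY plane, with step size
`v_avg · (1 + δ)`, `δ ~ N(0, 0.1)` truncated to ±20%, where `v_avg` is the
initial migrating→target distance divided by the migration window length.
Observations are 2×64×64 stacks of an annotated top-view grayscale image
(x, y, size, role) and a depth image (z).

**Reward** is a sum of three models. With `ρ = d / (r_a + r_b)` the
center-distance/radius-sum ratio of a cell pair:

- *Neighbor Distance*: for each direct (Voronoi) neighbor,
  `R_Ni = −1000` if `ρ < 0.3`; linear from −1 to 0 on `0.3 ≤ ρ ≤ 0.8`;
  `0` for `ρ > 0.8`; and `R_N = Σ R_Ni`.
- *Destination*: `+100`, once, when the migrating cell has been a neighbor
  of the target for 5 consecutive steps within 90% of the observed
  migration time.
- Hypothesis term: a dense gradient penalty `−c · d/d₀` (gradient
  hypothesis), or a sparse `+10` per achieved subgoal — a pair of secondary
  neighbors the agent must become adjacent to (collective hypothesis).

**Agents.** DQN (two conv layers + FC head, Adam β₁=0.9 β₂=0.999,
lr 1e-4, batch 64, target network synced every 1000 updates, greedy factor
0.3→0.95) for the gradient hypothesis; a two-level hierarchical DQN for the
subgoal hypothesis (meta-controller 512/1024/1024 choosing subgoal pairs
from secondary neighbors, controller batch 32, greedy 0.8→0.95). Networks
are implemented in numpy (`cmgym.nn`) — no GPU framework required.

Neighborship is decided by 3-D Delaunay tessellation (Voronoi dual, long
edges pruned) or by a random-forest pair classifier trained against the
Voronoi ground truth.

## Worked example

```python
from cmgym.presets import (scaled_scenario_spec, scaled_environment,
                           scaled_dqn_config)
from cmgym.synthetic import generate_migration_scenario
from cmgym.agents import train_dqn, evaluate_policy

series, truth = generate_migration_scenario(scaled_scenario_spec(seed=1))
env = scaled_environment(series, "Cpaaa", "ABarpaapp",
                         hypothesis="gradient", seed=0)
policy, curve = train_dqn(env, scaled_dqn_config(seed=0))
result = evaluate_policy(env, policy, n_runs=20)
print(f"greedy success rate: {result.success_rate:.2f}")
print(f"final mean distance: {result.mean_distance_curve[-1]:.1f} µm")
```

prints (about 2 minutes on one CPU):

```
greedy success rate: 1.00
final mean distance: 17.4 µm
```

meaning all 20 greedy evaluation episodes reached the stable-neighbor
criterion within the time budget, ending ~17 µm from the target's center —
adjacent to it, given ~7 µm cell radii.

The same workflow runs from the shell:

```bash
cmgym synth --scenario corridor --seed 1 --out series.tsv --truth path.tsv
cmgym train --series series.tsv --hypothesis gradient --out ckpt/
cmgym evaluate --ckpt ckpt/checkpoint.pkl --series series.tsv --runs 5 --out eval/
cmgym ablate-neighbors --ckpt ckpt/checkpoint.pkl --series series.tsv --out ablate/
```

## Acceptance script

`scripts/acceptance.py` recomputes the framework's printed reward constants
by running the package — the per-pair penalty for an interpenetrating pair
(ratio 0.2), the destination reward at the first stable-neighbor step of a
scripted episode, and the intrinsic reward at a subgoal achievement in a
hierarchical episode — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
| --- | --- |
| `cmgym.lineage_io` | read/write/validate/upsample tracking series (TSV + AceTree-like CSV) |
| `cmgym.synthetic` | synthetic embryos and corridor migration scenarios |
| `cmgym.neighbors` | Voronoi/Delaunay neighbor graphs, radius model, random-forest classifier |
| `cmgym.rewards` | the three-part reward formulation |
| `cmgym.environment` | the Gym-style tissue environment (reset/step/render) |
| `cmgym.rendering` | grayscale + depth rasterization, annotated views |
| `cmgym.nn`, `cmgym.agents` | numpy DQN / hierarchical DQN |
| `cmgym.standardize` | multi-embryo midpoint alignment, neighbor-removal experiment |
| `cmgym.presets` | desk-scale configurations used by the test suite |
| `cmgym.cli` | the `cmgym` command line |

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
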