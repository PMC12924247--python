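# Methods

## The modelling problem

During embryogenesis some cells travel long distances through packed
tissue. The framework casts one such migration — a cell moving between two
rows of neighbors until it docks next to a target cell — as a Markov
decision process: the tissue (reconstructed from nucleus-tracking records)
is the environment, the migrating cell is the agent, and a mechanistic
hypothesis about what drives the migration is expressed purely as a reward
structure. If an agent trained under a hypothesis reproduces the observed
kinematics (the distance-to-target curve, the path shape), that hypothesis
is consistent with the data; training failures or divergent paths count
against it.

## Tissue reconstruction

Input series are per-frame tables `(frame, name, x, y, z, diameter)` with
C. elegans-style lineage names (each division appends one of `a p d v l r`).
Coordinates are µm internally; pixel-space input is converted with the
acquisition scale (defaults 0.254, 0.254, 0.1 µm/px on x, y, z, 30 z-planes
— kept as configuration defaults without reconciling the implied 3 µm
stack depth, which is an artifact of the source acquisition description).
Tracking intervals of 60 s are linearly upsampled 10× to 6 s steps; cells
are interpolated only across intervals where they exist at both endpoint
frames, so a dividing parent ends exactly at the copy of its last original
frame and its children start at the copy of theirs (no mid-interval
births).

## Neighborship

Two cells are neighbors when their nuclei are Delaunay-adjacent (the dual
of the Voronoi tessellation). Raw 3-D Delaunay over-connects across the
convex hull, so edges with center-distance/radius-sum ratio above 2.0 are
pruned; the cutoff sits comfortably above the biologically acceptable band
(0.3, 0.8) and below typical hull artifacts. Degenerate (coplanar or
collinear) frames fall back to lower-dimensional tessellation; 2–3 cells
are fully connected within the cutoff.

A random-forest pair classifier reproduces the Voronoi decision from
handcrafted features. Pure pairwise features (distance, sizes, ratio,
total cell count) cannot tell whether a third cell blocks the would-be
Voronoi face, which caps held-out balanced accuracy near 0.85; two context
features fix this: the relative-neighborhood lens criterion
`min_c max(d(c,a), d(c,b)) / d(a,b)` and the count of cells inside the
lens. Training pairs are Voronoi edges against non-edges sampled 1:1 (the
class balance is a design choice, not a data property). The model-based
radius estimate is `r = (3 V w(g) / (4π N))^(1/3)` with embryo volume `V`,
cell count `N` and a per-generation weight `w` defaulting to 1 (the
lineage modulation of radius is unspecified; `w` is the hook for it).

## Reward formulation

Per step, with `ρ` the pair ratio of the migrating cell and one neighbor:

| term | value |
| --- | --- |
| neighbor distance, per neighbor | `−1000` if `ρ < 0.3`; `−(0.8 − ρ)/0.5` on `[0.3, 0.8]`; `0` above |
| destination | `+100` once, when neighbor-of-target for 5 consecutive steps within 90% of the observed migration time |
| gradient hypothesis | `−c · d/d₀` every step (`c ≥ 0`, default 1; normalized by the initial distance so `c` is scale-free) |
| subgoal hypothesis | `+10` once per subgoal, when adjacent to both cells of the active pair |

Boundary convention: ρ = 0.3 belongs to the linear regime (penalty −1, not
−1000), making the penalty continuous from the right; the overlap penalty
applies strictly below 0.3. Subgoal achievement requires simultaneous
adjacency with both pair cells for 1 step (configurable), versus 5 for the
final target whose duration is stated. The two hypothesis terms are
mutually exclusive.

## Environment dynamics

Actions are 8 unit vectors at 45° in the XY plane with z held fixed
(`xyz26` is available as a config option; the 2-D top-view observation
pairs naturally with in-plane actions). Step length is
`v_avg (1 + δ)`, `δ ~ N(0, halfwidth/2)` truncated to ±halfwidth
(default 0.2, so ±20% ≈ ±2σ), with `v_avg` = initial migrating→target
distance / window steps. Environment cells are kinematic replays — the
agent never perturbs them and collisions are not resolved; penalties, not
physics, discourage interpenetration. Positions are clamped to the series
bounding box inflated by one mean radius (an eggshell stand-in; wall
behavior is otherwise unspecified). Episodes end when the destination
pays, the 90% budget is exhausted, or the series runs out.

## Observations

Cells are drawn as orthographically projected discs; nearer spheres
overwrite farther ones per pixel. The grayscale channel encodes role
(migrating 1.0, subgoal 0.9, target 0.8, environment 0.5 — distinct so the
roles survive the collapse to one channel); the depth channel is the
normalized camera distance to the nearest sphere surface, linear between
the scene's z extremes, background 1. The two 64×64 channels stack
channel-first. Two camera modes exist: `fixed` (whole migration field) and
`follow` (centered on the migrating cell). The follow mode exists because
at 32×32 a whole-field camera gives the agent less than one pixel of
visual change per action, which no small CNN can exploit; an egocentric
view makes the policy translation-invariant and is within the framework's
stated camera freedom.

## Agents

Both hypotheses use the same CNN head: two conv layers and one hidden FC
layer onto 8 action values (default 16/32 channels, kernels 8/4, strides
4/2, FC 256 — the published figure fixes only the layer types, so shapes
are config). Training is standard deep Q-learning: ε-greedy rollouts
(the *greedy factor* — the probability of the argmax action — rises
linearly 0.3→0.95 over epochs; one epoch = one episode plus its updates),
uniform replay, Adam(β₁ 0.9, β₂ 0.999, lr 1e-4), batch 64, target network
synced every 1000 gradient steps. Config-exposed standard refinements:
Huber loss (the −1000 spikes otherwise dominate the squared loss — the
classic error-clipping rationale), double-DQN targets, n-step returns
(default 1), and an optional training-side reward scale. The hierarchical
agent adds a fully-connected meta-controller (512/1024/1024) that scores
candidate subgoal pairs from features of the migrating cell's position,
the pair positions and the distance to target (scaled by the scene
half-extent); the controller (batch 32, greedy 0.8→0.95) pursues the
chosen pair and the meta re-selects on achievement or after a 25-step
horizon. With no secondary neighbors available the final target itself
becomes the goal (final-leg fallback).

All networks are plain numpy (im2col convolutions, manual backprop,
deterministic He initialization per seed); no GPU framework is needed, and
desk-scale runs finish in minutes.

## Synthetic worlds

The generator provides two stated worlds.

*Packed embryo* (`generate_embryo`): cells fill an ellipsoidal eggshell
(default semi-axes 27×18×15 µm) by random sequential adsorption at packing
density 0.35; the nucleus diameter is then calibrated to the realized
minimum spacing so that ≥90% of Voronoi-adjacent pairs land in the
acceptable ratio band (0.3, 0.8) — the diameter is the generator's free
parameter, the band is the constraint. Cells drift by a per-frame random
walk (sd 0.2 µm, small against ~7 µm radii so neighbor graphs stay
stable). One optional division replaces a cell with `name+a`, `name+p` at
the window midpoint.

*Corridor scenario* (`generate_migration_scenario`): two rows of flanking
cells (4 per row, spacing 0.55 diameters) line a straight path; a centered
passage sits at ratio 0.75 to each wall — inside the acceptable band near
its no-penalty edge, while crossing a row still costs −1000. The migrating
cell's recorded trajectory runs start→corridor→adjacent-to-target
(returned as the ground-truth path); remaining cells flank the corridor at
near-no-penalty spacing, off the path tube. Earlier designs that packed
spare cells against the start position made "flee the tissue" the
reward-optimal behavior — a sparseness artifact no real embryo offers — so
flanking placement is deliberate. Defaults: 20 cells, 60 s frames, 30 min
total.

What a green test on these worlds does *not* establish: real embryos have
hundreds of moving, dividing, deforming cells, anisotropic imaging noise
and tracking errors; the synthetic corridor is rigid, convex and fully
observed. Success here validates the machinery (rewards, environment,
learning), not the biological conclusion.

## Desk-scale presets

The published-scale training (900 epochs, 64×64, hours on a datacenter
GPU) is ~100× beyond one desktop CPU-minute budget. `cmgym.presets` pins
one scaled-down world and agent pair per hypothesis: the 20-cell corridor
with a 20-minute window, 32×32 observations from a follow camera
(extent 32 µm), small conv heads (8/16 channels, kernels 4/3, strides
2/2, FC 128), lr 1e-3, 175–200 epochs, n-step 3–5, Huber δ=10. The
gradient preset raises the chemotactic coefficient to `c = 10`
(config-exposed; default elsewhere remains 1): with two orders of
magnitude less training, the dense term must dominate what the small CNN
can resolve, or exploration never produces a single destination payment
to propagate. Test outcome at these presets: the DQN passes the ≥80%
greedy-success criterion on 3/3 seeds; the H-DQN on 2/3 (majority rule;
the failing seed stalls before its controller discovers the first subgoal
payments — a known sparse-reward failure mode at this sample budget).

## Standardization and the neighbor-removal experiment

Per-embryo distance arrays (migrating→target distance over the
co-existence window) are aligned at the sample closest to
(max+min)/2 — the *midpoint*, earliest index on ties — then averaged per
step with a ±1 sd band, reported only where at least two embryos overlap.
The neighbor-removal experiment takes the union of the migrating cell's
direct neighbors over the whole window (static removal; per-frame dynamic
removal is a config option), deletes them, and replays the same trained
policy in both worlds for paired ensembles of distance curves, top-view
paths and arrival steps. The framework asserts only the direction of the
effect (earlier arrival or wider path scatter without neighbors), not its
magnitude.

## Numerical conventions

- Frames are 0-based; time = frame × frame_interval; all lengths µm.
- The canonical TSV writes floats with `repr`, so read∘write is bit-exact.
- Episode rollouts are bit-reproducible given (seed, action sequence).
- Truncated-normal step noise is drawn by rejection, so the mean is exactly
  `v_avg` (verified to 1% over 10⁴ draws in the tests).
- One global seed fans out to per-module seeds via SHA-256 of
  `"{seed}:{module}"` (CLI), keeping modules decorrelated but reproducible.

## Known limitations

- Cells are spheres; nucleus size stands in for cell extent, and rotation
  is stored but unused.
- The classifier reproduces Voronoi ground truth, not the published
  classifier of the original lineage-analysis pipeline or its training
  data.
- The 8-action set is planar; the corridor worlds are effectively 2.5-D.
- H-DQN training at desk scale is seed-sensitive (see presets above).
- The acceptance surface covers printed constants, contracts, oracle
  equivalences and scaled-down learning — not the published figure-level
  curves, which require the original recordings and multi-hour trainings.
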