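"""Multi-embryo observation standardization and the neighbor-removal experiment.

Individual embryos migrate on different clocks, so per-embryo distance
arrays (migrating-to-target distance per timestep over the co-existence
window) are aligned at their *midpoint* — the sample closest to the mean
of the array's maximum and minimum — before the per-step mean and the
±1 standard-deviation band are computed.

The neighbor-removal experiment replays a trained policy in two
environments, intact and with the window-union of the migrating cell's
direct neighbors deleted, and reports paired distance-curve ensembles and
top-view paths so the influence of the flanking cells on the migration
can be read off directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from cmgym.errors import CmgymError
from cmgym.lineage_io import EmbryoSeries, migration_window
from cmgym.neighbors import neighbors_of
from cmgym.synthetic import remove_cells


@dataclass
class DistanceArray:
    """Per-timestep migrating-to-target Euclidean distance of one embryo."""

    values: np.ndarray
    timestep: float  # seconds per step
    embryo_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("distance array needs at least 2 values")
        if (self.values < 0).any():
            raise ValueError("distances must be >= 0")


@dataclass
class StandardizedCurve:
    mean: np.ndarray
    sd: np.ndarray
    n_embryos: int
    alignment_offsets: list
    start_step: int  # aligned-step index of the first reported sample


def distance_array(series: EmbryoSeries, migrating: str, target: str) -> DistanceArray:
    """Distance between the two cells at every frame of their window."""
    lo, hi = migration_window(series, migrating, target)
    t = series.table
    vals = []
    for f in range(lo, hi + 1):
        ft = t[t["frame"] == f]
        p = ft.loc[ft["name"] == migrating, ["x", "y", "z"]].to_numpy(float)[0]
        q = ft.loc[ft["name"] == target, ["x", "y", "z"]].to_numpy(float)[0]
        vals.append(float(np.linalg.norm(p - q)))
    return DistanceArray(
        values=np.asarray(vals), timestep=series.frame_interval,
        embryo_id=str(series.metadata.get("embryo_id", "")),
    )


def midpoint_index(arr: DistanceArray | np.ndarray) -> int:
    """Index of the sample closest to (max + min) / 2; earliest on ties."""
    values = arr.values if isinstance(arr, DistanceArray) else np.asarray(arr, float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    mid = (values.max() + values.min()) / 2.0
    return int(np.argmin(np.abs(values - mid)))


def align_and_average(arrays: list) -> StandardizedCurve:
    """Shift arrays so their midpoints coincide; average the overlap.

    Mean and sd are reported only where at least two arrays overlap after
    alignment.  Offsets are the per-array shifts (in steps) applied so all
    midpoints land on a common origin.
    """
    if len(arrays) < 2:
        raise ValueError("need at least 2 distance arrays to standardize")
    arrays = [a if isinstance(a, DistanceArray) else DistanceArray(np.asarray(a), 1.0)
              for a in arrays]
    mids = [midpoint_index(a) for a in arrays]
    # aligned-step index of sample i of array k: i - mids[k]
    starts = [-m for m in mids]
    ends = [len(a.values) - m for a, m in zip(arrays, mids)]
    lo, hi = min(starts), max(ends)
    span = hi - lo
    stack = np.full((len(arrays), span), np.nan)
    for k, (a, m) in enumerate(zip(arrays, mids)):
        s = -m - lo
        stack[k, s:s + len(a.values)] = a.values
    counts = np.sum(~np.isnan(stack), axis=0)
    keep = counts >= 2
    if not keep.any():
        raise CmgymError("no overlap between distance arrays after midpoint alignment")
    first = int(np.argmax(keep))
    last = span - int(np.argmax(keep[::-1]))
    sub = stack[:, first:last]
    mean = np.nanmean(sub, axis=0)
    sd = np.nanstd(sub, axis=0, ddof=0)
    return StandardizedCurve(
        mean=mean, sd=sd, n_embryos=len(arrays),
        alignment_offsets=[-m for m in mids], start_step=lo + first,
    )


# ---------------------------------------------------------------------------
# neighbor-removal experiment
# ---------------------------------------------------------------------------


@dataclass
class InfluenceReport:
    """Paired with/without-neighbor ensembles of the same trained policy."""

    removed: list
    with_neighbors: object     # EnsembleResult
    without_neighbors: object  # EnsembleResult
    arrival_steps_with: list
    arrival_steps_without: list
    paths_with: list           # (T, 3) position arrays
    paths_without: list

    @property
    def arrival_difference(self) -> float:
        """Mean arrival-step difference (with - without); positive means the
        bare environment is reached earlier."""
        aw = [s for s in self.arrival_steps_with if s is not None]
        ao = [s for s in self.arrival_steps_without if s is not None]
        if not aw or not ao:
            return float("nan")
        return float(np.mean(aw) - np.mean(ao))

    def path_variance(self, which: str = "without") -> float:
        paths = self.paths_without if which == "without" else self.paths_with
        t_min = min(len(p) for p in paths)
        stack = np.stack([p[:t_min] for p in paths])
        return float(stack.var(axis=0).sum(axis=1).mean())


def window_union_neighbors(series: EmbryoSeries, migrating: str, target: str,
                           model="voronoi") -> set[str]:
    """Union of the migrating cell's direct neighbors over the window,
    excluding the migrating and target cells themselves."""
    lo, hi = migration_window(series, migrating, target)
    union: set[str] = set()
    for f in range(lo, hi + 1):
        union |= neighbors_of(series.frame_table(f), migrating, model)
    return union - {migrating, target}


def neighbor_influence_experiment(
    series: EmbryoSeries,
    policy,
    migrating: str,
    target: str,
    reward_config=None,
    n_runs: int = 5,
    hypothesis: str = "gradient",
    meta_policy=None,
    env_kwargs: dict | None = None,
) -> InfluenceReport:
    """Evaluate a trained policy with and without the flanking neighbors."""
    from cmgym.agents import evaluate_policy
    from cmgym.environment import create

    removed = window_union_neighbors(series, migrating, target)
    if not removed:
        raise CmgymError("the migrating cell has no window-union neighbors to remove")
    bare = remove_cells(series, removed)
    if target not in bare.cells():
        raise CmgymError("neighbor removal deleted the target cell")
    env_kwargs = env_kwargs or {}
    results, arrivals, paths = {}, {}, {}
    for tag, ser in (("with", series), ("without", bare)):
        env = create(ser, migrating, target, reward_config=reward_config,
                     hypothesis=hypothesis, **env_kwargs)
        ens = evaluate_policy(env, policy, meta_policy=meta_policy, n_runs=n_runs)
        results[tag] = ens
        arrivals[tag] = [
            (len(r.distances) if r.success else None) for r in ens.runs
        ]
        paths[tag] = [r.positions for r in ens.runs]
    return InfluenceReport(
        removed=sorted(removed),
        with_neighbors=results["with"],
        without_neighbors=results["without"],
        arrival_steps_with=arrivals["with"],
        arrival_steps_without=arrivals["without"],
        paths_with=paths["with"],
        paths_without=paths["without"],
    )


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def plot_outputs(curves: dict, paths: dict | None, out_dir: str) -> list[str]:
    """Write distance-curve plots (mean ± 1 sd band) and top-view path plots.

    ``curves`` maps label -> StandardizedCurve, EnsembleResult or 1-D array;
    ``paths`` maps label -> list of (T, 3) arrays.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, cur in curves.items():
        if hasattr(cur, "mean_distance_curve"):
            mean, sd = cur.mean_distance_curve, cur.sd_band
        elif hasattr(cur, "sd"):
            mean, sd = cur.mean, cur.sd
        else:
            mean, sd = np.asarray(cur, float), None
        x = np.arange(len(mean))
        ax.plot(x, mean, label=label)
        if sd is not None and np.any(sd > 0):
            ax.fill_between(x, mean - sd, mean + sd, alpha=0.3)
    ax.set_xlabel("timestep")
    ax.set_ylabel("distance to target (µm)")
    ax.legend()
    p = os.path.join(out_dir, "distance_curves.png")
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    if paths:
        fig, ax = plt.subplots(figsize=(5, 5))
        for label, plist in paths.items():
            for k, pos in enumerate(plist):
                ax.plot(pos[:, 0], pos[:, 1], alpha=0.6,
                        label=label if k == 0 else None)
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        ax.set_aspect("equal")
        ax.legend()
        p = os.path.join(out_dir, "paths_topview.png")
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
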