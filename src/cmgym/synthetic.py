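"""Synthetic embryos and migration scenarios for download-free testing.

The generator emulates the statistical structure the rewards and agents
assume: cells packed in an ellipsoidal eggshell so that most
Voronoi-adjacent pairs have a center-distance / radius-sum ratio inside
the acceptable band (0.3, 0.8); a migrating cell with a known corridor
path between two rows of flanking cells, ending as a neighbor of a target
cell (the intercalation geometry); 60 s frames before upsampling; optional
divisions via lineage-name suffixing.  Everything is a pure function of
the ScenarioSpec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cmgym.errors import GenerationError, ValidationError
from cmgym.lineage_io import COLUMNS, EmbryoSeries

#: lineage-name stems used for generated environment cells
_STEMS = ("ABal", "ABar", "ABpl", "ABpr", "MSa", "MSp", "Ea", "Ep", "Ca", "Cp", "D")


@dataclass
class CorridorSpec:
    """Two parallel rows of cells flanking a straight migration path."""

    n_per_row: int = 4
    row_name_stem: str = "ABarp"  # flanking rows mimic the ABarp file
    spacing_ratio: float = 0.55   # row-cell spacing / radius sum
    #: half-gap between rows / cell radius; 1.5 puts a centered migrating
    #: cell at ratio 0.75 to each wall — inside the acceptable band, near
    #: the no-penalty edge, as in the observed intercalation corridor
    gap_ratio: float = 1.5


@dataclass
class ScenarioSpec:
    """Stated world of a synthetic embryo / migration scenario."""

    n_cells: int = 20
    eggshell: tuple[float, float, float] = (27.0, 18.0, 15.0)  # semi-axes, µm
    corridor: CorridorSpec = field(default_factory=CorridorSpec)
    migrating_name: str = "Cpaaa"
    target_name: str = "ABarpaapp"
    total_time: float = 1800.0     # 30 min — the observed intercalation scale
    frame_interval: float = 60.0   # pre-upsampling frame interval
    jitter_sd: float = 0.2         # µm per frame drift of environment cells
    divide: bool = False           # one mid-window division of an env cell
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 3:
            raise ValidationError("n_cells must be >= 3")
        if any(a <= 0 for a in self.eggshell):
            raise ValidationError("eggshell semi-axes must be > 0")
        if self.total_time < 2 * self.frame_interval:
            raise ValidationError("total_time must cover at least 2 frame intervals")

    @property
    def n_frames(self) -> int:
        return int(self.total_time // self.frame_interval) + 1

    def cell_radius(self) -> float:
        """Nucleus radius from the embryo-volume formula (w == 1)."""
        a, b, c = self.eggshell
        volume = 4.0 / 3.0 * np.pi * a * b * c
        return float((3.0 * volume / (4.0 * np.pi * self.n_cells)) ** (1.0 / 3.0))


def _inside_eggshell(p: np.ndarray, axes, margin: float = 0.0) -> bool:
    a, b, c = axes
    return (p[0] / (a - margin)) ** 2 + (p[1] / (b - margin)) ** 2 + (p[2] / (c - margin)) ** 2 <= 1.0


def _lineage_names(n: int, rng: np.random.Generator, reserved: set[str]) -> list[str]:
    names: list[str] = []
    seen = set(reserved)
    while len(names) < n:
        stem = _STEMS[int(rng.integers(len(_STEMS)))]
        suffix = "".join(rng.choice(list("apdvlr"), size=int(rng.integers(2, 5))))
        name = stem + suffix
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _pack_positions(
    n: int,
    radius: float,
    axes,
    rng: np.random.Generator,
    existing: np.ndarray | None = None,
    min_ratio: float = 0.4,
    link_ratio: float = 0.72,
    max_tries: int = 4000,
    avoid_segment: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> np.ndarray:
    """Rejection-sampled blob packing inside the eggshell.

    Each new cell must keep a distance ratio >= min_ratio to every placed
    cell and <= link_ratio to at least one (so the cloud stays contiguous
    and Voronoi edges stay short).  Ratios are relative to the radius sum
    2 * radius of an equal-radius pair.
    """
    pts = [] if existing is None else [p for p in existing]
    placed = []
    two_r = 2.0 * radius
    for _ in range(n):
        ok = False
        for _ in range(max_tries):
            if not pts:
                cand = rng.normal(scale=radius, size=3)
            else:
                anchor = pts[int(rng.integers(len(pts)))]
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                cand = anchor + direction * two_r * rng.uniform(min_ratio, link_ratio)
            if not _inside_eggshell(cand, axes, margin=0.5 * radius):
                continue
            if avoid_segment is not None:
                a, b, min_d = avoid_segment
                ab = b - a
                t = np.clip(np.dot(cand - a, ab) / np.dot(ab, ab), 0.0, 1.0)
                if np.linalg.norm(cand - (a + t * ab)) < min_d:
                    continue
            if pts:
                d = np.linalg.norm(np.asarray(pts) - cand, axis=1)
                if d.min() < min_ratio * two_r:
                    continue
                if d.min() > link_ratio * two_r:
                    continue
            pts.append(cand)
            placed.append(cand)
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not pack {n} cells of radius {radius:.1f} µm inside the "
                f"eggshell {tuple(axes)}; try fewer cells"
            )
    return np.asarray(placed)


def _rsa_positions(n: int, axes, rng: np.random.Generator,
                   density: float = 0.35, max_tries: int = 20000) -> tuple[np.ndarray, float]:
    """Random sequential adsorption: uniform fill of the eggshell with a
    minimum spacing chosen so ``n`` spheres of that diameter occupy
    ``density`` of the eggshell volume.  Returns (positions, min spacing)."""
    axes = np.asarray(axes, float)
    volume = 4.0 / 3.0 * np.pi * np.prod(axes)
    spacing = (6.0 * density * volume / (np.pi * n)) ** (1.0 / 3.0)
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        cand = u * rng.uniform() ** (1.0 / 3.0) * axes
        if pts and np.linalg.norm(np.asarray(pts) - cand, axis=1).min() < spacing:
            continue
        pts.append(cand)
        if len(pts) == n:
            return np.asarray(pts), spacing
    raise GenerationError(
        f"could not place {n} cells at packing density {density} inside the "
        f"eggshell {tuple(axes)}; try fewer cells"
    )


def _calibrate_diameter(pts: np.ndarray, ratio_low: float = 0.3,
                        ratio_high: float = 0.8, cutoff: float = 2.0) -> float:
    """Nucleus diameter that puts Voronoi-adjacent pair ratios in the
    acceptable band: scan scales keeping the minimum adjacent ratio just
    above ratio_low and pick the one maximizing the in-band fraction."""
    from cmgym.neighbors import _delaunay_pairs

    pairs = _delaunay_pairs(pts)
    d = np.sort([float(np.linalg.norm(pts[i] - pts[j])) for i, j in pairs])
    best_frac, best_diam = -1.0, d[0] / 0.32
    for diam in np.linspace(d[0] / 0.35, d[0] / (ratio_low + 0.001), 41):
        ratios = d / diam
        ratios = ratios[ratios <= cutoff]
        frac = float(np.mean((ratios > ratio_low) & (ratios < ratio_high)))
        if frac > best_frac:
            best_frac, best_diam = frac, diam
    return float(best_diam)


def _drift(base: np.ndarray, n_frames: int, sd: float, axes,
           rng: np.random.Generator) -> np.ndarray:
    """Random-walk drift (sd µm/frame per axis) kept inside the eggshell."""
    out = np.empty((n_frames, 3))
    out[0] = base
    for t in range(1, n_frames):
        step = rng.normal(scale=sd, size=3)
        cand = out[t - 1] + step
        out[t] = cand if _inside_eggshell(cand, axes) else out[t - 1]
    return out


def _assemble(frames_per_cell: dict[str, tuple[int, np.ndarray]], diameter: float,
              spec: ScenarioSpec, extra_meta: dict | None = None,
              diameters: dict[str, float] | None = None) -> EmbryoSeries:
    rows = []
    for name, (start, traj) in frames_per_cell.items():
        d = (diameters or {}).get(name, diameter)
        for k, p in enumerate(traj):
            rows.append((start + k, name, p[0], p[1], p[2], d))
    table = pd.DataFrame(rows, columns=COLUMNS)
    series = EmbryoSeries(
        table=table.sort_values(["frame", "name"]).reset_index(drop=True),
        frame_interval=spec.frame_interval,
        metadata={"generator": "synthetic", "seed": spec.seed, **(extra_meta or {})},
    )
    return series.validate()


def generate_embryo(spec: ScenarioSpec) -> EmbryoSeries:
    """Generate a packed embryo with jitter-drifting cells (no migration).

    Cells fill the eggshell by rejection-sampled packing; the nucleus
    diameter is then calibrated to the realized spacing so that most
    Voronoi-adjacent pairs sit in the acceptable ratio band (0.3, 0.8).
    """
    rng = np.random.default_rng(spec.seed)
    pts, _ = _rsa_positions(spec.n_cells, spec.eggshell, rng)
    diameter = _calibrate_diameter(pts)
    r = diameter / 2.0
    names = _lineage_names(spec.n_cells, rng, reserved=set())
    n_frames = spec.n_frames

    cells: dict[str, tuple[int, np.ndarray]] = {}
    divide_idx = 0 if spec.divide else -1
    division_frame = n_frames // 2
    for i, (name, base) in enumerate(zip(names, pts)):
        traj = _drift(base, n_frames, spec.jitter_sd, spec.eggshell, rng)
        if i == divide_idx:
            cells[name] = (0, traj[:division_frame])
            offset = np.array([0.4 * r, 0.0, 0.0])
            for child, sgn in ((name + "a", -1), (name + "p", +1)):
                child_traj = traj[division_frame:] + sgn * offset
                cells[child] = (division_frame, child_traj)
        else:
            cells[name] = (0, traj)
    return _assemble(cells, diameter, spec)


def generate_migration_scenario(spec: ScenarioSpec) -> tuple[EmbryoSeries, np.ndarray]:
    """Corridor intercalation scenario with a known ground-truth path.

    The migrating cell travels a straight corridor between two rows of
    flanking cells and ends as a Voronoi neighbor of the target cell at the
    corridor exit.  Returns the series and the migrating cell's per-frame
    positions (the ground-truth path).
    """
    rng = np.random.default_rng(spec.seed)
    cor = spec.corridor
    r = spec.cell_radius()
    two_r = 2.0 * r
    dx = cor.spacing_ratio * two_r
    half_gap = cor.gap_ratio * r

    # corridor must admit the migrating cell without interpenetration
    closest = np.hypot(half_gap, dx / 2.0)
    if closest / two_r < 0.3:
        raise GenerationError(
            "corridor blocked: flanking rows leave no gap wider than the "
            "migrating cell's overlap limit"
        )

    n_row = cor.n_per_row
    length = (n_row - 1) * dx
    x0 = -length / 2.0
    positions: dict[str, np.ndarray] = {}
    for i in range(n_row):
        positions[f"{cor.row_name_stem}a" + "a" * i + "p"] = np.array(
            [x0 + i * dx, +half_gap, 0.0])
        positions[f"{cor.row_name_stem}p" + "a" * i + "p"] = np.array(
            [x0 + i * dx, -half_gap, 0.0])

    x_target = length / 2.0 + dx
    positions[spec.target_name] = np.array([x_target, 0.0, 0.0])
    start = np.array([x0 - dx, 0.0, 0.0])
    end = np.array([x_target - cor.spacing_ratio * two_r, 0.0, 0.0])

    # the eggshell stretches to admit the corridor plus flanking tissue
    axes = spec.eggshell
    needed = max(abs(start[0]) + 1.2 * r, abs(x_target) + 1.2 * r)
    axes = (max(needed, axes[0]),
            max(cor.gap_ratio * r + 1.6 * two_r, axes[1]),
            max(1.8 * two_r, axes[2]))

    # remaining environment cells flank the corridor at comfortable
    # near-no-penalty spacing, keeping the scene compact and visually dense
    n_fixed = 2 * n_row + 2
    n_extra = max(spec.n_cells - n_fixed, 0)
    if n_extra:
        existing = np.vstack([start, *positions.values()])
        extra_pts = _pack_positions(
            n_extra, r, axes, rng,
            existing=existing,
            min_ratio=0.7, link_ratio=2.4,
            avoid_segment=(start, end + np.array([two_r, 0.0, 0.0]), 0.7 * two_r),
        )
        for name, p in zip(_lineage_names(n_extra, rng,
                                          reserved=set(positions) | {spec.migrating_name}),
                           extra_pts):
            positions[name] = p

    n_frames = spec.n_frames
    cells: dict[str, tuple[int, np.ndarray]] = {}
    for name, base in positions.items():
        cells[name] = (0, _drift(base, n_frames, spec.jitter_sd, axes, rng))

    # migrating cell: straight path, jitter on top, exact endpoints
    w = np.linspace(0.0, 1.0, n_frames)[:, None]
    path = start[None, :] * (1 - w) + end[None, :] * w
    noise = rng.normal(scale=spec.jitter_sd, size=(n_frames, 3))
    noise[0] = noise[-1] = 0.0
    path = path + noise
    cells[spec.migrating_name] = (0, path)

    series = _assemble(cells, two_r, spec, extra_meta={
        "scenario": "corridor",
        "migrating": spec.migrating_name,
        "target": spec.target_name,
        "eggshell": tuple(axes),
    })
    return series, path


def remove_cells(series: EmbryoSeries, names) -> EmbryoSeries:
    """Copy of the series with the named cells deleted from every frame."""
    names = set(names)
    unknown = names - series.cells()
    if unknown:
        raise ValueError(f"unknown cell name(s): {', '.join(sorted(unknown))}")
    out = series.copy()
    out.table = out.table[~out.table["name"].isin(names)].reset_index(drop=True)
    out.metadata = {**out.metadata, "removed_cells": sorted(names)}
    return out
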