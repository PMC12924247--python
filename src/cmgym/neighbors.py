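"""Neighbor relationships between cells: Voronoi ground truth and a classifier.

Two cells are neighbors when their Voronoi regions share a face, i.e. their
nuclei are Delaunay-adjacent.  Raw 3-D Delaunay over-connects across the
convex hull, so edges whose center-distance / radius-sum ratio exceeds a
cutoff (default 2.0, comfortably above the biologically acceptable band
(0.3, 0.8)) are pruned.  A random-forest classifier trained on handcrafted
pair features (distance, sizes, total cell count) against Voronoi ground
truth provides the same decision without a tessellation, mirroring how
neighborship is scored on real embryos.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from sklearn.ensemble import RandomForestClassifier

from cmgym.errors import ValidationError

#: Delaunay-edge pruning cutoff on the distance/radius-sum ratio.
DEFAULT_RATIO_CUTOFF = 2.0


@dataclass(frozen=True)
class NeighborGraph:
    """Per-frame cell adjacency with provenance."""

    frame: int
    edges: frozenset  # frozenset of frozenset({a, b}) name pairs
    provenance: str  # "voronoi" | "classifier"

    def neighbors(self, cell: str) -> set[str]:
        out = set()
        for e in self.edges:
            if cell in e:
                (other,) = set(e) - {cell}
                out.add(other)
        return out

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges


@dataclass(frozen=True)
class PairFeatures:
    """Handcrafted features of a cell pair used by the classifier.

    Besides the pair's own geometry (distance, sizes, ratio) two context
    features describe whether a third cell blocks the would-be Voronoi
    face: ``blocking_ratio`` is min over other cells c of
    max(d(c,a), d(c,b)) / d(a,b) (the relative-neighborhood-graph lens
    criterion; < 1 means some cell sits between the pair) and
    ``n_blocking`` counts the cells inside that lens.
    """

    distance: float
    size_a: float
    size_b: float
    radius_sum: float
    ratio: float
    n_cells_total: int
    blocking_ratio: float = 10.0
    n_blocking: int = 0

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.distance, self.size_a, self.size_b, self.radius_sum,
             self.ratio, self.n_cells_total, self.blocking_ratio, self.n_blocking],
            dtype=float,
        )


@dataclass(frozen=True)
class RadiusEstimate:
    radius: float
    generation: int
    embryo_volume: float
    n_cells: int


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _points_and_radii(frame_table: pd.DataFrame):
    pts = frame_table[["x", "y", "z"]].to_numpy(float)
    radii = frame_table["diameter"].to_numpy(float) / 2.0
    names = frame_table["name"].tolist()
    return names, pts, radii


def _row(frame_table: pd.DataFrame, name: str) -> pd.Series:
    sub = frame_table[frame_table["name"] == name]
    if sub.empty:
        raise ValueError(f"cell {name!r} not in frame")
    return sub.iloc[0]


def pair_ratio(frame_table: pd.DataFrame, a: str, b: str) -> float:
    """Center distance / radius sum for a named pair (radii = diameter/2)."""
    ra, rb = _row(frame_table, a), _row(frame_table, b)
    d = float(np.linalg.norm(
        ra[["x", "y", "z"]].to_numpy(float) - rb[["x", "y", "z"]].to_numpy(float)
    ))
    rs = (float(ra["diameter"]) + float(rb["diameter"])) / 2.0
    return d / rs if rs > 0 else np.inf


# ---------------------------------------------------------------------------
# Voronoi / Delaunay ground truth
# ---------------------------------------------------------------------------


def voronoi_neighbors(
    frame_table: pd.DataFrame,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
    frame: int | None = None,
) -> NeighborGraph:
    """Ground-truth adjacency from the 3-D Delaunay tessellation (Voronoi dual).

    Degenerate geometries (coplanar/collinear points, or fewer than 5 cells)
    fall back to a lower-dimensional tessellation; with 2 or 3 cells every
    pair within the ratio cutoff is connected.
    """
    names, pts, radii = _points_and_radii(frame_table)
    n = len(names)
    if n < 2:
        raise ValueError(f"need at least 2 cells for a neighbor graph, got {n}")
    if frame is None:
        frame = int(frame_table["frame"].iloc[0]) if "frame" in frame_table else 0

    pairs: set[tuple[int, int]] = set()
    if n <= 3:
        pairs = {(i, j) for i in range(n) for j in range(i + 1, n)}
    else:
        pairs = _delaunay_pairs(pts)

    edges = set()
    for i, j in pairs:
        d = float(np.linalg.norm(pts[i] - pts[j]))
        rs = radii[i] + radii[j]
        if rs > 0 and d / rs <= ratio_cutoff:
            edges.add(frozenset((names[i], names[j])))
    return NeighborGraph(frame=frame, edges=frozenset(edges), provenance="voronoi")


def _delaunay_pairs(pts: np.ndarray) -> set[tuple[int, int]]:
    """Index pairs of Delaunay-adjacent points, with dimensional fallback."""
    for dim in (3, 2, 1):
        sub = pts[:, :dim]
        if dim == 1:
            order = np.argsort(sub[:, 0])
            return {tuple(sorted((order[k], order[k + 1]))) for k in range(len(order) - 1)}
        # rank check: degenerate (flat) clouds make qhull fail in 3-D
        centered = sub - sub.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < dim:
            continue
        try:
            tri = Delaunay(sub)
        except Exception:
            continue
        pairs: set[tuple[int, int]] = set()
        for simplex in tri.simplices:
            for i in range(len(simplex)):
                for j in range(i + 1, len(simplex)):
                    a, b = int(simplex[i]), int(simplex[j])
                    pairs.add((min(a, b), max(a, b)))
        return pairs
    raise ValueError("could not tessellate point set in any dimension")


# ---------------------------------------------------------------------------
# radius estimation
# ---------------------------------------------------------------------------


_FOUNDERS = ("ABarppppp", "AB", "MS", "E", "C", "D", "P4", "P3", "P2", "P1", "P0", "Z2", "Z3", "EMS")


def lineage_generation(name: str) -> int:
    """Divisions since the founder blastomere (suffix letters after the stem)."""
    for founder in sorted(_FOUNDERS, key=len, reverse=True):
        if name.startswith(founder):
            return len(name) - len(founder)
    # unknown stem: count trailing suffix-alphabet letters
    g = 0
    for ch in reversed(name):
        if ch in "apdvlr":
            g += 1
        else:
            break
    return g


def estimate_radius(
    cell: str,
    frame_table: pd.DataFrame,
    embryo_volume: float,
    weight=None,
) -> RadiusEstimate:
    """Model-based cell radius from embryo volume and cell count.

    radius = (3 V w(g) / (4 pi N))^(1/3) with N the cells in the frame and
    w(g) a per-generation weight (default w == 1).  Strictly decreasing in N.
    """
    if not embryo_volume > 0:
        raise ValueError(f"embryo_volume must be > 0, got {embryo_volume}")
    n = len(frame_table)
    if n < 1:
        raise ValueError("frame has no cells")
    g = lineage_generation(cell)
    w = 1.0 if weight is None else float(weight(g))
    r = (3.0 * embryo_volume * w / (4.0 * np.pi * n)) ** (1.0 / 3.0)
    return RadiusEstimate(radius=r, generation=g, embryo_volume=embryo_volume, n_cells=n)


# ---------------------------------------------------------------------------
# pair features / classifier
# ---------------------------------------------------------------------------


def pair_features(
    frame_table: pd.DataFrame,
    a: str,
    b: str,
    n_cells_total: int | None = None,
) -> PairFeatures:
    """Features of a cell pair; radii from nucleus diameters."""
    if a == b:
        raise ValueError("pair features need two distinct cells")
    ra, rb = _row(frame_table, a), _row(frame_table, b)
    pa = ra[["x", "y", "z"]].to_numpy(float)
    pb = rb[["x", "y", "z"]].to_numpy(float)
    d = float(np.linalg.norm(pa - pb))
    size_a, size_b = float(ra["diameter"]), float(rb["diameter"])
    radius_sum = (size_a + size_b) / 2.0
    n = len(frame_table) if n_cells_total is None else int(n_cells_total)
    ratio = d / radius_sum if radius_sum > 0 else 0.0
    if d == 0.0:
        ratio = 0.0
    others = frame_table[~frame_table["name"].isin([a, b])]
    blocking_ratio, n_blocking = 10.0, 0
    if len(others) and d > 0:
        pts = others[["x", "y", "z"]].to_numpy(float)
        dmax = np.maximum(np.linalg.norm(pts - pa, axis=1),
                          np.linalg.norm(pts - pb, axis=1)) / d
        blocking_ratio = float(min(dmax.min(), 10.0))
        n_blocking = int(np.sum(dmax < 1.0))
    return PairFeatures(
        distance=d, size_a=size_a, size_b=size_b,
        radius_sum=radius_sum, ratio=ratio, n_cells_total=n,
        blocking_ratio=blocking_ratio, n_blocking=n_blocking,
    )


class NeighborClassifier:
    """Random-forest pair classifier trained against Voronoi ground truth.

    sklearn-style estimator: ``fit(frames, graphs)`` then
    ``predict(features)`` / ``predict_pair(frame_table, a, b)``.
    Positive pairs are Voronoi edges; negatives are sampled non-edges at a
    1:1 ratio.  Deterministic given ``seed``.
    """

    def __init__(self, n_estimators: int = 100, max_depth=None, seed: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.seed = seed

    def get_params(self, deep=True):
        return {"n_estimators": self.n_estimators, "max_depth": self.max_depth,
                "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, frames, graphs):
        """Train on matching lists of frame tables and NeighborGraphs."""
        rng = np.random.default_rng(self.seed)
        X, y = [], []
        for ft, g in zip(frames, graphs):
            names = sorted(ft["name"].tolist())
            pos = [tuple(sorted(e)) for e in g.edges]
            neg_pool = [
                (a, b)
                for i, a in enumerate(names)
                for b in names[i + 1:]
                if not g.has_edge(a, b)
            ]
            if neg_pool:
                k = min(len(pos), len(neg_pool))
                idx = rng.choice(len(neg_pool), size=k, replace=False)
                neg = [neg_pool[int(i)] for i in idx]
            else:
                neg = []
            for a, b in pos:
                X.append(pair_features(ft, a, b).as_vector())
                y.append(1)
            for a, b in neg:
                X.append(pair_features(ft, a, b).as_vector())
                y.append(0)
        X, y = np.asarray(X), np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValidationError("training set has a single class; need both edges and non-edges")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            random_state=self.seed,
        )
        self.forest_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, features) -> np.ndarray:
        """Predict neighbor (1) / not (0) for PairFeatures or feature rows."""
        if isinstance(features, PairFeatures):
            features = features.as_vector()[None, :]
        X = np.atleast_2d(np.asarray(features, dtype=float))
        return self.forest_.predict(X)

    def predict_pair(self, frame_table: pd.DataFrame, a: str, b: str) -> bool:
        return bool(self.predict(pair_features(frame_table, a, b))[0])

    def graph(self, frame_table: pd.DataFrame, frame: int | None = None) -> NeighborGraph:
        """Classify every pair in a frame into a NeighborGraph."""
        names = sorted(frame_table["name"].tolist())
        feats, pairs = [], []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                feats.append(pair_features(frame_table, a, b).as_vector())
                pairs.append((a, b))
        pred = self.predict(np.asarray(feats))
        edges = frozenset(frozenset(p) for p, k in zip(pairs, pred) if k == 1)
        if frame is None:
            frame = int(frame_table["frame"].iloc[0]) if "frame" in frame_table else 0
        return NeighborGraph(frame=frame, edges=edges, provenance="classifier")

    def save(self, path: str) -> str:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "params": self.get_params(), "forest": self.forest_}, fh)
        return path

    @classmethod
    def load(cls, path: str) -> "NeighborClassifier":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        obj = cls(**blob["params"])
        obj.forest_ = blob["forest"]
        return obj


def train_classifier(frames, graphs, config: dict | None = None, seed: int = 0) -> NeighborClassifier:
    """Functional wrapper over NeighborClassifier.fit."""
    config = config or {}
    clf = NeighborClassifier(seed=seed, **config)
    return clf.fit(frames, graphs)


# ---------------------------------------------------------------------------
# neighbor queries
# ---------------------------------------------------------------------------


def _graph_for(frame_table: pd.DataFrame, model) -> NeighborGraph:
    if isinstance(model, NeighborGraph):
        return model
    if model == "voronoi" or model is None:
        return voronoi_neighbors(frame_table)
    if isinstance(model, NeighborClassifier):
        return model.graph(frame_table)
    raise ValueError(f"unknown neighbor model {model!r}")


def neighbors_of(frame_table: pd.DataFrame, cell: str, model="voronoi") -> set[str]:
    """Direct neighbors of ``cell`` under the chosen model."""
    if cell not in set(frame_table["name"]):
        raise ValueError(f"cell {cell!r} not in frame")
    return _graph_for(frame_table, model).neighbors(cell)


def secondary_neighbors(frame_table: pd.DataFrame, cell: str, model="voronoi") -> set[str]:
    """Neighbors of neighbors, excluding direct neighbors and the cell itself."""
    g = _graph_for(frame_table, model)
    if cell not in set(frame_table["name"]):
        raise ValueError(f"cell {cell!r} not in frame")
    direct = g.neighbors(cell)
    out: set[str] = set()
    for n in direct:
        out |= g.neighbors(n)
    return out - direct - {cell}
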