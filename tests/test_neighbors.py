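import itertools

import numpy as np
import pandas as pd
import pytest

from cmgym.errors import ValidationError
from cmgym.neighbors import (
    NeighborClassifier,
    estimate_radius,
    neighbors_of,
    pair_features,
    pair_ratio,
    secondary_neighbors,
    train_classifier,
    voronoi_neighbors,
)
from conftest import tetrahedron_frame


def frame_of(points, diameter=8.0, names=None):
    points = np.asarray(points, float)
    names = names or [f"C{i}" for i in range(len(points))]
    return pd.DataFrame({"frame": 0, "name": names,
                         "x": points[:, 0], "y": points[:, 1], "z": points[:, 2],
                         "diameter": diameter})


def brute_force_delaunay_pairs(points):
    """Exact Delaunay adjacency for points in general position: a 4-subset is
    a simplex iff its circumsphere is empty; every simplex edge is adjacent."""
    points = np.asarray(points, float)
    n = len(points)
    pairs = set()
    for quad in itertools.combinations(range(n), 4):
        p = points[list(quad)]
        # circumcenter from |x-p_i|^2 equal for all i -> linear system
        a = 2 * (p[1:] - p[0])
        b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
        try:
            center = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            continue
        r2 = ((p[0] - center) ** 2).sum()
        others = [k for k in range(n) if k not in quad]
        d2 = ((points[others] - center) ** 2).sum(axis=1)
        if np.all(d2 > r2 + 1e-9):
            pairs.update(tuple(sorted(e)) for e in itertools.combinations(quad, 2))
    return pairs


class TestVoronoiNeighbors:
    def test_tetrahedron_fully_connected(self):
        g = voronoi_neighbors(tetrahedron_frame())
        assert len(g.edges) == 6

    def test_two_cells_single_edge(self):
        g = voronoi_neighbors(frame_of([[0, 0, 0], [5, 0, 0]]))
        assert len(g.edges) == 1

    def test_lattice_face_adjacent_present_long_diagonals_pruned(self):
        pts = np.array([[i, j, k] for i in range(3) for j in range(3) for k in range(3)],
                       float) * 6.0
        rng = np.random.default_rng(0)
        pts += rng.normal(scale=1e-3, size=pts.shape)  # break ties
        ft = frame_of(pts, diameter=7.0)
        g = voronoi_neighbors(ft, ratio_cutoff=1.0)
        # all 54 face-adjacent pairs (spacing 6, ratio 6/7) survive
        names = ft.name.tolist()
        for i in range(27):
            for j in range(i + 1, 27):
                d = np.linalg.norm(pts[i] - pts[j])
                if d < 6.5:
                    assert g.has_edge(names[i], names[j])
                if d > 10.0:  # space diagonals: ratio > cutoff
                    assert not g.has_edge(names[i], names[j])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_delaunay(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 30, size=(10, 3))
        ft = frame_of(pts, diameter=1000.0)  # huge radii: no ratio pruning
        g = voronoi_neighbors(ft)
        got = {tuple(sorted((int(a[1:]), int(b[1:])))) for a, b in
               (tuple(e) for e in g.edges)}
        assert got == brute_force_delaunay_pairs(pts)

    def test_symmetric_no_self_edges(self, corridor_series):
        g = voronoi_neighbors(corridor_series.frame_table(0))
        for e in g.edges:
            assert len(set(e)) == 2

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            voronoi_neighbors(frame_of([[0, 0, 0]]))

    def test_coplanar_fallback(self):
        pts = [[0, 0, 0], [6, 0, 0], [0, 6, 0], [6, 6, 0], [3, 3, 0]]
        g = voronoi_neighbors(frame_of(pts))
        assert len(g.edges) > 0  # 2-D fallback triangulates the plane


class TestNeighborQueries:
    def test_center_of_octahedral_cross(self):
        pts = [[0, 0, 0], [6, 0, 0], [-6, 0, 0], [0, 6, 0], [0, -6, 0],
               [0, 0, 6], [0, 0, -6]]
        ft = frame_of(pts, diameter=10.0)
        assert neighbors_of(ft, "C0") == {f"C{i}" for i in range(1, 7)}

    def test_isolated_far_cell_empty(self):
        ft = frame_of([[0, 0, 0], [5, 0, 0], [200, 0, 0]], diameter=8.0)
        assert neighbors_of(ft, "C2") == set()

    def test_matches_graph_edges(self, corridor_series):
        ft = corridor_series.frame_table(0)
        g = voronoi_neighbors(ft)
        assert neighbors_of(ft, "Cpaaa") == g.neighbors("Cpaaa")

    def test_unknown_cell_rejected(self, corridor_series):
        with pytest.raises(ValueError):
            neighbors_of(corridor_series.frame_table(0), "Nope")

    def test_secondary_of_chain(self):
        ft = frame_of([[0, 0, 0], [6, 0, 0], [12, 0, 0]], diameter=8.0)
        g = voronoi_neighbors(ft, ratio_cutoff=0.8)  # prune the A-C edge
        assert secondary_neighbors(ft, "C0", g) == {"C2"}

    def test_fully_connected_triple_empty(self):
        ft = frame_of([[0, 0, 0], [6, 0, 0], [3, 5, 0]], diameter=10.0)
        assert secondary_neighbors(ft, "C0") == set()

    def test_corridor_secondary_lie_ahead(self, corridor_series):
        ft = corridor_series.frame_table(0)
        sec = secondary_neighbors(ft, "Cpaaa")
        assert sec
        x_mig = float(ft[ft.name == "Cpaaa"].x.iloc[0])
        ahead = [n for n in sec if float(ft[ft.name == n].x.iloc[0]) > x_mig]
        assert ahead


class TestPairFeatures:
    def test_coincident_cells(self):
        ft = frame_of([[0, 0, 0], [0, 0, 0]], diameter=4.0)
        f = pair_features(ft, "C0", "C1")
        assert f.distance == 0 and f.ratio == 0

    def test_symmetry(self, corridor_series):
        ft = corridor_series.frame_table(0)
        a, b = sorted(ft.name)[:2]
        assert pair_features(ft, a, b).distance == pair_features(ft, b, a).distance

    def test_ratio_arithmetic(self):
        ft = frame_of([[0, 0, 0], [4, 0, 0]], diameter=[4.0, 6.0])
        assert pair_features(ft, "C0", "C1").ratio == pytest.approx(0.8)
        assert pair_ratio(ft, "C0", "C1") == pytest.approx(0.8)


class TestEstimateRadius:
    def test_whole_embryo_sphere(self):
        ft = frame_of([[0, 0, 0]])
        vol = 4 / 3 * np.pi * 5**3
        assert estimate_radius("Ca", ft, vol).radius == pytest.approx(5.0)

    def test_cube_root_scaling(self):
        ft1 = frame_of([[0, 0, 0]])
        ft2 = frame_of([[0, 0, 0], [9, 0, 0]])
        r1 = estimate_radius("Ca", ft1, 100.0).radius
        r2 = estimate_radius("Ca", ft2, 100.0).radius
        assert r1 / r2 == pytest.approx(2 ** (1 / 3))

    def test_unit_case(self):
        ft = frame_of([[0, 0, 0]])
        assert estimate_radius("Ca", ft, 4 * np.pi / 3).radius == pytest.approx(1.0)

    def test_bad_volume_rejected(self):
        with pytest.raises(ValueError):
            estimate_radius("Ca", frame_of([[0, 0, 0]]), 0.0)


@pytest.fixture(scope="module")
def trained(embryo_series):
    frames = [embryo_series.frame_table(f) for f in range(5)]
    graphs = [voronoi_neighbors(ft) for ft in frames]
    return train_classifier(frames, graphs, seed=0), frames, graphs


class TestClassifier:
    def test_in_sample_accuracy(self, trained):
        clf, frames, graphs = trained
        ft, g = frames[0], graphs[0]
        names = sorted(ft.name)
        ok = total = 0
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                total += 1
                ok += clf.predict_pair(ft, a, b) == g.has_edge(a, b)
        assert ok / total >= 0.9

    def test_seeded_retrain_identical(self, embryo_series):
        frames = [embryo_series.frame_table(0)]
        graphs = [voronoi_neighbors(frames[0])]
        c1 = train_classifier(frames, graphs, seed=7)
        c2 = train_classifier(frames, graphs, seed=7)
        g1 = c1.graph(frames[0])
        assert g1.edges == c2.graph(frames[0]).edges

    def test_agrees_with_voronoi_on_tetrahedron(self, trained):
        clf = trained[0]
        ft = tetrahedron_frame(edge=8.0, diameter=10.0)
        names = ft.name.tolist()
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert clf.predict_pair(ft, a, b)

    def test_single_class_training_rejected(self):
        ft = frame_of([[0, 0, 0], [5, 0, 0]], diameter=8.0)
        g = voronoi_neighbors(ft)
        with pytest.raises(ValidationError):
            NeighborClassifier(seed=0).fit([ft], [g])

    def test_save_load_roundtrip(self, trained, tmp_path):
        clf, frames, _ = trained
        p = clf.save(str(tmp_path / "clf.pkl"))
        back = NeighborClassifier.load(p)
        assert back.graph(frames[0]).edges == clf.graph(frames[0]).edges
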