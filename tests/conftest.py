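import numpy as np
import pandas as pd
import pytest

from cmgym.lineage_io import COLUMNS, EmbryoSeries
from cmgym.synthetic import ScenarioSpec, generate_embryo, generate_migration_scenario


def make_series(frames, frame_interval=60.0):
    """Build an EmbryoSeries from {frame: [(name, x, y, z, diameter), ...]}."""
    rows = []
    for f, recs in frames.items():
        for name, x, y, z, d in recs:
            rows.append((f, name, float(x), float(y), float(z), float(d)))
    table = pd.DataFrame(rows, columns=COLUMNS)
    return EmbryoSeries(table=table, frame_interval=frame_interval).validate()


@pytest.fixture
def tiny_series():
    """Two frames, three cells, easy numbers."""
    return make_series({
        0: [("Ca", 0, 0, 0, 4), ("Cp", 10, 0, 0, 4), ("ABa", 5, 8, 0, 4)],
        1: [("Ca", 1, 0, 0, 4), ("Cp", 10, 1, 0, 4), ("ABa", 5, 8, 1, 4)],
    })


@pytest.fixture(scope="session")
def embryo_series():
    return generate_embryo(ScenarioSpec(seed=1))


@pytest.fixture(scope="session")
def corridor():
    """Default corridor migration scenario (series, ground-truth path)."""
    return generate_migration_scenario(ScenarioSpec(seed=1))


@pytest.fixture(scope="session")
def corridor_series(corridor):
    return corridor[0]


def tetrahedron_frame(edge=10.0, diameter=8.0):
    pts = np.array([
        [0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
        [0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)],
    ]) * edge
    return pd.DataFrame({
        "frame": 0,
        "name": [f"C{i}" for i in range(4)],
        "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
        "diameter": diameter,
    })
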